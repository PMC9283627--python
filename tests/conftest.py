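import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import epinet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    """50 x 60 x 8 planted screen: 5% aggravating + 5% alleviating at six
    noise-SDs, 30% of planted pairs rewired to a single condition."""
    return epinet.ScreenConfig(n_donors=50, n_recipients=60, seed=1)


@pytest.fixture(scope="session")
def planted_bundle(small_cfg):
    """Full analysis of the seed-1 planted screen, shared across tests."""
    rm_raw, mm_raw, truth = epinet.generate_screen(small_cfg)
    rm = epinet.normalize_screen(rm_raw)
    mm = epinet.normalize_screen(mm_raw)
    fitness = {"RM": epinet.estimate_fitness(rm), "MM": epinet.estimate_fitness(mm)}
    scores, nets = {}, {}
    for screen in (rm, mm):
        cond = screen.condition
        mult = epinet.score_multiplicative(screen, fitness[cond])
        gp = epinet.score_gaussian_process(screen, fitness[cond])
        scores[cond] = (mult, gp)
        nets[cond] = epinet.call_static_network(mult, gp)
    return {
        "config": small_cfg,
        "truth": truth,
        "screens": {"RM": rm, "MM": mm},
        "fitness": fitness,
        "scores": scores,
        "networks": nets,
    }


def make_static_network(universe_pairs, edges, condition="RM"):
    """StaticNetwork stub from explicit pair lists (for stats/evolution tests).

    ``edges`` is a list of (donor, recipient, sign).
    """
    all_scores = pd.DataFrame(universe_pairs, columns=["donor", "recipient"])
    all_scores["condition"] = condition
    all_scores["S_gp"] = 0.0
    edf = pd.DataFrame(edges, columns=["donor", "recipient", "sign"])
    edf["condition"] = condition
    edf["S"] = np.where(edf["sign"] == "aggravating", -5.0, 5.0) if len(edf) else []
    return epinet.StaticNetwork(condition, all_scores, edf)


@pytest.fixture
def network_stub():
    return make_static_network
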
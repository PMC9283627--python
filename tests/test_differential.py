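"""Differential scores, split-half null, empirical P, gain/loss calling."""

import numpy as np
import pandas as pd
import pytest

import epinet


def _static_pair_net(scores: dict, condition: str) -> epinet.StaticNetwork:
    df = pd.DataFrame(
        {"donor": [k[0] for k in scores], "recipient": [k[1] for k in scores],
         "condition": condition, "S_gp": list(scores.values())}
    )
    return epinet.StaticNetwork(condition, df, df.head(0).assign(S=[], Z=[], P=[], sign=[]))


def test_differential_is_plain_difference():
    rm = _static_pair_net({("a", "x"): 1.0, ("b", "y"): -2.0}, "RM")
    mm = _static_pair_net({("a", "x"): 1.0, ("b", "y"): 1.5}, "MM")
    rec = epinet.compute_differential(rm, mm).set_index(["donor", "recipient"])
    assert rec.loc[("a", "x"), "S_DF"] == 0.0
    assert rec.loc[("b", "y"), "S_DF"] == pytest.approx(3.5)


def test_pair_scored_in_one_condition_is_flagged():
    rm = _static_pair_net({("a", "x"): 1.0, ("b", "y"): 2.0}, "RM")
    mm = _static_pair_net({("a", "x"): 0.5}, "MM")
    rec = epinet.compute_differential(rm, mm).set_index(["donor", "recipient"])
    assert not rec.loc[("b", "y"), "both_scored"]
    assert np.isnan(rec.loc[("b", "y"), "S_DF"])
    called = epinet.call_differential(
        epinet.assign_differential_p(rec.reset_index(), np.r_[np.zeros(200), 1.0])
    )
    assert called.set_index(["donor", "recipient"]).loc[("b", "y"), "diff_class"] == "neutral"


def test_differential_antisymmetry():
    rng = np.random.default_rng(3)
    pairs = {(f"d{i}", f"r{i}"): rng.normal() for i in range(20)}
    pairs_mm = {k: rng.normal() for k in pairs}
    rm = _static_pair_net(pairs, "RM")
    mm = _static_pair_net(pairs_mm, "MM")
    fwd = epinet.compute_differential(rm, mm)["S_DF"].to_numpy()
    rev = epinet.compute_differential(mm, rm)["S_DF"].to_numpy()
    assert np.array_equal(fwd, -rev)


def test_difference_null_requires_enough_replicates(small_cfg):
    rm, mm, _ = epinet.generate_screen(
        epinet.ScreenConfig(n_donors=5, n_recipients=6, n_replicates=3, seed=2)
    )
    with pytest.raises(ValueError, match="split halves"):
        epinet.difference_null(rm, mm, lambda s: None, n_splits=1)
    with pytest.raises(ValueError, match="n_splits"):
        epinet.difference_null(rm, mm, lambda s: None, n_splits=0)


def test_difference_null_is_centered_on_noise_free_screens():
    cfg = epinet.ScreenConfig(
        n_donors=20, n_recipients=24, noise_sd=0.0, row_effect_sd=0.0,
        col_effect_sd=0.0, edge_effect=0.0, planted_fraction_aggravating=0.0,
        planted_fraction_alleviating=0.0, seed=11,
    )
    rm, mm, _ = epinet.generate_screen(cfg)
    fit = {"RM": epinet.estimate_fitness(rm), "MM": epinet.estimate_fitness(mm)}

    def scorer(screen):
        return epinet.score_multiplicative(screen, fit[screen.condition], min_replicates=2,
                                           variance_floor=1.0)

    null = epinet.difference_null(rm, mm, scorer, n_splits=2, seed=0)
    assert np.all(np.abs(null) < 1e-6)


def test_empirical_p_examples():
    rec = pd.DataFrame({"donor": ["a"], "recipient": ["x"], "S_RM": [0.0],
                        "S_MM": [1.5], "S_DF": [1.5], "both_scored": [True]})
    # m=4 null {-1, 0, 1, 2}: one |null| >= 1.5 -> P = (1+1)/5
    out = epinet.assign_differential_p(rec, np.array([-1.0, 0.0, 1.0, 2.0]))
    assert out["P_DF"].iloc[0] == pytest.approx(0.4)
    # S_DF beyond every null value with m=999 -> P = 1/1000
    out = epinet.assign_differential_p(rec.assign(S_DF=99.0), np.linspace(-1, 1, 999))
    assert out["P_DF"].iloc[0] == pytest.approx(0.001)
    # S_DF = 0 -> every null value qualifies -> P = 1
    out = epinet.assign_differential_p(rec.assign(S_DF=0.0), np.linspace(-1, 1, 999))
    assert out["P_DF"].iloc[0] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="empty null"):
        epinet.assign_differential_p(rec, np.array([]))


@pytest.mark.parametrize(
    "s_df,p_df,expected",
    [
        (-3.0, 0.01, "aggravating"),
        (1.7, 0.04, "alleviating"),  # inclusive boundary
        (-2.6, 0.05, "aggravating"),  # both boundaries inclusive
        (1.0, 0.001, "neutral"),  # inside the neutral band regardless of P
        (5.0, 0.2, "neutral"),  # not significant
    ],
)
def test_differential_call_cutoffs(s_df, p_df, expected):
    rec = pd.DataFrame({"donor": ["a"], "recipient": ["x"], "S_RM": [0.0],
                        "S_MM": [s_df], "S_DF": [s_df], "P_DF": [p_df],
                        "both_scored": [True]})
    out = epinet.call_differential(rec)
    assert out["diff_class"].iloc[0] == expected


def _records(rows):
    df = pd.DataFrame(rows, columns=["donor", "recipient", "S_RM", "S_MM", "P_DF"])
    df["S_DF"] = df["S_MM"] - df["S_RM"]
    df["both_scored"] = True
    return epinet.call_differential(df)


def _net_with_edges(pairs, condition):
    uni = [("a", "x"), ("b", "y"), ("c", "z")]
    df = pd.DataFrame(uni, columns=["donor", "recipient"])
    df["condition"] = condition
    df["S_gp"] = 0.0
    edges = pd.DataFrame(pairs, columns=["donor", "recipient"])
    edges["sign"] = "alleviating"
    return epinet.StaticNetwork(condition, df, edges)


def test_gain_loss_labels():
    rm = _net_with_edges([("b", "y")], "RM")  # b-y significant in RM only
    mm = _net_with_edges([("a", "x")], "MM")  # a-x significant in MM only
    rec = _records([
        ("a", "x", 0.0, 6.0, 0.01),   # neutral RM -> significant MM: gain
        ("b", "y", -6.0, 0.0, 0.01),  # significant RM -> neutral MM: loss
        ("c", "z", 0.0, 4.9, 0.01),   # |S_DF| below the 5.0 magnitude cut
    ])
    out = epinet.classify_gain_loss(rec, rm, mm).set_index(["donor", "recipient"])
    assert out.loc[("a", "x"), "gain_loss"] == "gain"
    assert out.loc[("b", "y"), "gain_loss"] == "loss"
    assert out.loc[("c", "z"), "gain_loss"] == "none"
    # the two labeled records carry a clustering display order
    orders = out["cluster_order"].dropna()
    assert sorted(orders) == [0.0, 1.0]


def test_gain_loss_tie_rule_uses_dominant_shift():
    rm = _net_with_edges([("a", "x")], "RM")
    mm = _net_with_edges([("a", "x")], "MM")  # significant in both
    rec = _records([("a", "x", -2.0, -9.0, 0.01)])
    out = epinet.classify_gain_loss(rec, rm, mm)
    assert out["gain_loss"].iloc[0] == "gain"  # |S_MM| > |S_RM|
    rec = _records([("a", "x", 9.0, 2.0, 0.01)])
    out = epinet.classify_gain_loss(rec, rm, mm)
    assert out["gain_loss"].iloc[0] == "loss"


def test_cluster_order_is_deterministic():
    rng = np.random.default_rng(9)
    rows = [(f"d{i}", f"r{i}", rng.normal(), rng.normal() + 8.0, 0.01) for i in range(30)]
    rm = _net_with_edges([], "RM")
    mm = _net_with_edges([], "MM")
    a = epinet.classify_gain_loss(_records(rows), rm, mm)["cluster_order"]
    b = epinet.classify_gain_loss(_records(rows), rm, mm)["cluster_order"]
    assert a.equals(b)
    assert sorted(a.dropna()) == list(range(30))


def test_rewiring_recovery(planted_bundle):
    """Rewired planted pairs are called in the differential network; pairs
    planted identically in both conditions mostly are not."""
    truth = planted_bundle["truth"]
    fit = planted_bundle["fitness"]
    nets = planted_bundle["networks"]
    rm, mm = planted_bundle["screens"]["RM"], planted_bundle["screens"]["MM"]

    def half_scorer(screen):
        return epinet.score_gaussian_process(screen, fit[screen.condition], min_replicates=2)

    rec = epinet.compute_differential(nets["RM"], nets["MM"])
    null = epinet.difference_null(rm, mm, half_scorer, n_splits=4, seed=1)
    rec = epinet.call_differential(epinet.assign_differential_p(rec, null))
    nonneutral = set(map(tuple, rec.loc[rec["diff_class"] != "neutral", ["donor", "recipient"]].to_numpy()))
    rewired, stable = truth.rewired_pairs, truth.stable_pairs()
    assert len(nonneutral & rewired) / len(rewired) >= 0.75
    assert len(nonneutral & stable) / len(stable) < 0.10


def test_recount_of_deposited_style_table():
    """Applying the printed cut-offs to a differential edge-list reproduces
    its headline counts (synthetic deposited-style fixture)."""
    rng = np.random.default_rng(21)
    n = 400
    s_df = rng.normal(0, 3, n)
    p_df = np.where(np.abs(s_df) > 2, 0.01, 0.5)
    df = pd.DataFrame({
        "donor": [f"d{i}" for i in range(n)], "recipient": [f"r{i}" for i in range(n)],
        "S_RM": 0.0, "S_MM": s_df, "S_DF": s_df, "P_DF": p_df, "both_scored": True,
    })
    counts = epinet.recount_table(df)
    expect_agg = int(((s_df <= -2.6) & (p_df <= 0.05)).sum())
    expect_alv = int(((s_df >= 1.7) & (p_df <= 0.05)).sum())
    assert counts["n_aggravating"] == expect_agg
    assert counts["n_alleviating"] == expect_alv
    assert counts["n_at_magnitude"] == int(((np.abs(s_df) >= 5) & (p_df <= 0.05)).sum())
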
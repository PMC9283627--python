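"""Enrichment, permutation, profile-correlation and degree statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import epinet
from epinet.screen import GeneRecord


def _gene(gid, procs, scope="local", orphan=False):
    return GeneRecord(gid, 0, orphan, scope, False, frozenset(procs))


# ---------------------------------------------------------------- hypergeom

@pytest.mark.parametrize(
    "k,n,M,N,expected",
    [
        (0, 3, 5, 10, 1.0),      # upper tail always includes k = 0
        (3, 3, 3, 3, 1.0),       # forced draw
        (2, 3, 5, 10, 0.5),      # (C(5,2)C(5,1) + C(5,3)) / C(10,3)
    ],
)
def test_hypergeom_examples(k, n, M, N, expected):
    assert epinet.hypergeom_upper_tail(k, n, M, N) == pytest.approx(expected, abs=1e-12)


def test_hypergeom_rejects_bad_parameters():
    with pytest.raises(ValueError):
        epinet.hypergeom_upper_tail(4, 3, 5, 10)
    with pytest.raises(ValueError):
        epinet.hypergeom_upper_tail(1, 3, 11, 10)


# ------------------------------------------------------------------ BH FDR

def _bh_oracle(p):
    """Step-up definition: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


def test_bh_examples():
    assert epinet.bh_fdr([0.03]) == pytest.approx([0.03])
    assert epinet.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert epinet.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)
    assert epinet.bh_fdr([]).size == 0


@given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=40))
def test_bh_matches_step_up_definition(p):
    got = epinet.bh_fdr(p)
    want = _bh_oracle(p)
    assert np.allclose(got, want, atol=1e-12)
    assert (got <= 1.0 + 1e-12).all()


# -------------------------------------------------------------- crosstalk

def test_crosstalk_empty_network_is_flat(network_stub):
    genes = [_gene(f"g{i}", ["A" if i % 2 else "B"]) for i in range(8)]
    uni = [(f"g{i}", f"g{j}") for i in range(8) for j in range(i + 1, 8)]
    net = network_stub(uni, [])
    out = epinet.process_crosstalk(net, genes)
    assert (out["k"] == 0).all()
    assert (out["P"] == 1.0).all()


def test_crosstalk_finds_planted_process_pair(network_stub):
    """Edges planted only between processes A and B make (A, B) the most
    enriched of all process pairs."""
    rng = np.random.default_rng(11)
    procs = ["A", "B", "C", "D"]
    genes = [_gene(f"g{i:02d}", [procs[i % 4]]) for i in range(40)]
    by_proc = {p: [g.gene_id for g in genes if p in g.major_bioprocesses] for p in procs}
    uni = [(a, b) for i, a in enumerate([g.gene_id for g in genes])
           for b in [g.gene_id for g in genes][i + 1:]]
    edges = []
    for a in by_proc["A"]:
        for b in by_proc["B"]:
            if rng.random() < 0.8:
                edges.append((a, b, "aggravating"))
    net = network_stub(uni, edges)
    out = epinet.process_crosstalk(net, genes)
    best = out.sort_values("P").iloc[0]
    assert {best["process_a"], best["process_b"]} == {"A", "B"}
    assert (out["q"] >= out["P"] - 1e-12).all()


def test_crosstalk_counts_category_pairs_including_self_pairs(network_stub):
    """c categories whose pairs all occur in the universe yield
    c*(c+1)/2 tested pairs (53 categories -> 1431)."""
    c = 53
    genes = [_gene(f"g{i:02d}", [f"c{i:02d}"]) for i in range(c)]
    ids = [g.gene_id for g in genes]
    uni = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    # add one self-process pair per category via a duplicate-gene partner
    extra_genes = [_gene(f"h{i:02d}", [f"c{i:02d}"]) for i in range(c)]
    uni += [(f"g{i:02d}", f"h{i:02d}") for i in range(c)]
    net = network_stub(uni, [])
    out = epinet.process_crosstalk(net, genes + extra_genes)
    assert len(out) == c * (c + 1) // 2 == 1431


def test_crosstalk_requires_annotations(network_stub):
    net = network_stub([("g0", "g1")], [])
    with pytest.raises(ValueError, match="unannotated"):
        epinet.process_crosstalk(net, [_gene("g0", ["A"])])


# ------------------------------------------------------------- permutation

def test_module_permutation_flags_planted_crosstalk(network_stub):
    rng = np.random.default_rng(3)
    genes = [f"g{i:02d}" for i in range(40)]
    modules = {g: f"m{i // 10}" for i, g in enumerate(genes)}
    uni = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
    # dense edges between m0 and m1 only, sparse elsewhere
    edges = []
    for a, b in uni:
        ma, mb = modules[a], modules[b]
        p = 0.9 if {ma, mb} == {"m0", "m1"} else 0.05
        if rng.random() < p:
            edges.append((a, b, "aggravating"))
    res = epinet.module_crosstalk_permutation(network_stub(uni, edges), modules, n_perm=300, seed=0)
    res = res.set_index(["module_a", "module_b"])
    assert res.loc[("m0", "m1"), "significant"]
    assert res.loc[("m0", "m1"), "Z"] == res["Z"].max()
    # Z definition: (observed - mean) / sd
    row = res.loc[("m0", "m1")]
    assert row["Z"] == pytest.approx((row["observed"] - row["perm_mean"]) / row["perm_sd"])


def test_module_permutation_degenerate_sd_is_flagged(network_stub):
    genes = [f"g{i}" for i in range(8)]
    modules = {g: f"m{i // 4}" for i, g in enumerate(genes)}
    res = epinet.module_crosstalk_permutation(network_stub([("g0", "g1")], []), modules, n_perm=50, seed=0)
    assert res["sd_zero"].all()
    assert res["Z"].isna().all()
    assert not res["significant"].any()


def test_module_permutation_rejects_tiny_modules(network_stub):
    with pytest.raises(ValueError, match="at least 2"):
        epinet.module_crosstalk_permutation(
            network_stub([("g0", "g1")], []), {"g0": "m0", "g1": "m1"}, n_perm=10
        )


# ---------------------------------------------------------------- profiles

def _profile_scores(vectors: dict, partners: list) -> pd.DataFrame:
    rows = []
    for g, vec in vectors.items():
        for p, s in zip(partners, vec):
            rows.append((g, p, s))
    return pd.DataFrame(rows, columns=["donor", "recipient", "S"])


def test_profile_correlation_extremes_and_zero():
    partners = [f"r{i}" for i in range(4)]
    scores = _profile_scores(
        {"a": [1, 0, 1, 0], "b": [1, 1, 0, 0], "c": [1, 0, 1, 0], "d": [-1, 0, -1, 0]},
        partners,
    )
    assert epinet.profile_correlation(scores, "a", "c", min_shared=4).r == pytest.approx(1.0)
    assert epinet.profile_correlation(scores, "a", "d", min_shared=4).r == pytest.approx(-1.0)
    assert epinet.profile_correlation(scores, "a", "b", min_shared=4).r == pytest.approx(0.0, abs=1e-12)


def test_profile_correlation_is_symmetric_and_respects_min_shared():
    rng = np.random.default_rng(0)
    partners = [f"r{i}" for i in range(40)]
    scores = _profile_scores({"a": rng.normal(size=40), "b": rng.normal(size=40)}, partners)
    ab = epinet.profile_correlation(scores, "a", "b")
    ba = epinet.profile_correlation(scores, "b", "a")
    assert ab.r == ba.r
    assert ab.n_shared == 40
    assert epinet.profile_correlation(scores, "a", "b", min_shared=41) is None


def test_autocorrelation_classes():
    partners = [f"r{i}" for i in range(8)]
    x = [1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0]
    z = [1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0]  # orthogonal to x, same norm
    rm = _profile_scores({"a": x}, partners)
    cfg = epinet.AnalysisConfig(min_shared=8)
    pc, cls = epinet.autocorrelation(rm, _profile_scores({"a": x}, partners), "a", cfg)
    assert pc.r == pytest.approx(1.0) and cls == "high"
    # r exactly 0.25 by construction -> boundary goes to "high"
    y = [0.25 * xi + np.sqrt(1 - 0.25**2) * zi for xi, zi in zip(x, z)]
    pc, cls = epinet.autocorrelation(rm, _profile_scores({"a": y}, partners), "a", cfg)
    assert pc.r == pytest.approx(0.25)
    assert cls == "high"
    pc, cls = epinet.autocorrelation(rm, _profile_scores({"a": z}, partners), "a", cfg)
    assert pc.r == pytest.approx(0.0, abs=1e-12) and cls == "low"


def test_autocorrelation_null_is_tight():
    """Independent random RM/MM profiles of length 300 rarely exceed |r| 0.2."""
    rng = np.random.default_rng(3)
    partners = [f"r{i}" for i in range(300)]
    hits = 0
    n_genes = 200
    rm = _profile_scores({f"g{i}": rng.normal(size=300) for i in range(n_genes)}, partners)
    mm = _profile_scores({f"g{i}": rng.normal(size=300) for i in range(n_genes)}, partners)
    cfg = epinet.AnalysisConfig(min_shared=30)
    for i in range(n_genes):
        pc, _ = epinet.autocorrelation(rm, mm, f"g{i}", cfg)
        hits += abs(pc.r) < 0.2
    assert hits / n_genes >= 0.95


# ------------------------------------------------------------------ degree

def test_degree_hub_boundary(network_stub):
    genes = [_gene("hub", ["A"], scope="global")] + [
        _gene(f"g{i:03d}", ["A"]) for i in range(150)
    ]
    ids = [g.gene_id for g in genes]
    uni = [("hub", g) for g in ids[1:]]
    edges100 = [("hub", g, "aggravating") for g in ids[1:101]]
    per_gene, _ = epinet.degree_stats(network_stub(uni, edges100), genes)
    row = per_gene.set_index("gene").loc["hub"]
    assert row["degree"] == 100 and row["hub"]
    edges99 = edges100[:99]
    per_gene, _ = epinet.degree_stats(network_stub(uni, edges99), genes)
    assert not per_gene.set_index("gene").loc["hub", "hub"]


def test_degree_empty_network_and_ratio(network_stub):
    genes = [_gene("a", ["A"]), _gene("b", ["A"])]
    per_gene, summaries = epinet.degree_stats(network_stub([("a", "b")], []), genes)
    assert (per_gene["degree"] == 0).all()
    assert not per_gene["hub"].any()
    assert np.isnan(per_gene["agg_allev_ratio"]).all()  # zero alleviating -> missing
    assert summaries["scope_pairs"]["local-local"] == 0


def test_degree_class_summaries(network_stub):
    genes = [
        _gene("gl", ["A"], scope="global"),
        _gene("lo1", ["A"]),
        _gene("lo2", ["A"], orphan=True),
    ]
    edges = [("gl", "lo1", "aggravating"), ("lo1", "lo2", "alleviating")]
    uni = [("gl", "lo1"), ("lo1", "lo2"), ("gl", "lo2")]
    per_gene, summaries = epinet.degree_stats(network_stub(uni, edges), genes)
    assert summaries["scope_pairs"] == {"local-local": 1, "global-local": 1, "global-global": 0}
    assert summaries["orphan_pairs"] == {"orphan-annotated": 1, "other": 1}
    row = per_gene.set_index("gene").loc["lo1"]
    assert row["degree"] == 2
    assert row["agg_allev_ratio"] == pytest.approx(1.0)
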
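"""Condition-rewiring (differential) genetic-interaction network.

The differential score of a pair is the change of its Gaussian-process
static score between minimal and rich medium, S_DF = S_MM - S_RM.
Significance is assessed against an empirical null distribution of score
differences built by split-half rescoring within each condition: replicate
colonies are split in half, each half scored independently, and the
within-condition half-vs-half score differences pooled — they carry
replicate noise but no condition effect. Differential calls use the
published cuts (-2.6 <= S_DF for aggravating, S_DF >= 1.7 for alleviating,
P <= 0.05), and gain/loss of interaction is assigned at |S_DF| >= 5.0 with
a deterministic average-linkage clustering order for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import NEUTRAL, StaticNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferentialThresholds:
    lower_diff_cut: float = -2.6
    upper_diff_cut: float = 1.7
    p_cut: float = 0.05
    gainloss_magnitude: float = 5.0

    def __post_init__(self) -> None:
        if not self.lower_diff_cut < 0 < self.upper_diff_cut:
            raise ValueError("cuts must satisfy lower < 0 < upper")


def compute_differential(rm: StaticNetwork, mm: StaticNetwork) -> pd.DataFrame:
    """One record per pair: S_RM, S_MM (GP scores) and S_DF = S_MM - S_RM.

    Pairs scored in only one condition get NaN S_DF and ``both_scored``
    False; they are excluded from significance calling downstream.
    """
    a = rm.all_scores[["donor", "recipient", "S_gp"]].rename(columns={"S_gp": "S_RM"})
    b = mm.all_scores[["donor", "recipient", "S_gp"]].rename(columns={"S_gp": "S_MM"})
    rec = a.merge(b, on=["donor", "recipient"], how="outer")
    rec["S_DF"] = rec["S_MM"] - rec["S_RM"]
    rec["both_scored"] = np.isfinite(rec["S_DF"])
    return rec


def difference_null(
    rm_screen,
    mm_screen,
    scorer,
    n_splits: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Empirical null of score differences by within-condition split halves.

    ``scorer`` is a pipeline handle mapping a ColonyScreen to a score table
    with columns (donor, recipient, S). For each of ``n_splits`` seeded
    random splits, the replicates of each condition are halved, each half
    scored independently, and the half-A minus half-B scores pooled across
    pairs, splits and conditions.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    rng = np.random.default_rng(seed)
    diffs = []
    for screen in (rm_screen, mm_screen):
        n_rep = screen.colonies.shape[2]
        if n_rep < 4:
            raise ValueError("cannot form split halves with fewer than 4 replicates")
        half = n_rep // 2
        for _ in range(n_splits):
            perm = rng.permutation(n_rep)
            halves = []
            for idx in (perm[:half], perm[half : 2 * half]):
                sub = screen.copy()
                sub.colonies = screen.colonies[:, :, idx]
                sub.plate_assign = screen.plate_assign[:, :, idx, :]
                halves.append(scorer(sub))
            merged = halves[0].merge(
                halves[1], on=["donor", "recipient"], suffixes=("_a", "_b")
            )
            diffs.append((merged["S_a"] - merged["S_b"]).to_numpy())
    pooled = np.concatenate(diffs)
    return pooled[np.isfinite(pooled)]


def assign_differential_p(records: pd.DataFrame, null_sample: np.ndarray) -> pd.DataFrame:
    """Two-sided empirical P with add-one smoothing against the null.

    P_DF = (1 + #{null : |null| >= |S_DF|}) / (m + 1), always in (0, 1];
    NaN S_DF stays NaN.
    """
    null_abs = np.sort(np.abs(np.asarray(null_sample, dtype=float)))
    m = null_abs.size
    if m == 0:
        raise ValueError("empty null sample")
    if m < 100:
        logger.warning("difference null has only %d values; P resolution is coarse", m)
    out = records.copy()
    s = np.abs(out["S_DF"].to_numpy())
    # count of null values >= |S_DF| via searchsorted on the sorted |null|
    ge = m - np.searchsorted(null_abs, s, side="left")
    p = (1.0 + ge) / (m + 1.0)
    p[~np.isfinite(s)] = np.nan
    out["P_DF"] = p
    return out


def call_differential(
    records: pd.DataFrame, thresholds: DifferentialThresholds | None = None
) -> pd.DataFrame:
    """Classify each pair: aggravating (S_DF <= lower cut), alleviating
    (S_DF >= upper cut), else neutral; significance requires P_DF <= p_cut.
    Boundaries inclusive."""
    t = thresholds or DifferentialThresholds()
    out = records.copy()
    s, p = out["S_DF"].to_numpy(), out["P_DF"].to_numpy()
    cls = np.full(len(out), NEUTRAL, dtype=object)
    with np.errstate(invalid="ignore"):
        cls[(s <= t.lower_diff_cut) & (p <= t.p_cut)] = "aggravating"
        cls[(s >= t.upper_diff_cut) & (p <= t.p_cut)] = "alleviating"
    out["diff_class"] = cls
    return out


def _leaf_order(linkage: np.ndarray, n: int, labels: list) -> list:
    """Deterministic leaf order: smaller cluster first, lexicographic
    tie-break by the cluster's minimal pair id."""
    size = {}
    min_label = {}
    for i in range(n):
        size[i] = 1
        min_label[i] = labels[i]
    for j, (a, b, _d, _s) in enumerate(linkage):
        node = n + j
        size[node] = size[int(a)] + size[int(b)]
        min_label[node] = min(min_label[int(a)], min_label[int(b)])

    def expand(node: int) -> list:
        if node < n:
            return [node]
        a, b = int(linkage[node - n][0]), int(linkage[node - n][1])
        first, second = (a, b)
        if (size[b], min_label[b]) < (size[a], min_label[a]):
            first, second = (b, a)
        return expand(first) + expand(second)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 2 * n + 100))
    try:
        return expand(2 * n - 2) if n > 1 else [0]
    finally:
        sys.setrecursionlimit(old)


def classify_gain_loss(
    records: pd.DataFrame,
    rm: StaticNetwork,
    mm: StaticNetwork,
    thresholds: DifferentialThresholds | None = None,
) -> pd.DataFrame:
    """Label gain/loss of interaction and attach a clustering display order.

    Restricted to pairs with P_DF <= p_cut and |S_DF| >= gainloss_magnitude:
    gain = neutral in the RM static network but significant in MM; loss =
    significant in RM but neutral in MM; pairs significant (or neutral) in
    both are labeled by the dominant |S| shift (gain iff |S_MM| > |S_RM|).
    The ``cluster_order`` column ranks the labeled records by average-linkage
    hierarchical clustering on (S_RM, S_MM), Euclidean metric, with a
    deterministic smaller-cluster-first leaf order; unlabeled records get NaN.
    """
    from scipy.cluster.hierarchy import linkage as scipy_linkage

    t = thresholds or DifferentialThresholds()
    out = records.copy()
    sig_rm = set(map(tuple, rm.significant_edges[["donor", "recipient"]].to_numpy()))
    sig_mm = set(map(tuple, mm.significant_edges[["donor", "recipient"]].to_numpy()))

    s = out["S_DF"].to_numpy()
    with np.errstate(invalid="ignore"):
        eligible = (out["P_DF"].to_numpy() <= t.p_cut) & (np.abs(s) >= t.gainloss_magnitude)
    eligible &= np.isfinite(s)

    gl = np.full(len(out), "none", dtype=object)
    pairs = list(map(tuple, out[["donor", "recipient"]].to_numpy()))
    for i in np.where(eligible)[0]:
        in_rm, in_mm = pairs[i] in sig_rm, pairs[i] in sig_mm
        if not in_rm and in_mm:
            gl[i] = "gain"
        elif in_rm and not in_mm:
            gl[i] = "loss"
        else:
            gl[i] = "gain" if abs(out["S_MM"].iat[i]) > abs(out["S_RM"].iat[i]) else "loss"
    out["gain_loss"] = gl

    out["cluster_order"] = np.nan
    idx = np.where(eligible)[0]
    if idx.size >= 2:
        feats = out.iloc[idx][["S_RM", "S_MM"]].to_numpy()
        lk = scipy_linkage(feats, method="average", metric="euclidean")
        order = _leaf_order(lk, idx.size, [pairs[i] for i in idx])
        ranks = np.empty(idx.size)
        ranks[order] = np.arange(idx.size)
        out.iloc[idx, out.columns.get_loc("cluster_order")] = ranks
    elif idx.size == 1:
        out.iloc[idx, out.columns.get_loc("cluster_order")] = 0.0
    return out


@dataclass
class DifferentialNetwork:
    """Called differential records plus the thresholds that produced them."""

    records: pd.DataFrame
    thresholds: DifferentialThresholds

    @property
    def significant_edges(self) -> pd.DataFrame:
        sig = self.records[self.records["diff_class"] != NEUTRAL].copy()
        sig = sig.rename(columns={"S_DF": "S", "diff_class": "sign"})
        return sig[["donor", "recipient", "S", "sign"]].reset_index(drop=True)

    @property
    def all_pairs(self) -> pd.DataFrame:
        return self.records[self.records["both_scored"]]


def recount_table(records: pd.DataFrame, thresholds: DifferentialThresholds | None = None) -> dict:
    """Recount headline tallies from a differential table (e.g., a deposited
    network export parsed by :func:`epinet.io.read_edge_list`).

    Returns counts of aggravating / alleviating differential calls at the
    score-and-P cuts, the pairs passing the gain/loss magnitude filter, and
    gain/loss tallies when a ``gain_loss`` column is present.
    """
    t = thresholds or DifferentialThresholds()
    called = call_differential(records, t)
    s, p = called["S_DF"].to_numpy(), called["P_DF"].to_numpy()
    with np.errstate(invalid="ignore"):
        at_magnitude = (np.abs(s) >= t.gainloss_magnitude) & (p <= t.p_cut)
    counts = {
        "n_aggravating": int((called["diff_class"] == "aggravating").sum()),
        "n_alleviating": int((called["diff_class"] == "alleviating").sum()),
        "n_at_magnitude": int(np.nansum(at_magnitude)),
    }
    if "gain_loss" in records.columns:
        counts["n_gain"] = int((records.loc[at_magnitude, "gain_loss"] == "gain").sum())
        counts["n_loss"] = int((records.loc[at_magnitude, "gain_loss"] == "loss").sum())
    return counts
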
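"""Downstream statistics on static and differential GI networks.

Covers process-crosstalk enrichment (exact hypergeometric upper tail with
Benjamini-Hochberg FDR), permutation module-crosstalk Z-tests, GI-profile
Pearson correlation and cross-condition autocorrelation, hub detection and
degree/ratio summaries by regulator class.

The hypergeometric parameterization follows the network convention:
k = significant GIs between the two categories, n = possible GIs between
them, M = significant GIs in the whole network, N = possible GIs in the
network. Fuzzy category membership counts a gene pair once per category
pair it instantiates, with M and N on the same pair universe so
(k, n, M, N) stay consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .scoring import AGGRAVATING, ALLEVIATING, StaticNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    hub_min_degree: int = 100
    autocorr_cut: float = 0.25
    min_shared: int = 30
    fdr_alpha: float = 0.05
    enrichment_p_cut: float = 0.008

    def __post_init__(self) -> None:
        for name in ("hub_min_degree", "autocorr_cut", "min_shared", "fdr_alpha", "enrichment_p_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ProfileCorrelation:
    gene_a: str
    gene_b: str
    r: float
    n_shared: int


def hypergeom_upper_tail(k: int, n: int, M: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(population N, successes M, draws n)."""
    if not (0 <= k <= min(n, M) and n <= N and M <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k}, n={n}, M={M}, N={N}")
    return float(hypergeom.sf(k - 1, N, M, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (empty in, empty out)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _edges_universe(network) -> tuple:
    """(significant edges df with sign, universe pairs df) for either
    a StaticNetwork or a DifferentialNetwork."""
    if isinstance(network, StaticNetwork):
        return network.significant_edges, network.all_scores[["donor", "recipient"]]
    return network.significant_edges, network.all_pairs[["donor", "recipient"]]


def _category_map(genes, categories) -> dict:
    if categories is not None:
        return {g: frozenset(c) for g, c in categories.items()}
    return {g.gene_id: frozenset(g.major_bioprocesses) for g in genes}


def process_crosstalk(
    network,
    genes=None,
    direction: str = "any",
    config: AnalysisConfig | None = None,
    categories: dict | None = None,
) -> pd.DataFrame:
    """Hypergeometric inter/intra-process GI enrichment with BH FDR.

    Tests every unordered category pair, including self-pairs (with c
    categories that is c*(c+1)/2 tests). ``direction`` restricts the
    significant edges to aggravating or alleviating calls; ``categories``
    overrides the gene -> label-set map (e.g., minor bioprocesses), default
    is the major bioprocesses of ``genes``.

    Returns a DataFrame with columns process_a, process_b, k, n, M, N, P, q.
    """
    config = config or AnalysisConfig()
    if direction not in ("any", AGGRAVATING, ALLEVIATING):
        raise ValueError(f"unknown direction {direction!r}")
    edges, universe = _edges_universe(network)
    if direction != "any":
        edges = edges[edges["sign"] == direction]
    cats = _category_map(genes or [], categories)

    net_genes = set(universe["donor"]) | set(universe["recipient"])
    missing = sorted(net_genes - set(cats))
    if missing:
        raise ValueError(f"unannotated genes in network: {missing[:10]}{'...' if len(missing) > 10 else ''}")

    def pair_counts(df: pd.DataFrame) -> dict:
        counts: dict = {}
        for d, r in df[["donor", "recipient"]].itertuples(index=False):
            seen = set()
            for pa in cats[d]:
                for pb in cats[r]:
                    key = (pa, pb) if pa <= pb else (pb, pa)
                    seen.add(key)
            for key in seen:
                counts[key] = counts.get(key, 0) + 1
        return counts

    n_by = pair_counts(universe)
    k_by = pair_counts(edges)
    M, N = len(edges), len(universe)
    all_labels = sorted({lab for s in cats.values() for lab in s})
    rows = []
    for pa, pb in combinations_with_replacement(all_labels, 2):
        n = n_by.get((pa, pb), 0)
        if n == 0:
            continue  # category pair never co-occurs in the universe
        k = k_by.get((pa, pb), 0)
        rows.append((pa, pb, k, n, M, N, hypergeom_upper_tail(min(k, min(n, M)), n, M, N)))
    out = pd.DataFrame(rows, columns=["process_a", "process_b", "k", "n", "M", "N", "P"])
    out["q"] = bh_fdr(out["P"]) if len(out) else []
    out["direction"] = direction
    return out


def module_crosstalk_permutation(
    network,
    module_assignment: dict,
    n_perm: int = 1000,
    z_cut: float = 1.65,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation Z-test for inter-module GI counts.

    Observed: significant GIs whose endpoints fall in two different modules,
    per unordered module pair. Null: gene -> module labels shuffled
    (module sizes preserved) ``n_perm`` times. Z = (obs - mean)/sd;
    significant iff Z >= z_cut; a degenerate permutation SD yields NaN Z
    with ``sd_zero`` flagged, never +/-inf.

    Columns: module_a, module_b, observed, perm_mean, perm_sd, Z,
    significant, sd_zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    edges, _ = _edges_universe(network)
    genes = sorted(module_assignment)
    sizes = pd.Series(module_assignment).value_counts()
    if (sizes < 2).any():
        raise ValueError("every module must contain at least 2 genes")
    gene_idx = {g: i for i, g in enumerate(genes)}
    modules = sorted(sizes.index)
    mod_idx = {m: i for i, m in enumerate(modules)}
    labels0 = np.array([mod_idx[module_assignment[g]] for g in genes])

    mask = edges["donor"].isin(gene_idx) & edges["recipient"].isin(gene_idx)
    u = edges.loc[mask, "donor"].map(gene_idx).to_numpy()
    v = edges.loc[mask, "recipient"].map(gene_idx).to_numpy()
    n_mod = len(modules)

    def pair_count_matrix(labels: np.ndarray) -> np.ndarray:
        a, b = labels[u], labels[v]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        mat = np.zeros((n_mod, n_mod))
        np.add.at(mat, (lo, hi), 1.0)
        return mat

    observed = pair_count_matrix(labels0)
    rng = np.random.default_rng(seed)
    perm_sum = np.zeros((n_mod, n_mod))
    perm_sq = np.zeros((n_mod, n_mod))
    for _ in range(n_perm):
        mat = pair_count_matrix(rng.permutation(labels0))
        perm_sum += mat
        perm_sq += mat**2
    mean = perm_sum / n_perm
    var = np.maximum(perm_sq / n_perm - mean**2, 0.0)
    sd = np.sqrt(var)

    rows = []
    for i in range(n_mod):
        for j in range(i + 1, n_mod):  # inter-module pairs only
            sd_zero = sd[i, j] == 0
            z = np.nan if sd_zero else (observed[i, j] - mean[i, j]) / sd[i, j]
            rows.append(
                (
                    modules[i],
                    modules[j],
                    int(observed[i, j]),
                    mean[i, j],
                    sd[i, j],
                    z,
                    bool(not sd_zero and z >= z_cut),
                    bool(sd_zero),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["module_a", "module_b", "observed", "perm_mean", "perm_sd", "Z", "significant", "sd_zero"],
    )


def _profile(scores: pd.DataFrame, gene: str) -> dict:
    """GI profile of a gene: partner -> score, pooling donor and recipient
    roles (averaged if a partner is scored in both)."""
    vals: dict = {}
    counts: dict = {}
    as_donor = scores[scores["donor"] == gene]
    for r, s in zip(as_donor["recipient"], as_donor["S"]):
        vals[r] = vals.get(r, 0.0) + s
        counts[r] = counts.get(r, 0) + 1
    as_recip = scores[scores["recipient"] == gene]
    for d, s in zip(as_recip["donor"], as_recip["S"]):
        vals[d] = vals.get(d, 0.0) + s
        counts[d] = counts.get(d, 0) + 1
    return {p: vals[p] / counts[p] for p in vals}


def _score_table(source) -> pd.DataFrame:
    if isinstance(source, StaticNetwork):
        df = source.all_scores[["donor", "recipient", "S_gp"]]
        return df.rename(columns={"S_gp": "S"})
    return source[["donor", "recipient", "S"]]


def profile_correlation(
    scores,
    gene_a: str,
    gene_b: str,
    min_shared: int = 30,
) -> ProfileCorrelation | None:
    """Pearson correlation of two genes' GI profiles over shared partners.

    Partners equal to either gene are excluded, as are missing scores.
    Returns None (with a log entry) when fewer than ``min_shared`` partners
    are co-scored.
    """
    tab = _score_table(scores)
    pa, pb = _profile(tab, gene_a), _profile(tab, gene_b)
    shared = sorted((set(pa) & set(pb)) - {gene_a, gene_b})
    x = np.array([pa[p] for p in shared])
    y = np.array([pb[p] for p in shared])
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < min_shared:
        logger.info("profile_correlation(%s, %s): only %d shared partners; suppressed", gene_a, gene_b, n)
        return None
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return ProfileCorrelation(gene_a, gene_b, r, n)


def autocorrelation(
    rm_scores,
    mm_scores,
    gene: str,
    config: AnalysisConfig | None = None,
) -> tuple:
    """Correlation of one gene's GI profile between RM and MM.

    Returns (ProfileCorrelation, class) with class "high" iff
    r >= autocorr_cut (boundary assigned to high), or (None, None) when
    too few shared partners.
    """
    config = config or AnalysisConfig()
    ta, tb = _score_table(rm_scores), _score_table(mm_scores)
    pa, pb = _profile(ta, gene), _profile(tb, gene)
    shared = sorted((set(pa) & set(pb)) - {gene})
    x = np.array([pa[p] for p in shared])
    y = np.array([pb[p] for p in shared])
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < config.min_shared:
        logger.info("autocorrelation(%s): only %d shared partners; suppressed", gene, n)
        return None, None
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    # boundary assigned to "high"; tolerance guards exact-threshold round-off
    cls = "high" if r >= config.autocorr_cut - 1e-9 else "low"
    return ProfileCorrelation(f"{gene}:RM", f"{gene}:MM", r, n), cls


def degree_stats(
    network,
    genes,
    config: AnalysisConfig | None = None,
) -> tuple:
    """Per-gene degree / sign-ratio / hub table plus class summaries.

    Returns (per_gene, summaries): per_gene has columns gene, degree,
    n_aggravating, n_alleviating, agg_allev_ratio (NaN when the gene has no
    alleviating GIs), hub, regulator_scope, is_orphan. ``summaries`` counts
    edges by endpoint class: local-local vs local-global vs global-global
    and orphan-annotated vs other.
    """
    config = config or AnalysisConfig()
    edges, universe = _edges_universe(network)
    meta = {g.gene_id: g for g in genes}
    net_genes = sorted(set(universe["donor"]) | set(universe["recipient"]))

    deg = {g: 0 for g in net_genes}
    agg = {g: 0 for g in net_genes}
    alv = {g: 0 for g in net_genes}
    scope_pair = {"local-local": 0, "global-local": 0, "global-global": 0}
    orphan_pair = {"orphan-annotated": 0, "other": 0}
    for d, r, sign in edges[["donor", "recipient", "sign"]].itertuples(index=False):
        for g in (d, r):
            deg[g] += 1
            if sign == AGGRAVATING:
                agg[g] += 1
            elif sign == ALLEVIATING:
                alv[g] += 1
        if d in meta and r in meta:
            scopes = sorted((meta[d].regulator_scope, meta[r].regulator_scope))
            scope_pair["-".join(scopes)] += 1
            if meta[d].is_orphan != meta[r].is_orphan:
                orphan_pair["orphan-annotated"] += 1
            else:
                orphan_pair["other"] += 1

    per_gene = pd.DataFrame(
        {
            "gene": net_genes,
            "degree": [deg[g] for g in net_genes],
            "n_aggravating": [agg[g] for g in net_genes],
            "n_alleviating": [alv[g] for g in net_genes],
        }
    )
    per_gene["agg_allev_ratio"] = np.where(
        per_gene["n_alleviating"] > 0,
        per_gene["n_aggravating"] / np.maximum(per_gene["n_alleviating"], 1),
        np.nan,
    )
    per_gene["hub"] = per_gene["degree"] >= config.hub_min_degree
    per_gene["regulator_scope"] = [getattr(meta.get(g), "regulator_scope", None) for g in net_genes]
    per_gene["is_orphan"] = [getattr(meta.get(g), "is_orphan", None) for g in net_genes]
    summaries = {"scope_pairs": scope_pair, "orphan_pairs": orphan_pair}
    return per_gene, summaries
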
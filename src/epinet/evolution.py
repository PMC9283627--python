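"""Phylogenetic co-conservation and paralogy of interacting gene pairs.

A phylogenetic profile is a binary ortholog presence/absence vector over a
panel of bacterial phyla (default 17). A GI pair counts as evolutionarily
co-conserved only when both genes are present in every phylum of the panel.
Paralogs are detected from tabulated pairwise alignment statistics by the
coverage / E-value / identity filter (>= 50% alignment coverage,
E <= 5e-2, >= 30% identity, all inclusive, satisfied in at least one
direction). Orthology retrieval and the alignments themselves are upstream;
this module consumes tables only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .scoring import AGGRAVATING
from .stats import _edges_universe

logger = logging.getLogger(__name__)

COVERAGE_MIN = 0.5
EVALUE_MAX = 5e-2
IDENTITY_MIN = 0.30


def co_conserved(pair, profiles: pd.DataFrame) -> bool:
    """True iff both genes are present in all phyla of the panel."""
    a, b = pair
    for g in (a, b):
        if g not in profiles.index:
            raise KeyError(f"no phylogenetic profile for gene {g!r}")
    sub = profiles.loc[[a, b]]
    return bool((sub.to_numpy() == 1).all())


def conservation_enrichment(
    network,
    profiles: pd.DataFrame,
    annotations,
    n_perm: int = 1000,
    z_cut: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation Z for co-conserved significant GIs per process pair.

    Observed: count of co-conserved significant GIs between each unordered
    bioprocess pair (fuzzy membership, pair counted once per instantiated
    process pair). Null: profile rows shuffled across genes ``n_perm``
    times. Z = (obs - mean)/sd; degenerate SD gives NaN Z with ``sd_zero``
    set.

    Columns: process_a, process_b, observed, perm_mean, perm_sd, Z,
    significant, sd_zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    edges, _ = _edges_universe(network)
    cats = {g.gene_id: frozenset(g.major_bioprocesses) for g in annotations}
    gene_list = list(profiles.index)
    gene_pos = {g: i for i, g in enumerate(gene_list)}
    allones = (profiles.to_numpy() == 1).all(axis=1)

    pairs = []
    for d, r in edges[["donor", "recipient"]].itertuples(index=False):
        if d in gene_pos and r in gene_pos and d in cats and r in cats:
            keys = set()
            for pa in cats[d]:
                for pb in cats[r]:
                    keys.add((pa, pb) if pa <= pb else (pb, pa))
            pairs.append((gene_pos[d], gene_pos[r], keys))
    all_keys = sorted({k for _, _, ks in pairs for k in ks})
    key_idx = {k: i for i, k in enumerate(all_keys)}

    def counts(presence: np.ndarray) -> np.ndarray:
        c = np.zeros(len(all_keys))
        for i, j, ks in pairs:
            if presence[i] and presence[j]:
                for k in ks:
                    c[key_idx[k]] += 1
        return c

    observed = counts(allones)
    rng = np.random.default_rng(seed)
    tot = np.zeros(len(all_keys))
    tot2 = np.zeros(len(all_keys))
    for _ in range(n_perm):
        c = counts(allones[rng.permutation(len(gene_list))])
        tot += c
        tot2 += c**2
    mean = tot / n_perm
    sd = np.sqrt(np.maximum(tot2 / n_perm - mean**2, 0.0))
    sd_zero = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd_zero, np.nan, (observed - mean) / np.where(sd_zero, 1.0, sd))
    return pd.DataFrame(
        {
            "process_a": [k[0] for k in all_keys],
            "process_b": [k[1] for k in all_keys],
            "observed": observed.astype(int),
            "perm_mean": mean,
            "perm_sd": sd,
            "Z": z,
            "significant": ~sd_zero & (z >= z_cut),
            "sd_zero": sd_zero,
        }
    )


def paralog_filter(hits) -> list:
    """Unordered paralog pairs passing the alignment criteria.

    A pair is retained iff some hit in either direction has
    coverage >= 0.5, E-value <= 5e-2 and identity >= 0.30 (inclusive).
    Output deduplicated and sorted lexicographically.
    """
    kept = set()
    for h in hits:
        if h.coverage >= COVERAGE_MIN and h.e_value <= EVALUE_MAX and h.identity >= IDENTITY_MIN:
            kept.add(tuple(sorted((h.query_id, h.subject_id))))
    return sorted(kept)


def paralog_gi_bias(
    network,
    paralog_pairs,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Aggravating-GI enrichment among paralog pairs vs random singletons.

    Observed: fraction of scorable paralog pairs whose call is aggravating.
    Null: equal-sized sets of non-paralog scorable pairs sampled ``n_perm``
    times. Returns observed fraction, permutation mean/sd, Z, and the
    add-one-smoothed empirical P of seeing an equal-or-larger fraction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    edges, universe = _edges_universe(network)
    sign_of = {
        (d, r): s for d, r, s in edges[["donor", "recipient", "sign"]].itertuples(index=False)
    }
    uni_pairs = list(map(tuple, universe[["donor", "recipient"]].to_numpy()))
    uni_set = set(uni_pairs)

    para = set()
    for a, b in paralog_pairs:
        if (a, b) in uni_set:
            para.add((a, b))
        elif (b, a) in uni_set:
            para.add((b, a))
    if not para:
        raise ValueError("no scorable paralog pair in the network universe")

    def agg_fraction(pairs) -> float:
        return float(np.mean([sign_of.get(p) == AGGRAVATING for p in pairs]))

    observed = agg_fraction(para)
    others = [p for p in uni_pairs if p not in para]
    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(others), size=len(para), replace=False)
        draws[i] = agg_fraction([others[j] for j in pick])
    mean, sd = float(draws.mean()), float(draws.std())
    z = np.nan if sd == 0 else (observed - mean) / sd
    p = (1.0 + float((draws >= observed).sum())) / (n_perm + 1.0)
    return {
        "observed_fraction": observed,
        "n_paralog_pairs": len(para),
        "perm_mean": mean,
        "perm_sd": sd,
        "Z": z,
        "P": p,
    }
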
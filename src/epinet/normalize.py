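"""Plate normalization, linkage filtering, and single-mutant fitness.

Colony screens carry systematic experimental variation: whole-plate scale
differences (pinning pressure, agar batch) and within-plate row/column and
edge gradients. Normalization rescales every plate to a common median and
optionally removes row/column trends by median polish on the log scale.

Gene pairs whose loci sit close together on the circular chromosome
recombine at low frequency during conjugation, so their apparent double
mutants are unreliable; such linked pairs (default within 30 kbp) are
dropped before scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen import ColonyScreen, GeneRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationConfig:
    reference_statistic: str = "plate_median"
    correct_row_col: bool = True
    linkage_window: int = 30_000
    min_replicates: int = 4
    missing_policy: str = "drop_pair"  # drop_pair | impute_median

    def __post_init__(self) -> None:
        if self.linkage_window < 0:
            raise ValueError("linkage_window must be >= 0")
        if self.min_replicates < 2:
            raise ValueError("min_replicates must be >= 2")
        if self.reference_statistic != "plate_median":
            raise ValueError(f"unknown reference_statistic {self.reference_statistic!r}")
        if self.missing_policy not in ("drop_pair", "impute_median"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass
class FitnessTable:
    """Single-mutant relative fitness per gene in one condition.

    W_d (donors) and W_r (recipients) are medians of a gene's colony sizes
    over all partners and replicates, divided by the condition-wide median
    colony size (``reference_size``). Genes with too few non-missing
    observations are listed in ``excluded`` and carry no W.
    """

    condition: str
    donor_fitness: pd.Series
    recipient_fitness: pd.Series
    reference_size: float
    excluded: set = field(default_factory=set)

    def w(self, gene_id: str) -> float:
        if gene_id in self.donor_fitness.index:
            return float(self.donor_fitness[gene_id])
        return float(self.recipient_fitness[gene_id])


def _median_polish_log(plate: np.ndarray, tol: float = 1e-13, max_iter: int = 2000) -> np.ndarray:
    """Remove row/column effects from one plate by median polish on logs.

    Zeros and NaNs are left untouched. The plate's overall log-median is
    preserved so polishing never changes the plate's scale.
    """
    out = plate.copy()
    mask = np.isfinite(plate) & (plate > 0)
    if mask.sum() < 4:
        return out
    z = np.where(mask, np.log(np.where(mask, plate, 1.0)), np.nan)
    before = np.nanmedian(z)
    for _ in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rm = np.nanmedian(z, axis=1, keepdims=True)
            rm = np.where(np.isfinite(rm), rm, 0.0)
            z = z - rm
            cm = np.nanmedian(z, axis=0, keepdims=True)
            cm = np.where(np.isfinite(cm), cm, 0.0)
            z = z - cm
        if max(np.abs(rm).max(initial=0.0), np.abs(cm).max(initial=0.0)) < tol:
            break
    z = z - np.nanmedian(z) + before
    out[mask] = np.exp(z[mask])
    return out


def normalize_screen(screen: ColonyScreen, config: NormalizationConfig | None = None) -> ColonyScreen:
    """Rescale plates to a common median, optionally removing row/col trends.

    Each plate is multiplied by a factor making its median non-missing
    colony size equal to the condition-wide median of plate medians; with
    ``correct_row_col`` a median polish on log sizes removes within-plate
    row and column gradients first. Missing entries are preserved and output
    sizes stay >= 0. Idempotent up to numerical tolerance.
    """
    config = config or NormalizationConfig()
    out = screen.copy()
    flat = out.colonies.reshape(-1)
    plate_of = out.plate_assign[..., 0].reshape(-1)
    rows = out.plate_assign[..., 1].reshape(-1)
    cols = out.plate_assign[..., 2].reshape(-1)
    n_plates = int(plate_of.max()) + 1
    pr, pc = out.plate_shape

    if config.correct_row_col:
        for p in range(n_plates):
            sel = np.where(plate_of == p)[0]
            grid = np.full((pr, pc), np.nan)
            grid[rows[sel], cols[sel]] = flat[sel]
            polished = _median_polish_log(grid)
            flat[sel] = polished[rows[sel], cols[sel]]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        plate_medians = np.array(
            [np.nanmedian(flat[plate_of == p]) for p in range(n_plates)]
        )
    usable = np.isfinite(plate_medians) & (plate_medians > 0)
    if not usable.any():
        logger.warning("%s: no plate has a positive median; screen left unscaled", screen.condition)
        out.colonies = flat.reshape(out.colonies.shape)
        return out
    target = float(np.median(plate_medians[usable]))
    for p in range(n_plates):
        if not usable[p]:
            logger.warning("plate %d has no usable colonies; left unscaled", p)
            continue
        sel = plate_of == p
        flat[sel] = flat[sel] * (target / plate_medians[p])
    out.colonies = np.maximum(flat.reshape(out.colonies.shape), 0.0)
    out.colonies[~np.isfinite(out.colonies)] = np.nan
    return out


def circular_distance(a: int, b: int, genome_length: int) -> int:
    """Shortest arc between two loci on a circular chromosome."""
    d = abs(int(a) - int(b)) % genome_length
    return min(d, genome_length - d)


def filter_linked_pairs(
    pairs: list,
    genes: list,
    window: int = 30_000,
    genome_length: int = 4_600_000,
) -> list:
    """Drop gene pairs within ``window`` bp on the circular chromosome.

    Pairs at circular distance <= window (inclusive, reading "within" as a
    closed bound) are removed; the rest are returned in input order.
    """
    loci = {g.gene_id: g.locus_position for g in genes}
    kept = []
    for d, r in pairs:
        try:
            pd_, pr_ = loci[d], loci[r]
        except KeyError as exc:
            raise KeyError(f"unknown gene id {exc.args[0]!r} in pair ({d}, {r})") from None
        if circular_distance(pd_, pr_, genome_length) > window:
            kept.append((d, r))
    return kept


def estimate_fitness(
    screen: ColonyScreen,
    min_replicates: int = 4,
) -> FitnessTable:
    """Marginal single-mutant fitness from a normalized screen.

    W_d = median over recipients and replicates of the donor's colonies
    divided by the condition-wide median colony size; W_r analogous over
    donors. Medians ignore missing values; genes with fewer than
    ``min_replicates`` non-missing observations are excluded and flagged.
    """
    col = screen.colonies
    reference = float(np.nanmedian(col))
    if not np.isfinite(reference) or reference <= 0:
        raise ValueError("screen has no positive colony sizes; cannot set reference")
    excluded: set = set()

    def marginal(axis_ids: list, take) -> pd.Series:
        vals = {}
        for i, g in enumerate(axis_ids):
            obs = take(i)
            n = np.isfinite(obs).sum()
            if n < min_replicates:
                excluded.add(g)
                logger.warning("%s: only %d observations; excluded from fitness", g, n)
                continue
            vals[g] = np.nanmedian(obs) / reference
        return pd.Series(vals, dtype=float)

    wd = marginal(screen.donors, lambda i: col[i, :, :])
    wr = marginal(screen.recipients, lambda i: col[:, i, :])
    return FitnessTable(screen.condition, wd, wr, reference, excluded)
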
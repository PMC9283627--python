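"""Synthetic eSGA screen generator with planted ground truth.

Emulates a conjugation-based double-mutant colony screen of bacterial
transcription-factor genes run in two growth conditions (rich medium, RM,
and minimal medium, MM): per-condition donor x recipient x replicate colony
size arrays with plate structure, planted aggravating/alleviating epistasis
with condition-specific rewiring, plate row/column/edge artifacts, gene
annotations (fuzzy bioprocess membership, orphan and global-regulator flags,
circular genomic coordinates), phylum-level ortholog presence profiles and
pairwise alignment hits for paralogy.

Every generator derives its random stream from the root seed through a fixed
integer label, so adding a generator never perturbs existing outputs and the
same (config, seed) is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CONDITIONS = ("RM", "MM")

MAJOR_BIOPROCESSES = (
    "metabolism",
    "transport",
    "stress_response",
    "envelope_biogenesis",
    "cell_division_shape",
    "flagellar_motility",
    "dna_replication_repair",
    "translation",
    "transcription_core",
    "signal_transduction",
    "nucleoid_structure",
    "antibiotic_resistance",
    "unknown_function",
)

MINOR_BIOPROCESSES = tuple(f"minor_{i:02d}" for i in range(1, 42))

TF_FAMILIES = ("LysR", "TetR/AcrR", "OmpR", "AraC", "GntR", "HTH", "LuxR", "MarR")

# fixed labels for child RNG streams (never renumber)
_STREAM_FITNESS = 1
_STREAM_PLANT = 2
_STREAM_NOISE_RM = 3
_STREAM_NOISE_MM = 4
_STREAM_PLATE_RM = 5
_STREAM_PLATE_MM = 6
_STREAM_MISSING_RM = 7
_STREAM_MISSING_MM = 8
_STREAM_ANNOT = 9
_STREAM_PHYLO = 10
_STREAM_ALIGN = 11
_STREAM_LAYOUT = 12


def _rng(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(label,)))


class ConfigurationError(ValueError):
    """Invalid screen configuration."""


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of one synthetic two-condition screen.

    Sizes default to the scale of the TF screen this emulates (278 donor
    query mutants crossed into ~300 arrayed recipients, eight replicate
    colonies per pair on 1536-format plates). ``effect_size`` is expressed in
    units of the replicate noise SD and is applied to the expected
    double-mutant colony size: negative for aggravating pairs (double mutant
    worse than the multiplicative expectation), positive for alleviating.
    """

    n_donors: int = 278
    n_recipients: int = 300
    n_replicates: int = 8
    genome_length: int = 4_600_000
    plate_rows: int = 32
    plate_cols: int = 48
    baseline_colony_size: float = 100.0
    fitness_mean: float = 0.95
    fitness_sd: float = 0.08
    fitness_low: float = 0.4
    fitness_high: float = 1.2
    planted_fraction_aggravating: float = 0.05
    planted_fraction_alleviating: float = 0.05
    effect_size: float = 6.0
    rewired_fraction: float = 0.3
    noise_sd: float = 6.0
    row_effect_sd: float = 1.5
    col_effect_sd: float = 1.5
    edge_effect: float = 2.0
    missing_fraction: float = 0.0
    linkage_window: int = 30_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_donors, self.n_recipients, self.plate_rows, self.plate_cols) <= 0:
            raise ConfigurationError("screen dimensions must be positive")
        if self.n_replicates < 2:
            raise ConfigurationError("need at least 2 replicate colonies per pair")
        if self.planted_fraction_aggravating + self.planted_fraction_alleviating > 0.4:
            raise ConfigurationError("planted fractions must sum to <= 0.4")
        for name in ("noise_sd", "row_effect_sd", "col_effect_sd", "edge_effect"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.rewired_fraction <= 1.0:
            raise ConfigurationError("rewired_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigurationError("missing_fraction must lie in [0, 1)")
        if self.baseline_colony_size <= 0:
            raise ConfigurationError("baseline_colony_size must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 < self.fitness_low < self.fitness_high <= 1.2:
            raise ConfigurationError("fitness bounds must satisfy 0 < low < high <= 1.2")

    def with_seed(self, seed: int) -> "ScreenConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class GeneRecord:
    """One transcription-factor gene and its annotations."""

    gene_id: str
    locus_position: int
    is_orphan: bool
    regulator_scope: str  # "global" | "local"
    is_essential_hypomorph: bool
    major_bioprocesses: frozenset
    minor_bioprocess: str | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.major_bioprocesses:
            raise ValueError(f"{self.gene_id}: major_bioprocesses must be non-empty")
        if self.regulator_scope not in ("global", "local"):
            raise ValueError(f"{self.gene_id}: bad regulator_scope {self.regulator_scope!r}")
        if self.locus_position < 0:
            raise ValueError(f"{self.gene_id}: negative locus_position")


@dataclass(frozen=True)
class PlantedInteraction:
    donor_id: str
    recipient_id: str
    condition: str  # RM | MM
    sign: str  # aggravating | alleviating
    effect_size: float  # in replicate-noise SD units, signed magnitude as configured


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated screen."""

    planted_interactions: list  # of PlantedInteraction
    rewired_pairs: set  # of (donor_id, recipient_id) present in exactly one condition
    single_mutant_fitness: dict  # condition -> {gene_id: W}

    def planted_pairs(self, condition: str | None = None, sign: str | None = None) -> set:
        return {
            (p.donor_id, p.recipient_id)
            for p in self.planted_interactions
            if (condition is None or p.condition == condition)
            and (sign is None or p.sign == sign)
        }

    def stable_pairs(self) -> set:
        """Planted pairs present in both conditions."""
        return self.planted_pairs("RM") & self.planted_pairs("MM")


@dataclass
class ColonyScreen:
    """Colony sizes of one condition, indexed (donor, recipient, replicate).

    Missing colonies are NaN. ``plate_assign`` maps every position to
    (plate_id, row, col) on the pinning grid.
    """

    condition: str
    colonies: np.ndarray  # float, shape (n_donors, n_recipients, n_replicates)
    donors: list
    recipients: list
    plate_assign: np.ndarray  # int, shape (n_donors, n_recipients, n_replicates, 3)
    plate_shape: tuple  # (rows, cols)

    @property
    def n_plates(self) -> int:
        return int(self.plate_assign[..., 0].max()) + 1

    def copy(self) -> "ColonyScreen":
        return ColonyScreen(
            self.condition,
            self.colonies.copy(),
            list(self.donors),
            list(self.recipients),
            self.plate_assign,
            self.plate_shape,
        )


def donor_ids(n: int) -> list:
    return [f"d{i:04d}" for i in range(n)]


def recipient_ids(n: int) -> list:
    return [f"r{i:04d}" for i in range(n)]


def _draw_fitness(rng: np.random.Generator, n: int, cfg: ScreenConfig) -> np.ndarray:
    """Truncated-normal single-mutant relative fitness W in (low, high]."""
    w = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(cfg.fitness_mean, cfg.fitness_sd, todo.size)
        ok = (draw > cfg.fitness_low) & (draw <= cfg.fitness_high)
        w[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return w


def _plate_assignment(cfg: ScreenConfig) -> np.ndarray:
    """Replicate pinnings go to separate plate sets, as in arrayed screens.

    Each replicate pinning scatters the pairs over its plates in a seeded
    random order, so plate rows/columns are never confounded with donor or
    recipient identity and plate artifacts are independent across a pair's
    replicates.
    """
    n_pairs = cfg.n_donors * cfg.n_recipients
    per_plate = cfg.plate_rows * cfg.plate_cols
    n_plates_per_rep = -(-n_pairs // per_plate)
    rng = _rng(cfg.seed, _STREAM_LAYOUT)
    out = np.empty((n_pairs, cfg.n_replicates, 3), dtype=np.int64)
    for k in range(cfg.n_replicates):
        slot = np.empty(n_pairs, dtype=np.int64)
        slot[rng.permutation(n_pairs)] = np.arange(n_pairs)
        out[:, k, 0] = k * n_plates_per_rep + slot // per_plate
        pos = slot % per_plate
        out[:, k, 1] = pos // cfg.plate_cols
        out[:, k, 2] = pos % cfg.plate_cols
    return out.reshape(cfg.n_donors, cfg.n_recipients, cfg.n_replicates, 3)


def _plate_effects(cfg: ScreenConfig, assign: np.ndarray, stream: int) -> np.ndarray:
    """Additive per-row / per-column offsets plus a border bonus."""
    rng = _rng(cfg.seed, stream)
    n_plates = int(assign[..., 0].max()) + 1
    row_off = rng.normal(0.0, cfg.row_effect_sd, (n_plates, cfg.plate_rows))
    col_off = rng.normal(0.0, cfg.col_effect_sd, (n_plates, cfg.plate_cols))
    plate, row, col = assign[..., 0], assign[..., 1], assign[..., 2]
    eff = row_off[plate, row] + col_off[plate, col]
    border = (
        (row == 0)
        | (row == cfg.plate_rows - 1)
        | (col == 0)
        | (col == cfg.plate_cols - 1)
    )
    return eff + cfg.edge_effect * border


def _plant_interactions(cfg: ScreenConfig, donors: list, recipients: list) -> tuple:
    """Choose planted pairs, signs, and which are rewired (single-condition)."""
    rng = _rng(cfg.seed, _STREAM_PLANT)
    n_pairs = cfg.n_donors * cfg.n_recipients
    n_agg = int(round(cfg.planted_fraction_aggravating * n_pairs))
    n_all = int(round(cfg.planted_fraction_alleviating * n_pairs))
    chosen = rng.choice(n_pairs, size=n_agg + n_all, replace=False)
    signs = ["aggravating"] * n_agg + ["alleviating"] * n_all

    n_planted = n_agg + n_all
    n_rewired = int(round(cfg.rewired_fraction * n_planted))
    rewired_idx = set(rng.choice(n_planted, size=n_rewired, replace=False).tolist()) if n_rewired else set()
    rewired_cond = rng.integers(0, 2, size=n_planted)  # 0 -> RM only, 1 -> MM only

    planted: list = []
    rewired_pairs: set = set()
    for j, (flat, sign) in enumerate(zip(chosen, signs)):
        d, r = donors[flat // cfg.n_recipients], recipients[flat % cfg.n_recipients]
        magnitude = cfg.effect_size if sign == "alleviating" else -cfg.effect_size
        if j in rewired_idx:
            cond = CONDITIONS[rewired_cond[j]]
            planted.append(PlantedInteraction(d, r, cond, sign, magnitude))
            rewired_pairs.add((d, r))
        else:
            for cond in CONDITIONS:
                planted.append(PlantedInteraction(d, r, cond, sign, magnitude))
    return planted, rewired_pairs


def generate_screen(config: ScreenConfig) -> tuple:
    """Generate (RM screen, MM screen, truth) for one synthetic experiment.

    The expected colony size of pair (d, r) is ``baseline * W_d * W_r``; a
    planted pair in a given condition shifts that expectation by
    ``effect_size * noise_sd`` (negative for aggravating). Plate row/column
    and edge artifacts are added, then i.i.d. Gaussian replicate noise,
    truncated at zero. Identical (config, seed) yields bit-identical output.
    """
    cfg = config
    donors = donor_ids(cfg.n_donors)
    recipients = recipient_ids(cfg.n_recipients)

    fit_rng = _rng(cfg.seed, _STREAM_FITNESS)
    fitness: dict = {}
    for cond in CONDITIONS:
        wd = _draw_fitness(fit_rng, cfg.n_donors, cfg)
        wr = _draw_fitness(fit_rng, cfg.n_recipients, cfg)
        fitness[cond] = dict(zip(donors + recipients, np.concatenate([wd, wr])))

    planted, rewired = _plant_interactions(cfg, donors, recipients)
    truth = SyntheticTruth(planted, rewired, fitness)

    d_index = {g: i for i, g in enumerate(donors)}
    r_index = {g: i for i, g in enumerate(recipients)}
    assign = _plate_assignment(cfg)

    screens = []
    for cond, noise_stream, plate_stream, miss_stream in (
        ("RM", _STREAM_NOISE_RM, _STREAM_PLATE_RM, _STREAM_MISSING_RM),
        ("MM", _STREAM_NOISE_MM, _STREAM_PLATE_MM, _STREAM_MISSING_MM),
    ):
        wd = np.array([fitness[cond][g] for g in donors])
        wr = np.array([fitness[cond][g] for g in recipients])
        expect = cfg.baseline_colony_size * np.outer(wd, wr)
        for p in planted:
            if p.condition == cond:
                expect[d_index[p.donor_id], r_index[p.recipient_id]] += p.effect_size * cfg.noise_sd
        sizes = expect[:, :, None] + _plate_effects(cfg, assign, plate_stream)
        noise = _rng(cfg.seed, noise_stream).normal(0.0, cfg.noise_sd, sizes.shape)
        sizes = np.maximum(sizes + noise, 0.0)
        if cfg.missing_fraction > 0:
            miss = _rng(cfg.seed, miss_stream).random(sizes.shape) < cfg.missing_fraction
            sizes[miss] = np.nan
        screens.append(
            ColonyScreen(cond, sizes, donors, recipients, assign, (cfg.plate_rows, cfg.plate_cols))
        )
    return screens[0], screens[1], truth


def generate_annotations(
    config: ScreenConfig,
    orphan_fraction: float = 72 / 304,
    global_fraction: float = 14 / 304,
    hypomorph_fraction: float = 7 / 304,
) -> list:
    """Annotate every donor and recipient gene of a screen.

    Orphan / global-regulator / hypomorph flags are assigned by deterministic
    quota (``round(fraction * n_genes)`` genes chosen by a seeded
    permutation), so the marginal counts are exact, matching how a curated
    gene list fixes its category sizes. Each gene draws a uniform locus on
    the circular chromosome, 1-3 fuzzy major bioprocesses, one minor
    bioprocess and a TF family.
    """
    for name, frac in (("orphan", orphan_fraction), ("global", global_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError(f"{name}_fraction must lie in [0, 1]")
    genes = donor_ids(config.n_donors) + recipient_ids(config.n_recipients)
    n = len(genes)
    rng = _rng(config.seed, _STREAM_ANNOT)

    def quota_flags(fraction: float) -> np.ndarray:
        flags = np.zeros(n, dtype=bool)
        k = int(round(fraction * n))
        flags[rng.permutation(n)[:k]] = True
        return flags

    orphan = quota_flags(orphan_fraction)
    glob = quota_flags(global_fraction)
    hypo = quota_flags(hypomorph_fraction)
    loci = rng.integers(0, config.genome_length, size=n)
    records = []
    for i, g in enumerate(genes):
        k_major = int(rng.integers(1, 4))
        majors = frozenset(rng.choice(MAJOR_BIOPROCESSES, size=k_major, replace=False).tolist())
        records.append(
            GeneRecord(
                gene_id=g,
                locus_position=int(loci[i]),
                is_orphan=bool(orphan[i]),
                regulator_scope="global" if glob[i] else "local",
                is_essential_hypomorph=bool(hypo[i]),
                major_bioprocesses=majors,
                minor_bioprocess=str(rng.choice(MINOR_BIOPROCESSES)),
                family=str(rng.choice(TF_FAMILIES)),
            )
        )
    return records


def generate_phylo_profiles(
    genes: list,
    n_phyla: int = 17,
    presence_prob: float = 0.5,
    coconservation_boost: float = 0.3,
    seed: int = 0,
    coconserved_pairs: list | None = None,
):
    """Binary ortholog-presence profiles over a panel of bacterial phyla.

    Each gene is present in a phylum with ``presence_prob``; genes named in
    ``coconserved_pairs`` are forced jointly present in all phyla with
    probability ``coconservation_boost`` per pair (else they share the first
    gene's profile), giving correlated vectors for planted co-conservation.

    Returns a pandas DataFrame indexed by gene_id with one 0/1 column per
    phylum.
    """
    import pandas as pd

    if n_phyla < 1:
        raise ConfigurationError("n_phyla must be >= 1")
    rng = _rng(seed, _STREAM_PHYLO)
    ids = [g.gene_id if isinstance(g, GeneRecord) else str(g) for g in genes]
    mat = (rng.random((len(ids), n_phyla)) < presence_prob).astype(np.int8)
    prof = pd.DataFrame(mat, index=ids, columns=[f"phylum_{i:02d}" for i in range(n_phyla)])
    for a, b in coconserved_pairs or []:
        if rng.random() < coconservation_boost:
            prof.loc[a] = 1
            prof.loc[b] = 1
        else:
            prof.loc[b] = prof.loc[a].to_numpy()
    return prof


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise protein alignment (BLASTP-style summary statistics)."""

    query_id: str
    subject_id: str
    coverage: float  # alignment length / query length, in [0, 1]
    e_value: float
    identity: float  # fraction identical positions, in [0, 1]

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValueError("self-hit: query_id == subject_id")
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


def generate_alignment_hits(
    genes: list,
    n_paralog_pairs: int,
    seed: int = 0,
    n_decoys: int | None = None,
) -> tuple:
    """Alignment hits with planted paralog pairs and failing decoys.

    Planted pairs satisfy all three paralogy criteria (coverage >= 0.5,
    E <= 5e-2, identity >= 0.30); each decoy fails at least one. Returns
    (hits, designated_paralog_pairs).
    """
    ids = [g.gene_id if isinstance(g, GeneRecord) else str(g) for g in genes]
    all_pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    if n_paralog_pairs > len(all_pairs):
        raise ConfigurationError("n_paralog_pairs exceeds the number of gene pairs")
    rng = _rng(seed, _STREAM_ALIGN)
    if n_decoys is None:
        n_decoys = n_paralog_pairs
    order = rng.permutation(len(all_pairs))
    paralogs = [all_pairs[i] for i in order[:n_paralog_pairs]]
    decoys = [all_pairs[i] for i in order[n_paralog_pairs : n_paralog_pairs + n_decoys]]

    hits = []
    for a, b in paralogs:
        hits.append(
            AlignmentHit(
                a,
                b,
                coverage=float(rng.uniform(0.5, 1.0)),
                e_value=float(10 ** rng.uniform(-30, np.log10(5e-2))),
                identity=float(rng.uniform(0.30, 0.95)),
            )
        )
    fail_modes = rng.integers(0, 3, size=len(decoys))
    for (a, b), mode in zip(decoys, fail_modes):
        cov = float(rng.uniform(0.5, 1.0))
        ev = float(10 ** rng.uniform(-30, np.log10(5e-2)))
        ident = float(rng.uniform(0.30, 0.95))
        if mode == 0:
            cov = float(rng.uniform(0.0, 0.49))
        elif mode == 1:
            ev = float(10 ** rng.uniform(np.log10(6e-2), 2))
        else:
            ident = float(rng.uniform(0.0, 0.29))
        hits.append(AlignmentHit(a, b, coverage=cov, e_value=ev, identity=ident))
    return hits, [tuple(sorted(p)) for p in paralogs]
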
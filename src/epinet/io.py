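"""Readers, writers, pipeline configuration and end-to-end orchestration.

All tables are tab-separated UTF-8 with '.' decimals and 'NA' for missing;
every file starts with '#'-prefixed header lines recording the package
version, the root seed and a hash of the configuration, so any output can
be traced to the run that produced it. ``run_pipeline`` chains
simulate -> normalize -> filter-linked -> score -> call -> differential ->
enrichment/permutation/profile/conservation stages and emits a manifest
with checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import (
    DifferentialNetwork,
    DifferentialThresholds,
    assign_differential_p,
    call_differential,
    classify_gain_loss,
    compute_differential,
    difference_null,
)
from .evolution import conservation_enrichment, paralog_filter, paralog_gi_bias
from .normalize import NormalizationConfig, estimate_fitness, filter_linked_pairs, normalize_screen
from .scoring import (
    GPConfig,
    ScoringThresholds,
    call_static_network,
    score_gaussian_process,
    score_multiplicative,
)
from .screen import (
    ColonyScreen,
    ScreenConfig,
    generate_alignment_hits,
    generate_annotations,
    generate_phylo_profiles,
    generate_screen,
)
from .stats import AnalysisConfig, autocorrelation, degree_stats, module_crosstalk_permutation, process_crosstalk

logger = logging.getLogger(__name__)

NA = "NA"


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


SCREEN_SCHEMA = {
    "donor": str,
    "recipient": str,
    "replicate": int,
    "plate": int,
    "row": int,
    "col": int,
    "size": float,
}
DIFFERENTIAL_SCHEMA = {
    "donor": str,
    "recipient": str,
    "S_RM": float,
    "S_MM": float,
    "S_DF": float,
    "P_DF": float,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs, with the root seed recorded in
    every output header."""

    screen: ScreenConfig = field(default_factory=ScreenConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    thresholds: ScoringThresholds = field(default_factory=ScoringThresholds)
    differential: DifferentialThresholds = field(default_factory=DifferentialThresholds)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    gp: GPConfig = field(default_factory=GPConfig)
    null_splits: int = 10
    n_perm: int = 200
    min_replicates: int = 4
    seed: int = 0
    log_level: str = "INFO"

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(self, seed=int(seed), screen=self.screen.with_seed(seed))

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file of nested key/value sections."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    sections = {
        "screen": ScreenConfig,
        "normalization": NormalizationConfig,
        "differential": DifferentialThresholds,
        "analysis": AnalysisConfig,
        "gp": GPConfig,
    }
    for key, cls in sections.items():
        if key in raw:
            kwargs[key] = cls(**raw[key])
    for key in ("null_splits", "n_perm", "min_replicates", "seed", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


def _header(seed: int, config_hash: str) -> str:
    return (
        f"# epinet v{__version__}\n"
        f"# seed={seed} config={config_hash}\n"
        "# sep=tab decimal=. missing=NA\n"
    )


def write_table(df: pd.DataFrame, path, seed: int = 0, config_hash: str = "-") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, config_hash))
        df.to_csv(fh, sep="\t", index=False, na_rep=NA)
    return path


def read_edge_list(path, schema: dict) -> tuple:
    """Read a '#'-headed TSV against a column schema.

    Header matching is case-insensitive and order-free; extra columns are
    kept. Rows whose numeric fields fail to parse are dropped and reported
    by line; returns (DataFrame, list of (line_number, message)).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, na_values=[NA], keep_default_na=True)
    rename = {c: c.strip() for c in df.columns}
    lower = {c.strip().lower(): c for c in df.columns}
    for col in schema:
        if col.lower() not in lower:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
        rename[lower[col.lower()]] = col
    df = df.rename(columns=rename)

    # line numbers: count header/comment lines before the column header
    n_comment = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    first_data_line = n_comment + 2  # 1-based, after the column header

    errors = []
    bad = np.zeros(len(df), dtype=bool)
    for col, typ in schema.items():
        if typ in (float, int):
            coerced = pd.to_numeric(df[col], errors="coerce")
            newly_bad = coerced.isna() & df[col].notna()
            for i in np.where(newly_bad)[0]:
                errors.append((first_data_line + int(i), f"unparseable {col}={df[col].iat[i]!r}"))
            bad |= newly_bad.to_numpy()
            df[col] = coerced
    if errors:
        logger.warning("%s: rejected %d malformed rows", path.name, int(bad.sum()))
    out = df[~bad].reset_index(drop=True)
    for col, typ in schema.items():
        if typ is int:
            out[col] = out[col].astype(np.int64)
    return out, errors


def screen_to_frame(screen: ColonyScreen) -> pd.DataFrame:
    nd, nr, nrep = screen.colonies.shape
    di, ri, ki = np.meshgrid(np.arange(nd), np.arange(nr), np.arange(nrep), indexing="ij")
    return pd.DataFrame(
        {
            "donor": np.asarray(screen.donors, dtype=object)[di.ravel()],
            "recipient": np.asarray(screen.recipients, dtype=object)[ri.ravel()],
            "replicate": ki.ravel(),
            "plate": screen.plate_assign[..., 0].ravel(),
            "row": screen.plate_assign[..., 1].ravel(),
            "col": screen.plate_assign[..., 2].ravel(),
            "size": screen.colonies.ravel(),
            "condition": screen.condition,
        }
    )


def frame_to_screen(df: pd.DataFrame, condition: str, plate_shape: tuple) -> ColonyScreen:
    donors = list(pd.unique(df["donor"]))
    recipients = list(pd.unique(df["recipient"]))
    nrep = int(df["replicate"].max()) + 1
    d_idx = {g: i for i, g in enumerate(donors)}
    r_idx = {g: i for i, g in enumerate(recipients)}
    colonies = np.full((len(donors), len(recipients), nrep), np.nan)
    assign = np.zeros((len(donors), len(recipients), nrep, 3), dtype=np.int64)
    di = df["donor"].map(d_idx).to_numpy()
    ri = df["recipient"].map(r_idx).to_numpy()
    ki = df["replicate"].to_numpy()
    colonies[di, ri, ki] = df["size"].to_numpy()
    assign[di, ri, ki, 0] = df["plate"].to_numpy()
    assign[di, ri, ki, 1] = df["row"].to_numpy()
    assign[di, ri, ki, 2] = df["col"].to_numpy()
    return ColonyScreen(condition, colonies, donors, recipients, assign, plate_shape)


def read_screen(path, condition: str, plate_shape: tuple) -> ColonyScreen:
    df, _ = read_edge_list(path, SCREEN_SCHEMA)
    return frame_to_screen(df, condition, plate_shape)


def genes_to_frame(genes) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "locus_position": [g.locus_position for g in genes],
            "is_orphan": [int(g.is_orphan) for g in genes],
            "regulator_scope": [g.regulator_scope for g in genes],
            "is_essential_hypomorph": [int(g.is_essential_hypomorph) for g in genes],
            "major_bioprocesses": [";".join(sorted(g.major_bioprocesses)) for g in genes],
            "minor_bioprocess": [g.minor_bioprocess or NA for g in genes],
            "family": [g.family or NA for g in genes],
        }
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _drop_linked(table: pd.DataFrame, kept: set) -> pd.DataFrame:
    mask = [
        (d, r) in kept for d, r in table[["donor", "recipient"]].itertuples(index=False)
    ]
    return table[mask].reset_index(drop=True)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the whole analysis on one synthetic screen; returns the manifest.

    Stage order: simulate, normalize, fitness, linkage filter, dual-model
    scoring, static network calling, differential scoring with split-half
    null, gain/loss clustering, process/module/conservation statistics,
    profile autocorrelation, hubs, paralog filter and bias. Any stage
    failure aborts with the stage name; outputs written so far are kept.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_test"
    probe.write_text("")
    probe.unlink()

    seed, chash = config.seed, config.config_hash()
    manifest = {"version": __version__, "seed": seed, "config_hash": chash, "outputs": {}}

    def emit(name: str, df: pd.DataFrame) -> None:
        p = write_table(df, out / name, seed, chash)
        manifest["outputs"][name] = _sha256(p)

    stage = "simulate"
    try:
        rm_raw, mm_raw, truth = generate_screen(config.screen)
        genes = generate_annotations(config.screen)
        emit("screen_RM_raw.tsv", screen_to_frame(rm_raw))
        emit("screen_MM_raw.tsv", screen_to_frame(mm_raw))
        emit("genes.tsv", genes_to_frame(genes))
        emit(
            "truth.tsv",
            pd.DataFrame(
                [
                    (p.donor_id, p.recipient_id, p.condition, p.sign, p.effect_size)
                    for p in truth.planted_interactions
                ],
                columns=["donor", "recipient", "condition", "sign", "effect_size"],
            ),
        )

        stage = "normalize"
        rm = normalize_screen(rm_raw, config.normalization)
        mm = normalize_screen(mm_raw, config.normalization)
        fit_rm = estimate_fitness(rm, config.normalization.min_replicates)
        fit_mm = estimate_fitness(mm, config.normalization.min_replicates)
        for fit in (fit_rm, fit_mm):
            emit(
                f"fitness_{fit.condition}.tsv",
                pd.DataFrame(
                    {
                        "gene_id": list(fit.donor_fitness.index) + list(fit.recipient_fitness.index),
                        "condition": fit.condition,
                        "W": list(fit.donor_fitness) + list(fit.recipient_fitness),
                    }
                ),
            )

        stage = "score"
        nets = {}
        tables = {}
        for screen, fit in ((rm, fit_rm), (mm, fit_mm)):
            mult = score_multiplicative(screen, fit, config.min_replicates)
            gp = score_gaussian_process(screen, fit, config.gp, config.min_replicates)
            tables[screen.condition] = (mult, gp)

        stage = "filter-linked"
        pairs = list(map(tuple, tables["RM"][0][["donor", "recipient"]].to_numpy()))
        kept = set(
            filter_linked_pairs(pairs, genes, config.normalization.linkage_window, config.screen.genome_length)
        )

        stage = "call"
        for cond, (mult, gp) in tables.items():
            net = call_static_network(
                _drop_linked(mult, kept), _drop_linked(gp, kept), config.thresholds
            )
            nets[cond] = net
            emit(f"scores_{cond}.tsv", net.all_scores)
            emit(f"edges_{cond}.tsv", net.significant_edges)

        stage = "differential"
        records = compute_differential(nets["RM"], nets["MM"])

        def half_scorer(screen: ColonyScreen) -> pd.DataFrame:
            fit = fit_rm if screen.condition == "RM" else fit_mm
            return score_gaussian_process(screen, fit, config.gp, min_replicates=2)

        null = difference_null(rm, mm, half_scorer, config.null_splits, seed)
        records = assign_differential_p(records, null)
        records = call_differential(records, config.differential)
        records = classify_gain_loss(records, nets["RM"], nets["MM"], config.differential)
        diff_net = DifferentialNetwork(records, config.differential)
        emit("differential.tsv", records)

        stage = "enrich"
        for direction in ("any", "aggravating", "alleviating"):
            emit(
                f"crosstalk_RM_{direction}.tsv",
                process_crosstalk(nets["RM"], genes, direction, config.analysis),
            )
        emit("crosstalk_differential_any.tsv", process_crosstalk(diff_net, genes, "any", config.analysis))

        stage = "permute-modules"
        modules = {g.gene_id: sorted(g.major_bioprocesses)[0] for g in genes}
        sizes = pd.Series(modules).value_counts()
        modules = {g: m for g, m in modules.items() if sizes[m] >= 2}
        emit(
            "module_permutation.tsv",
            module_crosstalk_permutation(diff_net, modules, config.n_perm, seed=seed),
        )

        stage = "profiles"
        rows = []
        for gene in nets["RM"].all_scores["donor"].unique():
            pc, cls = autocorrelation(nets["RM"], nets["MM"], gene, config.analysis)
            if pc is not None:
                rows.append((gene, pc.r, pc.n_shared, cls))
        emit("autocorrelation.tsv", pd.DataFrame(rows, columns=["gene", "r", "n_shared", "class"]))

        stage = "hubs"
        per_gene, _summ = degree_stats(diff_net, genes, config.analysis)
        emit("degree_stats.tsv", per_gene)

        stage = "conserve"
        profiles = generate_phylo_profiles(genes, seed=seed)
        emit("phylo_profiles.tsv", profiles.reset_index(names="gene_id"))
        emit(
            "conservation.tsv",
            conservation_enrichment(nets["RM"], profiles, genes, config.n_perm, seed=seed),
        )

        stage = "paralogs"
        n_para = min(50, len(genes) * (len(genes) - 1) // 2)
        hits, _designated = generate_alignment_hits(genes, n_para, seed=seed)
        para = paralog_filter(hits)
        emit("paralogs.tsv", pd.DataFrame(para, columns=["gene_a", "gene_b"]))
        try:
            bias = paralog_gi_bias(nets["RM"], para, config.n_perm, seed=seed)
            emit("paralog_bias.tsv", pd.DataFrame([bias]))
        except ValueError as exc:
            logger.warning("paralog bias skipped: %s", exc)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
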
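"""Static genetic-interaction scoring and network calling.

A genetic interaction (GI) is a deviation of a double mutant's fitness from
the neutral expectation combining its two single mutants. Under the
multiplicative model the expected colony size of pair (d, r) is

    E_dr = reference_size * W_d * W_r

and the S-score is a t-like statistic: the deviation of the replicate mean
from E_dr divided by its standard error, with a variance floor to stop
tiny-variance blowups. A Gaussian-process regression scored in parallel
captures smooth non-multiplicative trends in the marginal fitnesses; pairs
called non-neutral by BOTH models with the same sign (aggravating: S below
the lower cut; alleviating: S above the upper cut; |Z| >= 2, P <= 0.05) form
the static network, with the Gaussian-process score retained as the edge
weight.

Score tables are pandas DataFrames with columns
``donor, recipient, condition, S, n_obs`` (plus ``Z, P`` after
standardization); the per-row schema is the GI score record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .normalize import FitnessTable
from .screen import ColonyScreen

logger = logging.getLogger(__name__)

AGGRAVATING = "aggravating"
ALLEVIATING = "alleviating"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class ModelCuts:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < 0 < self.upper:
            raise ValueError("cuts must satisfy lower < 0 < upper")


@dataclass(frozen=True)
class ScoringThresholds:
    """Per-condition, per-model S cuts plus the two-SD significance rule.

    Defaults are the published cuts of the TF screen: multiplicative
    RM (-0.3, 1.8) and MM (-1.4, 3.0); Gaussian process RM (-0.9, 1.3) and
    MM (-2.3, 1.9); |Z| >= 2.0 with P <= 0.05. All comparisons inclusive.
    """

    mult: dict = field(
        default_factory=lambda: {"RM": ModelCuts(-0.3, 1.8), "MM": ModelCuts(-1.4, 3.0)}
    )
    gp: dict = field(
        default_factory=lambda: {"RM": ModelCuts(-0.9, 1.3), "MM": ModelCuts(-2.3, 1.9)}
    )
    z_cut: float = 2.0
    p_cut: float = 0.05

    def cuts(self, model: str, condition: str) -> ModelCuts:
        return getattr(self, model)[condition]


@dataclass(frozen=True)
class GPConfig:
    """Gaussian-process scorer settings (squared-exponential + white noise).

    ``max_fit_points`` caps the training set: larger screens are fitted on a
    fixed-seed subsample and predicted for all pairs. The observation noise
    is not a free hyperparameter: it is the pooled median of the per-pair
    replicate variances of the mean (s^2 / n), so the score denominator is
    identical in expectation across conditions and is never inflated by
    true interactions. ``noise_floor`` is a relative variance floor (times
    the response variance) that keeps the denominator positive on
    noise-free inputs. ``trim_sigma`` makes the mean fit robust: after a
    first fit, training points whose residuals exceed this many robust SDs
    (1.4826 * MAD) are dropped and the model refit, so strong interactions
    do not bend the fitted expectation surface. Set to 0 to disable.
    """

    max_fit_points: int = 400
    n_restarts: int = 0
    random_state: int = 0
    length_scale: float = 0.2
    noise_floor: float = 1e-6
    trim_sigma: float = 3.0


def _replicate_stats(screen: ColonyScreen) -> tuple:
    """Per-pair replicate count, mean and sample SD, NaN-aware."""
    col = screen.colonies
    finite = np.isfinite(col)
    n = finite.sum(axis=2)
    s = np.where(finite, col, 0.0).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s / n, np.nan)
        dev2 = np.where(finite, (col - mean[:, :, None]) ** 2, 0.0).sum(axis=2)
        sd = np.where(n > 1, np.sqrt(dev2 / np.maximum(n - 1, 1)), np.nan)
    return n, mean, sd


def _pair_frame(screen: ColonyScreen, fitness: FitnessTable, min_replicates: int):
    """Long-format scaffold of scorable pairs with W_d, W_r, mean, sd, n."""
    n, mean, sd = _replicate_stats(screen)
    wd = fitness.donor_fitness.reindex(screen.donors)
    wr = fitness.recipient_fitness.reindex(screen.recipients)
    di, ri = np.meshgrid(np.arange(len(screen.donors)), np.arange(len(screen.recipients)), indexing="ij")
    df = pd.DataFrame(
        {
            "donor": np.asarray(screen.donors, dtype=object)[di.ravel()],
            "recipient": np.asarray(screen.recipients, dtype=object)[ri.ravel()],
            "W_d": wd.to_numpy()[di.ravel()],
            "W_r": wr.to_numpy()[ri.ravel()],
            "n_obs": n.ravel(),
            "mean_obs": mean.ravel(),
            "sd_obs": sd.ravel(),
        }
    )
    ok = (df["n_obs"] >= min_replicates) & np.isfinite(df["W_d"]) & np.isfinite(df["W_r"])
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info(
            "%s: skipping %d pairs with < %d replicates or missing fitness",
            screen.condition,
            n_skip,
            min_replicates,
        )
    return df[ok].reset_index(drop=True)


def score_multiplicative(
    screen: ColonyScreen,
    fitness: FitnessTable,
    min_replicates: int = 4,
    variance_floor: float | str = "auto",
) -> pd.DataFrame:
    """Multiplicative-model S-score per pair.

    S = (mean observed - reference * W_d * W_r) / SE with
    SE = max(s, s_floor) / sqrt(n_obs); ``variance_floor="auto"`` sets
    s_floor to the 5th percentile of all replicate SDs, or pass a number.
    """
    df = _pair_frame(screen, fitness, min_replicates)
    if variance_floor == "auto":
        s_floor = float(np.nanpercentile(df["sd_obs"], 5)) if len(df) else 0.0
    else:
        s_floor = float(variance_floor)
    expected = fitness.reference_size * df["W_d"] * df["W_r"]
    se = np.maximum(df["sd_obs"], s_floor) / np.sqrt(df["n_obs"])
    df["S"] = (df["mean_obs"] - expected) / se
    df["condition"] = screen.condition
    return df[["donor", "recipient", "condition", "S", "n_obs"]]


def score_gaussian_process(
    screen: ColonyScreen,
    fitness: FitnessTable,
    gp_config: GPConfig | None = None,
    min_replicates: int = 4,
) -> pd.DataFrame:
    """Gaussian-process S-score per pair.

    Fits GP regression of the pair-mean colony size on (W_d, W_r) with a
    squared-exponential kernel (hyperparameters by marginal-likelihood
    optimization, fixed restarts/seed) and scores each pair as
    (observed mean - posterior mean) / posterior predictive SD, where the
    predictive variance is the smooth-function variance plus the pooled
    replicate noise of the pair mean. Degenerate predictors (all fitnesses
    identical) fall back to the multiplicative score with a warning.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

    cfg = gp_config or GPConfig()
    df = _pair_frame(screen, fitness, min_replicates)
    X = df[["W_d", "W_r"]].to_numpy()
    y = df["mean_obs"].to_numpy()
    if np.ptp(X, axis=0).max(initial=0.0) < 1e-12:
        logger.warning(
            "%s: degenerate predictors (all W identical); falling back to multiplicative scoring",
            screen.condition,
        )
        return score_multiplicative(screen, fitness, min_replicates).assign(model="multiplicative_fallback")

    # pooled noise of the pair mean: median of s^2/n, floored relative to var(y)
    with np.errstate(invalid="ignore"):
        per_pair_var = df["sd_obs"].to_numpy() ** 2 / df["n_obs"].to_numpy()
    noise_var = float(np.nanmedian(per_pair_var))
    noise_var = max(noise_var, cfg.noise_floor * float(np.var(y)))

    # y standardized by hand so the learned white-noise level has known units
    my, sy = float(np.mean(y)), max(float(np.std(y)), 1e-300)
    ys = (y - my) / sy
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF([cfg.length_scale] * 2, (1e-2, 1e1)) + WhiteKernel(
        0.1, (1e-10, 1e1)
    )

    def fit(idx: np.ndarray) -> GaussianProcessRegressor:
        gpr = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=False,
            n_restarts_optimizer=cfg.n_restarts,
            random_state=cfg.random_state,
        )
        gpr.fit(X[idx], ys[idx])
        return gpr

    if len(df) > cfg.max_fit_points:
        rng = np.random.default_rng(cfg.random_state)
        pick = rng.choice(len(df), size=cfg.max_fit_points, replace=False)
    else:
        pick = np.arange(len(df))
    gpr = fit(pick)

    if cfg.trim_sigma:
        resid = ys[pick] - gpr.predict(X[pick])
        med = np.median(resid)
        scale = 1.4826 * np.median(np.abs(resid - med))
        if scale > 1e-8:
            keep = np.abs(resid - med) <= cfg.trim_sigma * scale
            # refit only when the trim actually bites (a few % of points)
            if 20 <= keep.sum() <= 0.98 * pick.size:
                gpr = fit(pick[keep])

    # posterior of the smooth function only: subtract the learned white noise
    learned_noise = float(gpr.kernel_.k2.noise_level)
    mu = np.empty(len(df))
    sd = np.empty(len(df))
    for start in range(0, len(df), 20_000):
        stop = min(start + 20_000, len(df))
        mu[start:stop], sd[start:stop] = gpr.predict(X[start:stop], return_std=True)
    smooth_var = np.maximum(sd**2 - learned_noise, 0.0) * sy**2
    df["S"] = (y - (my + sy * mu)) / np.sqrt(smooth_var + noise_var)
    df["condition"] = screen.condition
    return df[["donor", "recipient", "condition", "S", "n_obs"]]


def standardize_scores(scores: pd.DataFrame, robust: bool = False) -> pd.DataFrame:
    """Add Z (standardized S over the condition) and two-sided normal P.

    Z = (S - mean(S)) / sd(S); ``robust`` switches to median / 1.4826*MAD.
    P = 2 * (1 - Phi(|Z|)), clipped into (0, 1].
    """
    if len(scores) < 30:
        raise ValueError("need at least 30 scored pairs to standardize")
    s = scores["S"].to_numpy()
    if robust:
        center = np.median(s)
        scale = 1.4826 * np.median(np.abs(s - center))
    else:
        center = s.mean()
        scale = s.std(ddof=1)
    if not np.isfinite(scale) or scale == 0:
        raise ValueError("degenerate score distribution (sd = 0)")
    out = scores.copy()
    out["Z"] = (s - center) / scale
    out["P"] = np.clip(2.0 * norm.sf(np.abs(out["Z"])), np.finfo(float).tiny, 1.0)
    return out


def _classify(df: pd.DataFrame, cuts: ModelCuts, z_cut: float, p_cut: float) -> pd.Series:
    sig = (np.abs(df["Z"]) >= z_cut) & (df["P"] <= p_cut)
    cls = np.full(len(df), NEUTRAL, dtype=object)
    cls[(df["S"] <= cuts.lower) & sig] = AGGRAVATING
    cls[(df["S"] >= cuts.upper) & sig] = ALLEVIATING
    return pd.Series(cls, index=df.index)


@dataclass
class StaticNetwork:
    """One condition's scored pairs plus the called significant edges.

    ``all_scores`` columns: donor, recipient, condition, S_mult, S_gp,
    Z_mult, Z_gp, P_mult, P_gp, n_obs, class_mult, class_gp, interaction_class.
    ``significant_edges`` is the subset passing the dual-model agreement
    rule, with columns donor, recipient, condition, S (= S_gp), Z, P, sign.
    """

    condition: str
    all_scores: pd.DataFrame
    significant_edges: pd.DataFrame

    @property
    def genes(self) -> set:
        return set(self.all_scores["donor"]) | set(self.all_scores["recipient"])


def call_static_network(
    mult: pd.DataFrame,
    gp: pd.DataFrame,
    thresholds: ScoringThresholds | None = None,
    require_sign_concordance: bool = True,
    robust_z: bool = False,
) -> StaticNetwork:
    """Call the static GI network from the two scoring models.

    A pair is significant iff both models classify it non-neutral (S beyond
    the model's condition cut, |Z| >= z_cut, P <= p_cut, all inclusive) and
    — by default — with the same sign. Significant edges carry the
    Gaussian-process score as weight.
    """
    thresholds = thresholds or ScoringThresholds()
    conds = set(mult["condition"]) | set(gp["condition"])
    if len(conds) != 1:
        raise ValueError(f"condition mismatch between score tables: {sorted(conds)}")
    condition = conds.pop()

    mult = standardize_scores(mult, robust=robust_z)
    gp = standardize_scores(gp, robust=robust_z)
    merged = mult.merge(
        gp, on=["donor", "recipient", "condition"], suffixes=("_mult", "_gp"), how="inner"
    )
    merged = merged.rename(columns={"n_obs_mult": "n_obs"}).drop(columns=["n_obs_gp"])

    cm = _classify(
        merged.rename(columns={"S_mult": "S", "Z_mult": "Z", "P_mult": "P"}),
        thresholds.cuts("mult", condition),
        thresholds.z_cut,
        thresholds.p_cut,
    )
    cg = _classify(
        merged.rename(columns={"S_gp": "S", "Z_gp": "Z", "P_gp": "P"}),
        thresholds.cuts("gp", condition),
        thresholds.z_cut,
        thresholds.p_cut,
    )
    merged["class_mult"] = cm
    merged["class_gp"] = cg
    if require_sign_concordance:
        agree = (cm == cg) & (cm != NEUTRAL)
    else:
        agree = (cm != NEUTRAL) & (cg != NEUTRAL)
    merged["interaction_class"] = np.where(agree, cg, NEUTRAL)

    edges = merged.loc[agree, ["donor", "recipient", "condition", "S_gp", "Z_gp", "P_gp"]].copy()
    edges = edges.rename(columns={"S_gp": "S", "Z_gp": "Z", "P_gp": "P"})
    edges["sign"] = merged.loc[agree, "interaction_class"].to_numpy()
    return StaticNetwork(condition, merged, edges.reset_index(drop=True))
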
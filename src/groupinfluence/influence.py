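"""Influence curves and per-individual turn/speed influence scores.

For each individual and metric, a 4-parameter logistic

    P(x) = c + (d - c) / (1 + exp(-k (x - x0))),   0 <= c <= d <= 1

is fitted by Bernoulli maximum likelihood to (predictor, group-outcome)
pairs: left-right movement vs. the group-turns-right label for turn
influence, front-back speed difference vs. the group-speeds-up label for
speed influence. The curve evaluated at the group-pooled 90% quantile of the
signed predictor yields a single probability-scale score per individual,
compared against a no-information baseline (1/2 for turning; the group's
empirical speed-up fraction for speeding up). Uncertainty comes from
resampling recording sessions (days) with replacement.

The turn score is by default symmetrized, (P(q90) + 1 - P(q10)) / 2, which
makes it exactly invariant under a left-right mirror of the raw tracks; the
speed score is the plain upper-quantile evaluation because its baseline is
not 1/2. Fits are canonicalized by predictor orientation so that mirrored
data yield exactly mirrored parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .config import PipelineConfig
from .frame import KinematicTable, build_tables

logger = logging.getLogger(__name__)

METRICS = ("turn", "speed")

_METRIC_COLS = {
    "turn": ("lrm", "group_turn_right", "valid_turn"),
    "speed": ("fb_speed_diff", "group_speed_up", "valid_speed"),
}


@dataclass
class InfluenceCurve:
    """Fitted modified-logistic influence curve for one individual."""

    individual_id: str
    metric: str
    c: float
    d: float
    x0: float
    k: float
    n_obs: int
    converged: bool
    loglik: float

    def predict(self, x) -> np.ndarray:
        """P(outcome = 1 | predictor = x) under the fitted curve."""
        x = np.asarray(x, dtype=float)
        return self.c + (self.d - self.c) * expit(self.k * (x - self.x0))


@dataclass
class InfluenceScore:
    """Probability-scale influence summary for one individual and metric."""

    individual_id: str
    metric: str
    score: float
    baseline: float
    q_ref: float
    ci_low: float
    ci_high: float
    n_obs: int


def _nll(theta, x, y):
    c, d, x0, k = theta
    p = c + (d - c) * expit(k * (x - x0))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p))


def _fit_canonical(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Multi-start bounded ML fit; returns (theta, loglik, success)."""
    scale = float(np.std(x))
    med = float(np.median(x))
    lo_mask = x <= med
    eps = 1e-3
    p_lo = float(np.clip(y[lo_mask].mean() if lo_mask.any() else 0.5, eps, 1 - eps))
    p_hi = float(
        np.clip(y[~lo_mask].mean() if (~lo_mask).any() else 0.5, eps, 1 - eps)
    )
    pbar = float(np.clip(y.mean(), eps, 1 - eps))

    k1 = 1.0 / scale
    starts = [
        (p_lo, p_hi, med, k1),
        (p_lo, p_hi, med, -k1),
        (max(pbar - 0.05, eps), min(pbar + 0.05, 1 - eps), med, 0.1 * k1),
        (eps, 1 - eps, med, 4.0 * k1),
        (eps, 1 - eps, med, -4.0 * k1),
    ]
    span = x.max() - x.min()
    bounds = [
        (0.0, 1.0),
        (0.0, 1.0),
        (x.min() - 2.0 * span, x.max() + 2.0 * span),
        (-100.0 * k1, 100.0 * k1),
    ]
    best = None
    best_nll = np.inf
    for s in starts:
        res = minimize(
            _nll,
            np.asarray(s, dtype=float),
            args=(x, y),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if res.fun < best_nll:
            best, best_nll = res, res.fun
    return best.x, -best_nll, bool(best.success or best_nll < np.inf)


def fit_influence_curve(
    x,
    y,
    individual_id: str = "",
    metric: str = "turn",
    min_obs: int = 200,
) -> InfluenceCurve:
    """Fit the constrained 4-parameter logistic by Bernoulli ML.

    Requires at least ``min_obs`` observations and both outcome classes;
    otherwise the curve is returned with ``converged=False`` and downstream
    scores are undefined. The fit is deterministic: a fixed multi-start grid
    seeded from empirical class rates, and an orientation canonicalization
    (fit on (-x, 1-y) when sum(x) < 0, parameters mapped back) so mirrored
    inputs give exactly mirrored curves. c > d solutions are equivalent to
    (d, c) with the slope negated and are canonicalized to c <= d.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    n = len(x)
    unfit = InfluenceCurve(
        individual_id, metric, np.nan, np.nan, np.nan, np.nan, n, False, np.nan
    )
    if n < min_obs or len(np.unique(y)) < 2 or np.std(x) == 0:
        return unfit

    flip = bool(x.sum() < 0)
    if flip:
        theta, ll, ok = _fit_canonical(-x, 1.0 - y)
        c, d, x0, k = theta
        # P(x) = 1 - Pc(-x)  =>  (c, d, x0, k) -> (1-d, 1-c, -x0, k)
        c, d, x0 = 1.0 - d, 1.0 - c, -x0
    else:
        theta, ll, ok = _fit_canonical(x, y)
        c, d, x0, k = theta
    if c > d:
        c, d, k = d, c, -k
    return InfluenceCurve(
        individual_id, metric, float(c), float(d), float(x0), float(k), n, ok,
        float(ll),
    )


def _pooled_predictor(table: KinematicTable, metric: str) -> np.ndarray:
    xcol, _, vcol = _METRIC_COLS[metric]
    df = table.df
    vals = df.loc[df[vcol].astype(bool), xcol].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def group_reference_quantile(
    table: KinematicTable, metric: str, q: float = 0.9
) -> float:
    """q-quantile (type-7, linear interpolation) of the pooled predictor.

    Pooled over all valid rows of all individuals in the group: the score of
    every individual is evaluated at the same group-wide reference value.
    """
    pool = _pooled_predictor(table, metric)
    if len(pool) == 0:
        raise ValueError(f"no valid rows for metric {metric!r}")
    return float(np.quantile(pool, q))


def baseline_probability(table: KinematicTable, metric: str) -> float:
    """No-information probability of the group outcome.

    Turning left/right is symmetric, so the turn baseline is exactly 1/2.
    The speed baseline is the group's empirical probability of speeding up,
    computed over unique (session, t) time steps (the label is shared by the
    group, so per-row counting would weight by group size).
    """
    if metric == "turn":
        return 0.5
    df = table.df
    rows = df[df["valid_speed"].astype(bool)]
    if rows.empty:
        raise ValueError("no valid speed rows")
    per_step = rows.groupby(["session_id", "t"])["group_speed_up"].mean()
    return float(per_step.mean())


def influence_score(
    curve: InfluenceCurve,
    q_ref: float,
    baseline: float,
    q_ref_low: Optional[float] = None,
) -> InfluenceScore:
    """Evaluate a fitted curve at the group reference quantile.

    With ``q_ref_low`` given, the symmetrized form
    (P(q_ref) + 1 - P(q_ref_low)) / 2 is used (default for the turn metric).
    Scores below the baseline indicate negative influence. Unfit curves
    yield NaN, reported as missing rather than zero.
    """
    if not curve.converged:
        return InfluenceScore(
            curve.individual_id, curve.metric, np.nan, baseline, q_ref,
            np.nan, np.nan, curve.n_obs,
        )
    if q_ref_low is None:
        s = float(curve.predict(q_ref))
    else:
        s = float(0.5 * (curve.predict(q_ref) + 1.0 - curve.predict(q_ref_low)))
    return InfluenceScore(
        curve.individual_id, curve.metric, s, baseline, q_ref, np.nan, np.nan,
        curve.n_obs,
    )


def _individual_xy(df: pd.DataFrame, individual_id: str, metric: str):
    xcol, ycol, vcol = _METRIC_COLS[metric]
    rows = df[(df["focal_id"] == individual_id) & df[vcol].astype(bool)]
    return rows[xcol].to_numpy(dtype=float), rows[ycol].to_numpy(dtype=float)


def _score_value(curve, q_ref, q_low):
    if q_low is None:
        return float(curve.predict(q_ref))
    return float(0.5 * (curve.predict(q_ref) + 1.0 - curve.predict(q_low)))


def bootstrap_interval(
    table: KinematicTable,
    individual_id: str,
    metric: str,
    n_boot: int = 1000,
    level: float = 0.90,
    seed: Optional[int] = None,
    q_ref: Optional[float] = None,
    q_ref_low: Optional[float] = None,
    min_obs: int = 200,
) -> tuple[float, float]:
    """Bootstrap the score by resampling recording sessions with replacement.

    The session (recording day) is the resampling unit, respecting within-day
    autocorrelation. The reference quantile(s) are held at their full-data
    values across replicates, isolating curve uncertainty. Replicates whose
    curve cannot be fitted are dropped (logged). Returns the (1-level)/2 and
    (1+level)/2 quantiles of replicate scores; (nan, nan) when fewer than two
    sessions contribute rows for the individual.
    """
    df = table.df
    _, _, vcol = _METRIC_COLS[metric]
    contributing = df.loc[
        (df["focal_id"] == individual_id) & df[vcol].astype(bool), "session_id"
    ].unique()
    if len(contributing) < 2:
        logger.info(
            "bootstrap undefined for %s/%s: %d session(s)",
            individual_id, metric, len(contributing),
        )
        return np.nan, np.nan
    sessions = np.sort(df["session_id"].unique())
    if q_ref is None:
        q_ref = group_reference_quantile(table, metric)
    rng = np.random.default_rng(seed)
    by_session = {s: g for s, g in df.groupby("session_id")}

    scores = []
    n_failed = 0
    for _ in range(n_boot):
        pick = rng.choice(sessions, size=len(sessions), replace=True)
        rep = pd.concat([by_session[s] for s in pick], ignore_index=True)
        x, y = _individual_xy(rep, individual_id, metric)
        curve = fit_influence_curve(
            x, y, individual_id, metric, min_obs=min_obs
        )
        if not curve.converged:
            n_failed += 1
            continue
        scores.append(_score_value(curve, q_ref, q_ref_low))
    if n_failed:
        logger.info(
            "%d/%d bootstrap replicates failed to fit for %s/%s",
            n_failed, n_boot, individual_id, metric,
        )
    if not scores:
        return np.nan, np.nan
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(scores, lo)),
        float(np.quantile(scores, 1.0 - lo)),
    )


def positional_variant_table(table: KinematicTable) -> KinematicTable:
    """Swap movement predictors for positional ones.

    The turn predictor becomes the focal's signed left-right position and the
    speed predictor its front-back position (both meters, full-group frame);
    outcome labels and all downstream fitting/scoring are unchanged.
    """
    df = table.df.copy()
    df["lrm"] = df["lr_position"]
    df["fb_speed_diff"] = df["fb_position"]
    pos_ok = df["valid_position"].astype(bool)
    df["valid_turn"] = pos_ok & df["group_turn_right"].notna()
    df["valid_speed"] = pos_ok & df["group_speed_up"].notna()
    return KinematicTable(df=df, R=table.R, group_id=table.group_id)


def compute_scores(
    table: KinematicTable,
    metrics: Sequence[str] = METRICS,
    variant: str = "movement",
    config: Optional[PipelineConfig] = None,
    statuses: Optional[Mapping[str, str]] = None,
    n_boot: Optional[int] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Influence scores for every individual in a (multi-session) table.

    Returns a tidy frame: group_id, ind_id, status, metric, score, baseline,
    ci_low, ci_high, n_obs, R, q_ref. ``n_boot=0`` skips the bootstrap.
    """
    cfg = config or PipelineConfig()
    if variant == "position":
        table = positional_variant_table(table)
    elif variant != "movement":
        raise ValueError("variant must be 'movement' or 'position'")
    if n_boot is None:
        n_boot = cfg.n_boot
    if seed is None:
        seed = cfg.seed

    rows = []
    individuals = sorted(table.df["focal_id"].unique())
    for metric in metrics:
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        pool = _pooled_predictor(table, metric)
        if len(pool) == 0:
            logger.warning("no valid rows for metric %s; skipped", metric)
            continue
        q_hi = float(np.quantile(pool, cfg.q))
        symmetrize = metric == "turn" and cfg.symmetrize_turn
        q_lo = float(np.quantile(pool, 1.0 - cfg.q)) if symmetrize else None
        base = baseline_probability(table, metric)
        for i, ind in enumerate(individuals):
            x, y = _individual_xy(table.df, ind, metric)
            curve = fit_influence_curve(x, y, ind, metric, min_obs=cfg.min_obs)
            sc = influence_score(curve, q_hi, base, q_ref_low=q_lo)
            ci = (np.nan, np.nan)
            if n_boot and curve.converged:
                sub_seed = None
                if seed is not None:
                    sub_seed = np.random.SeedSequence(
                        entropy=seed, spawn_key=(METRICS.index(metric), i)
                    )
                ci = bootstrap_interval(
                    table, ind, metric,
                    n_boot=n_boot, level=cfg.ci_level, seed=sub_seed,
                    q_ref=q_hi, q_ref_low=q_lo, min_obs=cfg.min_obs,
                )
            rows.append(
                {
                    "group_id": table.group_id,
                    "ind_id": ind,
                    "status": (statuses or {}).get(ind, "unknown"),
                    "metric": metric,
                    "score": sc.score,
                    "baseline": base,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "n_obs": curve.n_obs,
                    "R": table.R,
                    "q_ref": q_hi,
                }
            )
    return pd.DataFrame(rows)


def robustness_sweep(
    sessions,
    radii: Iterable[float],
    config: Optional[PipelineConfig] = None,
    metrics: Sequence[str] = METRICS,
    variant: str = "movement",
    statuses: Optional[Mapping[str, str]] = None,
    n_boot: int = 0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Re-run the full pipeline at each spatial threshold R.

    Returns the long concatenation of per-R score tables (the R column
    distinguishes runs). Per-R failures propagate as missing entries.
    """
    cfg = config or PipelineConfig()
    out = []
    for R in radii:
        if R <= 0:
            raise ValueError("radii must be positive")
        table = build_tables(sessions, R=R, displacement_mode=cfg.displacement_mode)
        out.append(
            compute_scores(
                table, metrics=metrics, variant=variant, config=cfg,
                statuses=statuses, n_boot=n_boot, seed=seed,
            )
        )
    return pd.concat(out, ignore_index=True)
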
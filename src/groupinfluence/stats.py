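"""Group-level statistics linking influence, social status, and frontness.

Influence scores (one per individual) and hourly frontness records are
modeled with linear mixed models carrying a random intercept per group, the
fixed effect of interest being social status (optionally with frontness as a
covariate). Pairwise status contrasts use a single-step Tukey adjustment,
and associations among the influence metrics use Spearman multilevel
correlations: both variables are rank-transformed and a random-intercept
model of y-ranks on x-ranks gives the standardized within-group
coefficient.

Denominator degrees of freedom follow a containment-style convention,
ddf = N - rank(X) - (n_groups - 1); mixed-model stacks differ in this
choice, so the convention is always reported alongside the statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)


@dataclass
class StatusModelResult:
    """Mixed-model fit of a response on social status (+ optional covariate)."""

    response: str
    coefficients: dict
    group_var: float
    F: float
    df_num: int
    df_den: int
    p: float
    covariate: Optional[str] = None
    covariate_F: Optional[float] = None
    covariate_p: Optional[float] = None
    singular: bool = False
    df_convention: str = "containment: N - rank(X) - (n_groups - 1)"
    # internals for post-hoc contrasts
    _levels: list = field(default_factory=list, repr=False)
    _beta: np.ndarray = field(default=None, repr=False)
    _vcov: np.ndarray = field(default=None, repr=False)
    _names: list = field(default_factory=list, repr=False)
    pairwise: Optional[pd.DataFrame] = None


@dataclass
class MultilevelCorrelation:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int
    grouping: str = "group"


def _wald_F(beta, vcov, idx, ddf):
    L = np.zeros((len(idx), len(beta)))
    for row, j in enumerate(idx):
        L[row, j] = 1.0
    est = L @ beta
    M = L @ vcov @ L.T
    F = float(est @ np.linalg.solve(M, est) / len(idx))
    p = float(sps.f.sf(F, len(idx), ddf))
    return F, p


def fit_status_lmm(
    data: pd.DataFrame,
    response: str = "score",
    status: str = "status",
    group: str = "group_id",
    covariate: Optional[str] = None,
) -> StatusModelResult:
    """Random-intercept LMM of a score on social status.

    ``data`` holds one row per observation (per individual for influence
    scores, per hourly segment for frontness) with the response, status and
    group columns. Missing responses are dropped listwise (logged). Fitted
    by REML; a singular or non-convergent fit falls back to the
    fixed-effects model with a warning and ``singular=True``.
    """
    df = data[[response, status, group] + ([covariate] if covariate else [])]
    n_before = len(df)
    df = df.dropna().copy()
    if n_before - len(df):
        logger.info("dropped %d rows with missing values", n_before - len(df))
    if df[group].nunique() < 2:
        raise ValueError("need >=2 groups for a random group intercept")
    if df[status].nunique() < 2:
        raise ValueError("need >=2 status levels")
    df[status] = df[status].astype(str)
    levels = sorted(df[status].unique())

    # treatment-coded design built directly (avoids per-fit formula parsing,
    # which dominates runtime in permutation studies)
    y = df[response].to_numpy(dtype=float)
    names = ["Intercept"] + [f"C({status})[T.{lev}]" for lev in levels[1:]]
    cols = [np.ones(len(df))]
    svals = df[status].to_numpy()
    for lev in levels[1:]:
        cols.append((svals == lev).astype(float))
    if covariate:
        names.append(covariate)
        cols.append(df[covariate].to_numpy(dtype=float))
    X = np.column_stack(cols)

    singular = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            mod = sm.MixedLM(y, X, groups=df[group].to_numpy())
            res = mod.fit(reml=True)
        group_var = float(np.squeeze(res.cov_re))
        beta = np.asarray(res.fe_params)
        k = len(names)
        vcov = np.asarray(res.cov_params())[:k, :k]
        if not np.all(np.isfinite(vcov)) or group_var < 0:
            raise ValueError("singular covariance")
    except Exception as err:  # noqa: BLE001 - any estimation failure
        logger.warning("mixed model failed (%s); falling back to OLS", err)
        singular = True
        res = sm.OLS(y, X).fit()
        group_var = 0.0
        beta = np.asarray(res.params)
        vcov = np.asarray(res.cov_params())

    N = len(df)
    rank_X = len(names)
    n_groups = df[group].nunique()
    ddf = max(int(N - rank_X - (n_groups - 1)), 1)

    status_idx = [i for i, nm in enumerate(names) if f"C({status})" in nm]
    F, p = _wald_F(beta, vcov, status_idx, ddf)

    cov_F = cov_p = None
    if covariate:
        cov_idx = [i for i, nm in enumerate(names) if nm == covariate]
        cov_F, cov_p = _wald_F(beta, vcov, cov_idx, ddf)

    result = StatusModelResult(
        response=response,
        coefficients=dict(zip(names, beta)),
        group_var=group_var,
        F=F,
        df_num=len(status_idx),
        df_den=ddf,
        p=p,
        covariate=covariate,
        covariate_F=cov_F,
        covariate_p=cov_p,
        singular=singular,
        _levels=levels,
        _beta=beta,
        _vcov=vcov,
        _names=names,
    )
    result.pairwise = tukey_pairwise(result)
    return result


def tukey_pairwise(model: StatusModelResult) -> pd.DataFrame:
    """All pairwise status contrasts with single-step Tukey adjustment.

    Estimates are differences of status coefficients; the adjusted p-value
    uses the studentized range distribution with k = number of levels and
    the model's denominator df, so p_adj >= p_unadj always.
    """
    levels = model._levels
    names = model._names
    k = len(levels)
    # contrast vector of each level over the fixed-effect parameters
    vecs = {}
    for lev in levels:
        vec = np.zeros(len(names))
        term = None
        for i, nm in enumerate(names):
            if nm.endswith(f"[T.{lev}]"):
                term = i
        if term is not None:
            vec[term] = 1.0
        vecs[lev] = vec  # reference level -> zero vector

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = vecs[levels[i]] - vecs[levels[j]]
            est = float(c @ model._beta)
            se = float(np.sqrt(max(c @ model._vcov @ c, 0.0)))
            if se == 0:
                t = np.inf if est != 0 else 0.0
            else:
                t = est / se
            p_un = float(2 * sps.t.sf(abs(t), model.df_den))
            p_adj = float(
                sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, model.df_den)
            )
            rows.append(
                {
                    "status_i": levels[i],
                    "status_j": levels[j],
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p_unadj": p_un,
                    "p_adj": min(max(p_adj, p_un), 1.0),
                }
            )
    return pd.DataFrame(rows)


def multilevel_spearman(
    x, y, group, var_x: str = "x", var_y: str = "y"
) -> MultilevelCorrelation:
    """Spearman correlation with a random group intercept.

    Both variables are rank-transformed (average ranks over the pooled
    sample); a random-intercept model of y-ranks on x-ranks yields the
    standardized slope r = b * sd(rank_x) / sd(rank_y), with a t-test on the
    slope (ddf = N - n_groups - 1). Invariant to strictly monotone
    transforms of either variable. With a single group this reduces to the
    ordinary Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    m = np.isfinite(x) & np.isfinite(y)
    x, y, group = x[m], y[m], group[m]
    n = len(x)
    if n < 3:
        raise ValueError("need >=3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return MultilevelCorrelation(var_x, var_y, np.nan, np.nan, n)

    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    n_groups = len(np.unique(group))
    if n_groups < 2:
        r, p = sps.spearmanr(x, y)
        return MultilevelCorrelation(var_x, var_y, float(r), float(p), n)

    df = pd.DataFrame({"xr": xr, "yr": yr, "g": group})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            res = smf.mixedlm("yr ~ xr", df, groups=df["g"]).fit(reml=True)
        b = float(res.fe_params["xr"])
        se = float(res.bse_fe["xr"])
        if not np.isfinite(se) or se == 0:
            raise ValueError("degenerate slope standard error")
        r = b * float(np.std(xr)) / float(np.std(yr))
        ddf = max(n - n_groups - 1, 1)
        t = b / se
        p = float(2 * sps.t.sf(abs(t), ddf))
    except Exception as err:  # noqa: BLE001
        logger.info(
            "multilevel correlation fell back to pooled Spearman (%s)", err
        )
        r, p = sps.spearmanr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    return MultilevelCorrelation(var_x, var_y, r, float(p), n)
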
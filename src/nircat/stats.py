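"""Hierarchical group statistics for per-slice release metrics.

Slices are nested within animals, so group comparisons use linear
mixed-effects models fit by REML with a random intercept per animal:

* treatment comparisons (sham vs GDX within a region): treatment fixed,
  animal random; the treatment t statistic uses denominator df =
  n_animals - 2, the animal-level df of a two-group design;
* region comparisons within a treatment group: region fixed, animal random,
  followed by single-step (Tukey-style) adjusted pairwise contrasts using
  the joint multivariate-normal distribution of the contrast z statistics.

Effect sizes: Cohen's f^2 from the marginal (fixed-effects) explained
variance of the mixed model; partial eta squared from the fixed-effect F
and its dfs; Hedges' g per pairwise contrast from slice-level values with
the small-sample correction J = 1 - 3/(4*nu - 1).  Within-subject
associations between metrics use the repeated-measures correlation
(shared-slope ANCOVA), reported with uncorrected p values.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .synthetic import REGIONS

__all__ = [
    "LmmResult",
    "EffectSizes",
    "TukeyContrast",
    "RmcorrResult",
    "lmm_treatment",
    "lmm_region_tukey",
    "rmcorr",
    "hedges_g",
]

logger = logging.getLogger(__name__)

#: Fixed seed for the Monte-Carlo multivariate-normal integration behind
#: single-step adjusted p values (reproducibility of the adjustment).
_MC_SEED = 20231115
_MC_SAMPLES = 200_000


@dataclass
class LmmResult:
    """Summary of one mixed-model fixed effect (or omnibus test)."""

    fixed_effect_estimate: float = math.nan
    standard_error: float = math.nan
    t_value: float = math.nan
    denominator_df: float = math.nan
    p_value: float = math.nan
    variance_animal: float = math.nan
    variance_residual: float = math.nan
    reml_loglik: float = math.nan
    f_value: float = math.nan
    numerator_df: float = math.nan
    n_obs: int = 0
    n_animals: int = 0
    degenerate: bool = False


@dataclass
class EffectSizes:
    cohens_f2: float = math.nan
    eta2_partial: float = math.nan
    hedges_g: dict = field(default_factory=dict)  # pair label -> g


@dataclass(frozen=True)
class TukeyContrast:
    pair: tuple[str, str]
    estimate: float
    standard_error: float
    z_value: float
    p_raw: float
    adjusted_p: float


@dataclass(frozen=True)
class RmcorrResult:
    r_m: float
    df: int
    p_value: float
    n_subjects: int
    n_obs: int


def hedges_g(x, y) -> float:
    """Standardized mean difference mean(x) - mean(y) with the small-sample
    bias correction J = 1 - 3/(4*nu - 1), nu = n1 + n2 - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per cell for Hedges' g")
    nu = n1 + n2 - 2
    s_pooled = math.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / nu)
    if s_pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d = (x.mean() - y.mean()) / s_pooled
    j = 1.0 - 3.0 / (4.0 * nu - 1.0)
    return j * d


def _fit_mixedlm(data: pd.DataFrame, formula: str):
    """REML fit with optimizer fallbacks: variance components estimated near
    the zero boundary can make gradient-based optimizers fail, in which case
    derivative-free methods are tried before giving up."""
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data["animal_id"])
        for method in (None, "powell", "nm", "lbfgs"):
            try:
                kwargs = {} if method is None else {"method": method}
                return model.fit(reml=True, **kwargs)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
    raise last_exc if last_exc is not None else RuntimeError("mixed-model fit failed")


def _marginal_f2(result, data: pd.DataFrame) -> float:
    """Cohen's f^2 from the marginal R^2 of the fixed effects.

    Marginal R^2 is the variance of the fixed-effects linear predictor over
    the total variance (fixed + animal + residual); the intercept-only null
    has marginal R^2 = 0, so f^2 = R^2 / (1 - R^2).
    """
    fe = result.fe_params
    X = result.model.exog
    var_fixed = float(np.var(X @ fe.values, ddof=0))
    var_animal = float(np.asarray(result.cov_re)[0, 0])
    var_resid = float(result.scale)
    total = var_fixed + var_animal + var_resid
    if total <= 0:
        return math.nan
    r2 = var_fixed / total
    return r2 / (1.0 - r2) if r2 < 1 else math.inf


def _animal_mean_reduction(
    data: pd.DataFrame, metric: str, order: list[str], df_den: int
) -> tuple[LmmResult, EffectSizes]:
    """Exact mixed-model limit when the residual variance is zero: the slice
    values collapse to animal means and the treatment test is the two-sample
    t on animal means with df = n_animals - 2."""
    means = (
        data.groupby(["animal_id", "treatment"], observed=True)[metric].mean().reset_index()
    )
    xa = means.loc[means["treatment"] == order[0], metric].to_numpy()
    xb = means.loc[means["treatment"] == order[1], metric].to_numpy()
    n1, n2 = len(xa), len(xb)
    sp2 = ((n1 - 1) * xa.var(ddof=1) + (n2 - 1) * xb.var(ddof=1)) / df_den
    est = float(xb.mean() - xa.mean())
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t_val = est / se
    p = 2.0 * sps.t.sf(abs(t_val), df_den)
    var_animal = float(sp2)
    var_fixed = float(np.var(np.where(means["treatment"] == order[1], est, 0.0), ddof=0))
    r2 = var_fixed / (var_fixed + var_animal) if (var_fixed + var_animal) > 0 else math.nan
    lmm = LmmResult(
        fixed_effect_estimate=est,
        standard_error=float(se),
        t_value=float(t_val),
        denominator_df=df_den,
        p_value=float(p),
        variance_animal=var_animal,
        variance_residual=0.0,
        f_value=float(t_val**2),
        numerator_df=1,
        n_obs=len(data),
        n_animals=n1 + n2,
    )
    eta2p = (t_val**2) / (t_val**2 + df_den)
    g = {
        f"{order[0]}-{order[1]}": hedges_g(
            data.loc[data["treatment"] == order[0], metric].to_numpy(),
            data.loc[data["treatment"] == order[1], metric].to_numpy(),
        )
    }
    return lmm, EffectSizes(
        cohens_f2=r2 / (1 - r2) if not math.isnan(r2) and r2 < 1 else math.nan,
        eta2_partial=float(eta2p),
        hedges_g=g,
    )


def lmm_treatment(table: pd.DataFrame, metric: str) -> tuple[LmmResult, EffectSizes]:
    """Sham-vs-GDX mixed model for one metric.

    REML fit of ``metric ~ treatment`` with a random intercept per animal;
    the treatment coefficient's t statistic is referred to a t distribution
    with n_animals - 2 denominator df.  Requires two treatment groups with
    at least two animals each.  Near-zero within-group variance yields a
    flagged degenerate result instead of a crash.
    """
    if metric not in table.columns:
        raise ValueError(f"metric column {metric!r} not in table")
    data = table.dropna(subset=[metric]).copy()
    if data.empty:
        raise ValueError(f"metric {metric!r} has no non-missing values")
    groups = sorted(data["treatment"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two treatment groups, found {groups}")
    per_group_animals = data.groupby("treatment")["animal_id"].nunique()
    if (per_group_animals < 2).any():
        raise ValueError("need >= 2 animals per treatment group")
    n_animals = data["animal_id"].nunique()
    df_den = n_animals - 2

    # order treatment so the coefficient is (second level - first level) with
    # sham first, matching sham-as-reference reporting
    order = [g for g in ("sham", "GDX") if g in groups] or groups
    data["treatment"] = pd.Categorical(data["treatment"], categories=order)

    if float(data.groupby("treatment", observed=True)[metric].var(ddof=1).max()) < 1e-24:
        gm = data.groupby("treatment", observed=True)[metric].mean()
        return (
            LmmResult(
                fixed_effect_estimate=float(gm.iloc[1] - gm.iloc[0]),
                denominator_df=df_den,
                n_obs=len(data),
                n_animals=n_animals,
                degenerate=True,
            ),
            EffectSizes(),
        )

    # With no residual (within-animal) variance the slice-level mixed model is
    # degenerate at the boundary; the exact limit is a two-sample comparison of
    # animal means, which is what we compute in that case.
    within_var = float(data.groupby("animal_id")[metric].var(ddof=1).max())
    total_var = float(data[metric].var(ddof=1))
    if total_var > 0 and within_var < 1e-10 * total_var:
        return _animal_mean_reduction(data, metric, order, df_den)

    try:
        result = _fit_mixedlm(data, f"{metric} ~ treatment")
    except Exception as exc:
        logger.warning("mixed-model fit failed (%s); flagging degenerate", exc)
        return (
            LmmResult(denominator_df=df_den, n_obs=len(data), n_animals=n_animals, degenerate=True),
            EffectSizes(),
        )

    coef_name = [c for c in result.fe_params.index if c.startswith("treatment")][0]
    est = float(result.fe_params[coef_name])
    se = float(result.bse_fe[coef_name])
    t_val = est / se
    p = 2.0 * sps.t.sf(abs(t_val), df_den)
    lmm = LmmResult(
        fixed_effect_estimate=est,
        standard_error=se,
        t_value=t_val,
        denominator_df=df_den,
        p_value=float(p),
        variance_animal=float(np.asarray(result.cov_re)[0, 0]),
        variance_residual=float(result.scale),
        reml_loglik=float(result.llf),
        f_value=t_val**2,
        numerator_df=1,
        n_obs=len(data),
        n_animals=n_animals,
    )
    f2 = _marginal_f2(result, data)
    eta2p = (t_val**2) / (t_val**2 + df_den)
    g = {}
    a, b = order
    xa = data.loc[data["treatment"] == a, metric].to_numpy()
    xb = data.loc[data["treatment"] == b, metric].to_numpy()
    g[f"{a}-{b}"] = hedges_g(xa, xb)
    return lmm, EffectSizes(cohens_f2=f2, eta2_partial=float(eta2p), hedges_g=g)


def _singlestep_adjusted_p(z: np.ndarray, corr: np.ndarray, seed: int = _MC_SEED) -> np.ndarray:
    """Single-step adjusted p: P(max_j |Z_j| >= |z_k|) under Z ~ N(0, corr).

    Monte-Carlo with a fixed seed; the adjusted p is bounded below by the
    unadjusted two-sided normal p, which is enforced to remove MC jitter.
    """
    rng = np.random.default_rng(seed)
    # pairwise contrasts are linearly dependent, so corr is only PSD
    draws = rng.multivariate_normal(
        np.zeros(len(z)), corr, size=_MC_SAMPLES, method="svd", check_valid="ignore"
    )
    maxabs = np.abs(draws).max(axis=1)
    p_adj = np.array([(maxabs >= abs(zk)).mean() for zk in z])
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    return np.clip(np.maximum(p_adj, p_raw), 0.0, 1.0)


def lmm_region_tukey(
    table: pd.DataFrame, metric: str, group: str
) -> tuple[LmmResult, list[TukeyContrast], EffectSizes]:
    """Region comparison within one treatment group.

    REML fit of ``metric ~ region`` (animal random intercept) on the group's
    slices, an omnibus Wald F for the region effect with containment
    denominator df (n_obs - n_animals - df1), and all pairwise region
    contrasts with z statistics and single-step adjusted p values.
    Hedges' g per pair is computed from the slice-level values.
    """
    data = table[(table["treatment"] == group)].dropna(subset=[metric]).copy()
    if data.empty:
        raise ValueError(f"no rows for group {group!r} with non-missing {metric!r}")
    present = [r for r in REGIONS if r in set(data["region"])]
    if len(present) < 2:
        raise ValueError(f"need >= 2 regions within group {group!r}, found {present}")
    data["region"] = pd.Categorical(data["region"], categories=present)

    result = _fit_mixedlm(data, f"{metric} ~ region")
    fe = result.fe_params
    k_fe = len(fe)
    V = np.asarray(result.cov_params())[:k_fe, :k_fe]

    # cell-mean design: row r of M maps beta -> mean of region r
    M = np.zeros((len(present), k_fe))
    M[:, 0] = 1.0
    for idx, name in enumerate(fe.index):
        for r_i, reg in enumerate(present):
            if name == f"region[T.{reg}]":
                M[r_i, idx] = 1.0

    pairs = list(itertools.combinations(range(len(present)), 2))
    L = np.array([M[a] - M[b] for a, b in pairs])
    est = L @ fe.values
    cov_c = L @ V @ L.T
    diag = np.diag(cov_c)
    if not np.all(np.isfinite(diag)) or np.any(diag <= 0):
        raise np.linalg.LinAlgError(
            "contrast covariance is not positive; the region model is too ill-conditioned"
        )
    se = np.sqrt(diag)
    z = est / se
    corr = cov_c / np.outer(se, se)
    if len(pairs) == 1:
        p_adj = 2.0 * sps.norm.sf(np.abs(z))
    else:
        p_adj = _singlestep_adjusted_p(z, corr)
    p_raw = 2.0 * sps.norm.sf(np.abs(z))

    contrasts = []
    g_by_pair = {}
    for (ia, ib), e, s, zz, pr, pa in zip(pairs, est, se, z, p_raw, p_adj):
        pair = (present[ia], present[ib])
        xa = data.loc[data["region"] == pair[0], metric].to_numpy()
        xb = data.loc[data["region"] == pair[1], metric].to_numpy()
        g_by_pair[f"{pair[0]}-{pair[1]}"] = hedges_g(xa, xb)
        contrasts.append(
            TukeyContrast(
                pair=pair,
                estimate=float(e),
                standard_error=float(s),
                z_value=float(zz),
                p_raw=float(pr),
                adjusted_p=float(pa),
            )
        )

    # omnibus Wald F for the region terms
    region_idx = [i for i, name in enumerate(fe.index) if name.startswith("region[")]
    beta_r = fe.values[region_idx]
    V_r = V[np.ix_(region_idx, region_idx)]
    df1 = len(region_idx)
    wald = float(beta_r @ np.linalg.solve(V_r, beta_r))
    f_val = wald / df1
    n_animals = data["animal_id"].nunique()
    df2 = max(len(data) - n_animals - df1, 1)
    p_f = float(sps.f.sf(f_val, df1, df2))

    lmm = LmmResult(
        f_value=f_val,
        numerator_df=df1,
        denominator_df=df2,
        p_value=p_f,
        variance_animal=float(np.asarray(result.cov_re)[0, 0]),
        variance_residual=float(result.scale),
        reml_loglik=float(result.llf),
        n_obs=len(data),
        n_animals=n_animals,
    )
    eta2p = (f_val * df1) / (f_val * df1 + df2)
    effects = EffectSizes(
        cohens_f2=_marginal_f2(result, data),
        eta2_partial=float(eta2p),
        hedges_g=g_by_pair,
    )
    return lmm, contrasts, effects


def rmcorr(
    table: pd.DataFrame,
    metric_x: str,
    metric_y: str,
    subject: str = "animal_id",
) -> RmcorrResult:
    """Repeated-measures correlation between two metrics.

    Shared-slope ANCOVA: the common within-subject correlation is recovered
    from the incremental sum of squares of the measure after removing
    subject means, with df = N_obs - N_subjects - 1.  Subjects with fewer
    than two complete observations are dropped (logged).
    """
    data = table.dropna(subset=[metric_x, metric_y])[[subject, metric_x, metric_y]].copy()
    counts = data.groupby(subject).size()
    keep = counts[counts >= 2].index
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.info("rmcorr: dropping subjects with <2 paired observations: %s", dropped)
    data = data[data[subject].isin(keep)]
    n_subj = data[subject].nunique()
    if n_subj < 2:
        raise ValueError("rmcorr needs >= 2 subjects with >= 2 paired observations")
    n = len(data)
    df = n - n_subj - 1
    if df < 1:
        raise ValueError("not enough observations for rmcorr degrees of freedom")

    # within-subject centering == absorbing subject fixed effects
    xc = data[metric_x] - data.groupby(subject)[metric_x].transform("mean")
    yc = data[metric_y] - data.groupby(subject)[metric_y].transform("mean")
    sxx = float((xc**2).sum())
    syy = float((yc**2).sum())
    sxy = float((xc * yc).sum())
    if sxx == 0 or syy == 0:
        raise ValueError("no within-subject variance in one of the metrics")
    r_m = sxy / math.sqrt(sxx * syy)
    r_m = max(-1.0, min(1.0, r_m))
    if abs(r_m) >= 1.0:
        p = 0.0
    else:
        t_val = r_m * math.sqrt(df / (1.0 - r_m**2))
        p = 2.0 * sps.t.sf(abs(t_val), df)
    return RmcorrResult(r_m=float(r_m), df=int(df), p_value=float(p), n_subjects=int(n_subj), n_obs=int(n))
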
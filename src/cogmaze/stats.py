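"""Mixed models, Bonferroni paired t-tests and the stereotypy-form test.

Linear mixed models have handling (and optionally session and the
handling-by-session interaction) as fixed effects, random intercepts
for litter and cage fitted as crossed variance components, and the
square-root of the stereotypy level as a covariate.  Grouping factors
with fewer than two levels are dropped with a warning; when none
remain the fit reduces to ordinary least squares.

Fixed-effect F tests are Wald tests on the GLS estimates at the REML
variance components.  The denominator df uses a Satterthwaite
approximation by default (``ddf_method="satterthwaite"``; lmerTest-style
multi-df pooling), with ``"residual"`` (``n_obs - rank(X)``) available
as a simpler alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import patsy
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "FixedEffectTest",
    "ComparisonResult",
    "KruskalWallisResult",
    "AlreadyTransformedError",
    "sqrt_transform",
    "fit_mixed_model",
    "paired_arm_comparisons",
    "stereotypy_form_test",
    "comparisons_to_frame",
    "fit_to_frame",
]

_TRANSFORM_ATTR = "sqrt_transformed_columns"


class AlreadyTransformedError(ValueError):
    """Guard against applying the square-root transform twice."""


def sqrt_transform(df: pd.DataFrame, col: str) -> str:
    """Add a ``sqrt_<col>`` column in place and return its name.

    Raises :class:`AlreadyTransformedError` if ``col`` was already
    transformed in this frame or is itself a transformed column.
    """
    done = set(df.attrs.get(_TRANSFORM_ATTR, ()))
    if col in done or col.startswith("sqrt_"):
        raise AlreadyTransformedError(f"column {col!r} is already square-root transformed")
    if (df[col].dropna() < 0).any():
        raise ValueError(f"column {col!r} has negative values; cannot sqrt-transform")
    new = f"sqrt_{col}"
    df[new] = np.sqrt(df[col])
    df.attrs[_TRANSFORM_ATTR] = done | {col}
    return new


@dataclass(frozen=True)
class ModelSpec:
    """Declarative layout of one mixed model."""

    outcome: str
    fixed: Tuple[str, ...] = ("handling",)
    covariate: Optional[str] = "stereotypy_level"
    covariate_transform: Optional[str] = "sqrt"
    random_effects: Tuple[str, ...] = ("litter", "cage")
    ddf_method: str = "satterthwaite"


@dataclass(frozen=True)
class FixedEffectTest:
    term: str
    fvalue: float
    df1: int
    df2: float
    pvalue: float


@dataclass
class MixedModelFit:
    """Fixed-effect estimates, per-term F tests and fit diagnostics."""

    spec: ModelSpec
    params: pd.Series
    tests: List[FixedEffectTest]
    method: str  # "mixedlm" or "ols"
    converged: bool
    dropped_random_effects: List[str] = field(default_factory=list)
    vc_estimates: Dict[str, float] = field(default_factory=dict)
    n_obs: int = 0

    def test_for(self, term: str) -> FixedEffectTest:
        for t in self.tests:
            if t.term == term:
                return t
        raise KeyError(term)


def _build_formula(spec: ModelSpec, cov_col: Optional[str]) -> str:
    terms = list(spec.fixed)
    if cov_col:
        terms.append(cov_col)
    rhs = " + ".join(terms) if terms else "1"
    return f"{spec.outcome} ~ {rhs}"


def _satterthwaite_df(
    contrast_idx: List[int],
    v_fe: np.ndarray,
    x: np.ndarray,
    sigma_inv: np.ndarray,
    d_sigmas: List[np.ndarray],
    theta_cov: np.ndarray,
) -> float:
    """Satterthwaite denominator df for the Wald test of a term.

    For each orthonormalised 1-df contrast m the df is
    ``2 * phi_m^2 / (g_m' A g_m)`` with ``phi_m`` the contrast variance,
    ``g_m`` its gradient w.r.t. the variance parameters and ``A`` the
    asymptotic covariance of those parameters; multi-df terms pool the
    per-contrast dfs as in lmerTest.
    """
    q = len(contrast_idx)
    sub = v_fe[np.ix_(contrast_idx, contrast_idx)]
    eigvals, eigvecs = np.linalg.eigh(sub)
    # dV/dtheta_i = V X' Sigma^-1 dSigma_i Sigma^-1 X V
    xs = sigma_inv @ x
    dv = [v_fe @ (xs.T @ ds @ xs) @ v_fe for ds in d_sigmas]
    nus = []
    for m in range(q):
        if eigvals[m] <= 0:
            continue
        c = np.zeros(v_fe.shape[0])
        c[contrast_idx] = eigvecs[:, m]
        phi = float(c @ v_fe @ c)
        g = np.array([float(c @ dvi @ c) for dvi in dv])
        denom = float(g @ theta_cov @ g)
        if denom <= 0:
            continue
        nu = 2.0 * phi * phi / denom
        if nu > 0:
            nus.append(nu)
    if not nus:
        return math.nan
    if q == 1:
        return nus[0]
    e_sum = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
    if e_sum <= q:
        return math.nan
    return 2.0 * e_sum / (e_sum - q)


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> MixedModelFit:
    """Fit the model declared by ``spec`` and return Type-III-style F tests.

    Random intercepts for the grouping factors are fitted as crossed
    variance components (the whole data set forms a single group); the
    variance components are estimated by REML via statsmodels, after
    which the fixed effects, their covariance and the Satterthwaite dfs
    are computed by generalised least squares at those estimates.
    """
    df = data.copy()
    df.attrs = dict(data.attrs)
    cov_col = None
    if spec.covariate:
        if spec.covariate_transform == "sqrt":
            if spec.covariate in df.attrs.get(_TRANSFORM_ATTR, ()):
                cov_col = f"sqrt_{spec.covariate}"  # already transformed upstream
            else:
                cov_col = sqrt_transform(df, spec.covariate)
        elif spec.covariate_transform is None:
            cov_col = spec.covariate
        else:
            raise ValueError(f"unknown covariate transform {spec.covariate_transform!r}")
    if spec.ddf_method not in ("satterthwaite", "residual"):
        raise ValueError(f"unsupported ddf_method {spec.ddf_method!r}")

    formula = _build_formula(spec, cov_col)
    model_cols = set(spec.random_effects) | {spec.outcome}
    df = df.dropna(subset=[c for c in model_cols if c in df.columns]
                   + ([cov_col] if cov_col else []))

    y_dm, x_dm = patsy.dmatrices(formula, df, return_type="dataframe")
    if float(np.var(np.asarray(y_dm))) < 1e-12:
        warnings.warn("outcome is (nearly) constant; fit will be singular",
                      UserWarning, stacklevel=2)

    kept, dropped = [], []
    for re_name in spec.random_effects:
        if re_name in df.columns and df[re_name].nunique() >= 2:
            kept.append(re_name)
        else:
            dropped.append(re_name)
            warnings.warn(
                f"random effect {re_name!r} has fewer than 2 levels; dropped",
                UserWarning, stacklevel=2)

    x = np.asarray(x_dm)
    y = np.asarray(y_dm).ravel()
    n = len(y)
    rank_x = int(np.linalg.matrix_rank(x))
    residual_ddf = float(n - rank_x)

    vc_estimates: Dict[str, float] = {}
    sat_parts = None  # (v_fe, x, sigma_inv, d_sigmas, theta_cov)
    if kept:
        work = df.copy()
        work["_group"] = 1
        vcf = {name: f"0 + C({name})" for name in kept}
        model = smf.mixedlm(formula, work, groups="_group",
                            re_formula="0", vc_formula=vcf)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
        except np.linalg.LinAlgError:
            warnings.warn("singular mixed-model fit; falling back to OLS",
                          UserWarning, stacklevel=2)
            kept, dropped = [], list(spec.random_effects)
        else:
            converged = bool(getattr(res, "converged", True))
    if kept:
        for i, name in enumerate(model.exog_vc.names):
            vc_estimates[name] = float(res.vcomp[i])
        scale = float(res.scale)
        # GLS at the REML variance components, consistent with the
        # Satterthwaite machinery below
        d_sigmas = []
        sigma = scale * np.eye(n)
        for name in kept:
            z = pd.get_dummies(df[name]).to_numpy(dtype=float)
            zzt = z @ z.T
            d_sigmas.append(zzt)
            sigma = sigma + vc_estimates.get(name, 0.0) * zzt
        d_sigmas.append(np.eye(n))  # d sigma / d scale
        if scale < 1e-10:  # degenerate (constant-outcome) fit
            sigma = sigma + 1e-10 * np.eye(n)
        sigma_inv = np.linalg.pinv(sigma)
        xtsi = x.T @ sigma_inv
        v_fe = np.linalg.pinv(xtsi @ x)
        beta = v_fe @ (xtsi @ y)
        params = pd.Series(beta, index=list(x_dm.columns))
        cov = v_fe
        # expected REML information of the variance parameters
        proj = sigma_inv - xtsi.T @ v_fe @ xtsi
        k = len(d_sigmas)
        info = np.empty((k, k))
        pds = [proj @ ds for ds in d_sigmas]
        for i in range(k):
            for j in range(i, k):
                info[i, j] = info[j, i] = 0.5 * np.trace(pds[i] @ pds[j])
        theta_cov = np.linalg.pinv(info)
        sat_parts = (v_fe, x, sigma_inv, d_sigmas, theta_cov)
        method = "mixedlm"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.ols(formula, df).fit()
        params = res.params.copy()
        cov = np.asarray(res.cov_params())
        converged = True
        method = "ols"

    tests: List[FixedEffectTest] = []
    for term, slc in x_dm.design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = list(range(slc.start or 0, slc.stop))
        beta_t = np.asarray(params)[idx]
        v = cov[np.ix_(idx, idx)]
        q = len(idx)
        try:
            fval = float(beta_t @ np.linalg.solve(v, beta_t) / q)
        except np.linalg.LinAlgError:
            fval = math.nan
        if spec.ddf_method == "satterthwaite" and sat_parts is not None:
            ddf = _satterthwaite_df(idx, *sat_parts)
            if not math.isfinite(ddf):
                ddf = residual_ddf
        else:
            ddf = residual_ddf
        pval = float(scipy.stats.f.sf(fval, q, ddf)) if ddf > 0 else math.nan
        tests.append(FixedEffectTest(term, fval, q, ddf, pval))
    return MixedModelFit(spec, params, tests, method, converged, dropped,
                         vc_estimates, n_obs=n)


def fit_to_frame(fit: MixedModelFit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "outcome": fit.spec.outcome,
            "term": [t.term for t in fit.tests],
            "F": [t.fvalue for t in fit.tests],
            "df1": [t.df1 for t in fit.tests],
            "df2": [t.df2 for t in fit.tests],
            "p": [t.pvalue for t in fit.tests],
            "method": fit.method,
        }
    )


# ---------------------------------------------------------------------------
# paired post-hoc comparisons


@dataclass(frozen=True)
class ComparisonResult:
    label: str
    statistic: float
    df: int
    pvalue: float
    pvalue_adj: float
    significant: bool


def paired_arm_comparisons(
    table: pd.DataFrame,
    contrasts: Sequence[Tuple[str, str, str]],
    alpha: float = 0.05,
    family_size: Optional[int] = None,
) -> List[ComparisonResult]:
    """Bonferroni-corrected paired t-tests over declared column contrasts.

    Each contrast is ``(label, column_a, column_b)``; rows with a
    missing value in either column are dropped pairwise.  The Bonferroni
    family defaults to the number of contrasts requested.
    """
    m = family_size if family_size is not None else len(contrasts)
    if m < 1:
        raise ValueError("empty contrast family")
    out: List[ComparisonResult] = []
    for label, col_a, col_b in contrasts:
        sub = table[[col_a, col_b]].dropna()
        n = len(sub)
        if n < 2:
            raise ValueError(f"contrast {label!r}: need at least 2 paired observations")
        diff = sub[col_a].to_numpy(float) - sub[col_b].to_numpy(float)
        if np.allclose(diff, 0.0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = scipy.stats.ttest_rel(sub[col_a], sub[col_b])
            t_stat, p = float(t_stat), float(p)
        p_adj = min(1.0, p * m)
        out.append(ComparisonResult(label, t_stat, n - 1, p, p_adj, p_adj < alpha))
    return out


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contrast": [r.label for r in results],
            "t": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p": [r.pvalue for r in results],
            "p_adj": [r.pvalue_adj for r in results],
            "significant": [r.significant for r in results],
        }
    )


# ---------------------------------------------------------------------------
# stereotypy-form comparison


@dataclass(frozen=True)
class KruskalWallisResult:
    statistic: float
    df: int
    pvalue: float


def stereotypy_form_test(levels_by_form: Dict[str, Sequence[float]]) -> KruskalWallisResult:
    """Kruskal-Wallis rank test of stereotypy levels across forms.

    Uses the tie-corrected statistic; when every observation is
    identical the statistic is reported as 0 with p = 1 (the tie
    correction is degenerate in that case).
    """
    groups = [np.asarray(v, dtype=float) for v in levels_by_form.values()]
    if len(groups) < 2:
        raise ValueError("need at least two stereotypy forms")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every form needs at least one observation")
    k = len(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KruskalWallisResult(0.0, k - 1, 1.0)
    stat, p = scipy.stats.kruskal(*groups)
    return KruskalWallisResult(float(stat), k - 1, float(p))
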
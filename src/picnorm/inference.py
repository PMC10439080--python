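"""Statistical analysis of naming latencies and norm variables.

The analysis chain mirrors standard practice for timed picture-naming
norms:

* latencies enter all models as the reciprocal ``-1000/RT`` (which
  normalizes their right-skewed distribution while keeping the sign of
  effects interpretable);
* skewed predictors are transformed by a skewness ladder (inverse for
  |skew| > 1, square root for moderate skew, log for frequency) and
  demeaned;
* rank-based statistics (Spearman correlations, Wilcoxon rank-sum
  class comparisons with effect size r = |Z|/sqrt(N)) with Bonferroni
  control of the family-wise error rate;
* a Variance Inflation Factor screen for collinear predictors;
* a linear mixed-effects model of the transformed latency with crossed
  random intercepts for participants, pictures, and alternative names
  nested within pictures, reduced from the maximal structure by a
  deterministic variance-threshold/singularity procedure.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

TRANSFORMS = ("none", "sqrt", "inverse_pos", "inverse_neg", "log", "reciprocal_rt")

#: |skewness| above which the inverse transform is applied, and the band
#: (moderate_skew, high_skew] in which the square-root transform is used.
HIGH_SKEW = 1.0
MODERATE_SKEW = 0.5


@dataclass
class TransformSpec:
    """A chosen variable transformation and its bookkeeping."""

    variable: str
    skewness: float
    transform: str
    demeaned: bool = False
    reflect_max: float | None = None  # max(x) used by inverse_neg
    direction_note: str = ""

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


def select_transform(
    values,
    variable: str = "",
    kind: str = "predictor",
    high_skew: float = HIGH_SKEW,
    moderate_skew: float = MODERATE_SKEW,
    demean: bool = True,
) -> TransformSpec:
    """Pick a normalizing transform from the sample skewness.

    ``kind`` overrides the ladder for the two special variables:
    latencies always get the reciprocal ``-1000/RT`` and frequency always
    the log.  Otherwise |skew| > ``high_skew`` selects an inverse
    transform (1/x for positive skew, 1/(max - x) for negative skew),
    moderate skew selects a square root (applied to reflected data when
    the skew is negative), and near-symmetric data are left alone.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 non-missing values")
    skew = float(stats.skew(arr, bias=False))
    note = ""
    if kind == "latency":
        transform = "reciprocal_rt"
    elif kind == "frequency":
        transform = "log"
    elif abs(skew) > high_skew:
        if skew > 0:
            if (arr <= 0).any():
                raise ValueError(
                    f"{variable or 'variable'}: inverse transform needs "
                    "strictly positive values"
                )
            transform = "inverse_pos"
            note = "effect direction inverted by 1/x"
        else:
            transform = "inverse_neg"
        return TransformSpec(variable, skew, transform, demean, float(arr.max()), note)
    elif abs(skew) > moderate_skew:
        transform = "sqrt"
    else:
        transform = "none"
    spec = TransformSpec(variable, skew, transform, demean, direction_note=note)
    if transform == "sqrt" and skew < 0:
        spec.reflect_max = float(arr.max())
    return spec


def apply_transform(values, spec: TransformSpec) -> np.ndarray:
    """Apply a transform elementwise, then demean if the spec asks for it.

    Missing values pass through untouched; domain violations raise with
    the offending positions named.
    """
    arr = np.asarray(pd.Series(values), dtype=float)
    out = np.full_like(arr, np.nan)
    ok = ~np.isnan(arr)
    x = arr[ok]

    def _domain(cond: np.ndarray, what: str) -> None:
        if (~cond).any():
            rows = np.flatnonzero(ok)[~cond][:10]
            raise ValueError(f"{spec.variable or 'values'}: {what} at rows {rows.tolist()}")

    if spec.transform == "none":
        y = x
    elif spec.transform == "sqrt":
        if spec.reflect_max is not None and spec.skewness < 0:
            refl = spec.reflect_max + 1.0 - x
            _domain(refl >= 0, "reflected value negative under sqrt")
            y = np.sqrt(refl)
        else:
            _domain(x >= 0, "negative value under sqrt")
            y = np.sqrt(x)
    elif spec.transform == "inverse_pos":
        _domain(x > 0, "non-positive value under 1/x")
        y = 1.0 / x
    elif spec.transform == "inverse_neg":
        m = spec.reflect_max if spec.reflect_max is not None else float(x.max())
        denom = m + 1.0 - x
        _domain(denom > 0, "non-positive denominator under 1/(max - x)")
        y = 1.0 / denom
    elif spec.transform == "log":
        _domain(x > 0, "non-positive value under log")
        y = np.log(x)
    elif spec.transform == "reciprocal_rt":
        _domain(x > 0, "non-positive latency under -1000/RT")
        y = -1000.0 / x
    else:  # pragma: no cover - guarded by TransformSpec
        raise ValueError(spec.transform)
    out[ok] = y
    if spec.demeaned:
        out[ok] = out[ok] - np.nanmean(out[ok])
    return out


def spearman_matrix(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Pairwise Spearman correlations with Bonferroni-flagged significance.

    Each pair is computed on its complete cases.  The family size m is
    the number of unique variable pairs; a pair is flagged significant
    iff its p-value is below ``alpha / m``.  Constant variables yield
    missing correlations with a warning.
    """
    if variables is None:
        variables = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(variables)
    m = k * (k - 1) // 2
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pval = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    sig = pd.DataFrame(False, index=variables, columns=variables)
    for a, b in itertools.combinations(variables, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 4:
            raise ValueError(f"pair ({a}, {b}) has fewer than 4 complete cases")
        if sub[a].nunique() < 2 or sub[b].nunique() < 2:
            logger.warning("pair (%s, %s): constant variable, rho undefined", a, b)
            r, p = np.nan, np.nan
        else:
            r, p = stats.spearmanr(sub[a], sub[b])
        rho.loc[a, b] = rho.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p
        flag = bool(p < alpha / m) if np.isfinite(p) else False
        sig.loc[a, b] = sig.loc[b, a] = flag
    return {"rho": rho, "p": pval, "significant": sig, "n_pairs": m}


@dataclass
class ComparisonResult:
    """Wilcoxon rank-sum comparison of one variable between word classes."""

    variable: str
    w_statistic: float
    p_value: float
    effect_size_r: float
    significant: bool
    method: str


def compare_classes(
    values_a,
    values_b,
    variable: str = "",
    threshold: float = 0.005,
    exact_limit: int = 20,
) -> ComparisonResult:
    """Two-sample two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The p-value is exact (full enumeration of the null distribution of
    the rank-sum statistic) when the combined sample size is at most
    ``exact_limit`` and there are no ties, and a tie-corrected normal
    approximation otherwise.  W is the Mann-Whitney U of the first
    sample; the effect size r = |Z|/sqrt(N) comes from the normal
    approximation in either case.
    """
    x = np.asarray(pd.Series(values_a).dropna(), dtype=float)
    y = np.asarray(pd.Series(values_b).dropna(), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m_ = x.size, y.size
    has_ties = len(np.unique(np.concatenate([x, y]))) < n + m_
    if n + m_ <= exact_limit and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        method = "normal approximation (tie-corrected)"
    u = float(res.statistic)
    # z from the (tie-corrected) normal approximation, for the effect size
    mu = n * m_ / 2.0
    combined = np.concatenate([x, y])
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n + m_) * (n + m_ - 1))
    sigma2 = n * m_ / 12.0 * (n + m_ + 1 - tie_term)
    z = 0.0 if sigma2 == 0 else (u - mu) / math.sqrt(sigma2)
    r = min(1.0, abs(z) / math.sqrt(n + m_))
    return ComparisonResult(
        variable=variable,
        w_statistic=u,
        p_value=float(res.pvalue),
        effect_size_r=r,
        significant=bool(res.pvalue < threshold),
        method=method,
    )


def compare_class_table(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    variables: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon comparisons per variable with a Bonferroni threshold.

    The significance threshold is ``alpha / len(variables)`` (with ten
    variables this is the conventional 0.005 level).
    """
    threshold = alpha / len(variables)
    rows = []
    for v in variables:
        res = compare_classes(table_a[v], table_b[v], variable=v, threshold=threshold)
        rows.append(
            {
                "variable": v,
                "W": res.w_statistic,
                "p": res.p_value,
                "effect_size_r": res.effect_size_r,
                "significant": res.significant,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance Inflation Factor per predictor.

    VIF_j = 1/(1 - R^2_j) from regressing predictor j on the remaining
    predictors (with an intercept).  Exact collinearity yields inf with
    a warning rather than an error.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least two predictors")
    X = design.dropna()
    if len(X) <= len(cols):
        raise ValueError("need more rows than predictors")
    out = {}
    for j in cols:
        others = [c for c in cols if c != j]
        exog = sm.add_constant(X[others].to_numpy())
        fit = sm.OLS(X[j].to_numpy(), exog).fit()
        r2 = fit.rsquared
        if r2 >= 1.0 - 1e-12:
            logger.warning("predictor %r is exactly collinear; VIF infinite", j)
            out[j] = np.inf
        else:
            out[j] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class LmmResult:
    """Fitted latency model: fixed effects, variance components, audit log."""

    fixed_effects: pd.DataFrame  # term, estimate, se, t, d
    random_components: dict[str, float]
    selection_log: list[str]
    n_obs: int
    n_dropped: int
    method: str
    converged: bool = True

    def coef(self, term: str) -> pd.Series:
        row = self.fixed_effects.set_index("term").loc[term]
        return row


def _fe_table(params, bse, tvalues, df_resid: float, terms) -> pd.DataFrame:
    rows = []
    for term in terms:
        t = tvalues[term]
        d = np.nan if term == "Intercept" else 2.0 * t / math.sqrt(df_resid)
        rows.append(
            {
                "term": term,
                "estimate": params[term],
                "se": bse[term],
                "t": t,
                "d": d,
            }
        )
    return pd.DataFrame(rows)


def fit_latency_model(
    data: pd.DataFrame,
    predictors: list[str],
    outcome: str = "neg_inv_rt",
    participant_col: str = "participant",
    picture_col: str = "picture",
    name_col: str = "name",
    var_floor: float = 1e-6,
    screen_ratio: float = 0.15,
    lrt_cutoff: float = 3.84,
) -> LmmResult:
    """Fit the crossed-random-intercepts model of transformed latency.

    The outcome is expected on the -1000/RT scale and the predictors
    transformed and demeaned.  Rows with any missing value are dropped
    (complete-case) and counted.  The maximal random structure —
    intercepts for participants, pictures, and names nested within
    pictures — is fitted first and then reduced, smallest variance
    first: a component is removed outright when its estimated variance
    is below ``var_floor`` or the fit fails to converge; a component
    whose variance falls below ``screen_ratio`` x residual variance is
    refitted without and removed when the REML likelihood-ratio
    statistic against the larger model stays under ``lrt_cutoff``
    (boundary estimates of truly absent components rarely reach exact
    zero, so near-zero variances need this confirmation step).  Each
    decision is logged.  With no components left the model collapses to
    OLS.  The reported effect size is d = 2t/sqrt(residual df); the t
    degrees of freedom use the residual approximation (n - p).
    """
    cols = [outcome] + predictors + [participant_col, picture_col, name_col]
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    df = data[cols].dropna().copy()
    n_dropped = len(data) - len(df)
    if n_dropped:
        logger.info("dropped %d incomplete rows before fitting", n_dropped)
    df["_name_key"] = (
        df[picture_col].astype(str) + ":" + df[name_col].astype(str)
    )
    df["_grp"] = 1

    log: list[str] = []
    vc_columns = {
        "participant": participant_col,
        "picture": picture_col,
        "name_within_picture": "_name_key",
    }
    components = []
    for label, col in vc_columns.items():
        if df[col].nunique() < 2:
            log.append(f"excluded {label}: fewer than 2 levels")
            logger.warning("random component %s excluded: <2 levels", label)
        else:
            components.append(label)

    rhs = " + ".join(predictors) if predictors else "1"
    formula = f"{outcome} ~ {rhs}"
    terms = ["Intercept"] + predictors

    def _fit_mixed(comps: list[str], reml: bool = True):
        """Fit the requested random-intercept structure.

        Crossed structures use the single-group variance-component
        parameterization; a lone component uses the canonical
        groups-based form, which is better behaved near the boundary.
        """
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(comps) == 1:
                model = smf.mixedlm(
                    formula, data=df, groups=vc_columns[comps[0]]
                )
                result = model.fit(reml=reml, method="lbfgs")
                vcomp = {comps[0]: float(result.cov_re.iloc[0, 0])}
            else:
                vc = {label: f"0 + C({vc_columns[label]})" for label in comps}
                model = smf.mixedlm(
                    formula, data=df, groups="_grp", vc_formula=vc, re_formula="0"
                )
                result = model.fit(reml=reml, method="lbfgs")
                vcomp = dict(
                    zip(model.exog_vc.names, np.asarray(result.vcomp, dtype=float))
                )
        return result, vcomp

    def _ml_loglike(comps: list[str]) -> float:
        if comps:
            return float(_fit_mixed(comps, reml=False)[0].llf)
        return float(smf.ols(formula, data=df).fit().llf)

    while True:
        if not components:
            log.append("no random components left; fitting OLS")
            ols = smf.ols(formula, data=df).fit()
            fe = _fe_table(ols.params, ols.bse, ols.tvalues, ols.df_resid, terms)
            return LmmResult(
                fixed_effects=fe,
                random_components={"residual": float(ols.scale)},
                selection_log=log,
                n_obs=len(df),
                n_dropped=n_dropped,
                method="OLS (all random components dropped)",
            )
        try:
            result, vcomp = _fit_mixed(components)
            fit_ok = True
        except (np.linalg.LinAlgError, ValueError):
            fit_ok = False
        if not fit_ok:
            weakest, reason = components[-1], "fit raised a numerical error"
            log.append(f"dropped {weakest}: {reason}")
            logger.info("random-structure reduction: %s", log[-1])
            components = [c for c in components if c != weakest]
            continue

        converged = bool(getattr(result, "converged", True))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if not np.isfinite(np.asarray(result.bse_fe, dtype=float)).all():
                converged = False  # singular: no usable fixed-effect SEs
        ordered = sorted(vcomp, key=vcomp.get)
        weakest = ordered[0]
        if not converged:
            reason = "fit did not converge (singular structure suspected)"
        elif vcomp[weakest] < var_floor:
            reason = f"variance {vcomp[weakest]:.3g} < {var_floor:g}"
        else:
            # near-zero components: confirm by an ML likelihood-ratio check
            dropped = None
            candidates = [c for c in ordered if vcomp[c] < screen_ratio * result.scale]
            for cand in candidates:
                reduced = [c for c in components if c != cand]
                lrt = 2.0 * (_ml_loglike(components) - _ml_loglike(reduced))
                if math.isnan(lrt):
                    lrt = -math.inf  # degenerate comparison: prefer simpler
                if lrt < lrt_cutoff:
                    dropped = cand
                    reason = (
                        f"variance {vcomp[cand]:.3g} below screen "
                        f"({screen_ratio:g} x residual) and LRT {lrt:.2f} < "
                        f"{lrt_cutoff:g}"
                    )
                    break
                log.append(
                    f"kept {cand}: variance {vcomp[cand]:.3g} below screen but "
                    f"LRT {lrt:.2f} >= {lrt_cutoff:g}"
                )
            if dropped is None:
                df_resid = len(df) - len(terms)
                fe = _fe_table(
                    result.fe_params, result.bse_fe, result.tvalues[terms],
                    df_resid, terms,
                )
                rc = {k: float(v) for k, v in vcomp.items()}
                rc["residual"] = float(result.scale)
                log.append(f"kept random components: {sorted(vcomp)}")
                return LmmResult(
                    fixed_effects=fe,
                    random_components=rc,
                    selection_log=log,
                    n_obs=len(df),
                    n_dropped=n_dropped,
                    method="REML mixed model",
                    converged=True,
                )
            weakest = dropped
        log.append(f"dropped {weakest}: {reason}")
        logger.info("random-structure reduction: %s", log[-1])
        components = [c for c in components if c != weakest]
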
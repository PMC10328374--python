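"""Cohort statistics: exact rank tests, group comparisons, mixed models,
post-hoc tests, ANCOVA, backward-AICc model selection, glucose summaries.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "wilcoxon_mann_whitney",
    "percent_difference",
    "round_half_away",
    "GroupComparison",
    "compare_groups",
    "MixedModelFit",
    "fit_lmm",
    "tukey_hsd",
    "levene",
    "linreg",
    "ancova_slopes",
    "ModelSelectionResult",
    "stepwise_aicc",
    "lifetime_average_glucose",
    "diabetic_inclusion_filter",
]


# ---------------------------------------------------------------- rank tests

def _rankdata_midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def wilcoxon_mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 20
) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    For pooled sample sizes up to ``exact_limit`` the p-value is computed by
    full enumeration of all labelings of the mid-ranked pooled sample
    (tie-correct); larger samples fall back to the normal approximation with
    tie correction.  Two-sided p is 2 * min(tail) capped at 1.

    Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    ranks = _rankdata_midranks(pooled)
    rx = ranks[:nx].sum()
    u = rx - nx * (nx + 1) / 2.0

    if nx + ny <= exact_limit:
        n = nx + ny
        base = nx * (nx + 1) / 2.0
        stats = np.fromiter(
            (sum(ranks[list(c)]) - base for c in itertools.combinations(range(n), nx)),
            dtype=float,
            count=math.comb(n, nx),
        )
        total = len(stats)
        eps = 1e-9
        p_low = np.sum(stats <= u + eps) / total
        p_high = np.sum(stats >= u - eps) / total
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return float(u), float(p)


def round_half_away(value: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    return int(math.floor(abs(value) + 0.5) * (1 if value >= 0 else -1))


def percent_difference(mean_treated: float, mean_control: float) -> float:
    """100 (treated - control) / control.  Unrounded; see round_half_away."""
    if mean_control == 0:
        raise ValueError("control mean is zero; percent difference undefined")
    return 100.0 * (mean_treated - mean_control) / mean_control


@dataclass
class GroupComparison:
    outcome: str
    mean_control: float
    sd_control: float
    mean_treated: float
    sd_treated: float
    percent_difference: float        # unrounded
    percent_difference_rounded: int
    U: float
    p: float


def compare_groups(
    table: pd.DataFrame,
    outcome: str,
    group_col: str = "genotype",
    control: str = "C57Bl/6J",
    treated: str = "TallyHO",
) -> GroupComparison:
    """Table-style two-group comparison: means, SDs, % difference, exact WMW p."""
    sub = table[[group_col, outcome]].dropna()
    xc = sub.loc[sub[group_col] == control, outcome].to_numpy(dtype=float)
    xt = sub.loc[sub[group_col] == treated, outcome].to_numpy(dtype=float)
    u, p = wilcoxon_mann_whitney(xt, xc)
    pct = percent_difference(xt.mean(), xc.mean())
    return GroupComparison(
        outcome=outcome,
        mean_control=float(xc.mean()),
        sd_control=float(xc.std(ddof=1)),
        mean_treated=float(xt.mean()),
        sd_treated=float(xt.std(ddof=1)),
        percent_difference=pct,
        percent_difference_rounded=round_half_away(pct),
        U=u,
        p=p,
    )


# ---------------------------------------------------------------- mixed model

@dataclass
class MixedModelFit:
    fixed_effects: pd.DataFrame         # estimate, SE, z, p, CI bounds
    variance_components: dict
    loglike: float
    qq_correlation: float
    levene_p: Optional[float]
    converged: bool
    singular: bool
    model: object = field(repr=False, default=None)


def fit_lmm(
    table: pd.DataFrame,
    outcome: str,
    fixed: Sequence[str] = ("genotype", "quadrant", "region", "microstructure"),
    group: str = "mouse",
    nested: Sequence[str] = ("quadrant", "region"),
    levene_factor: str = "genotype",
) -> MixedModelFit:
    """REML linear mixed model with nested random intercepts.

    Random structure: intercept per ``group`` (mouse) plus variance components
    for each level of the nesting chain (quadrant within mouse, region within
    quadrant).  Residual diagnostics: Q-Q quantile correlation of residuals
    against normal quantiles, and a Levene test across ``levene_factor``.
    """
    data = table.dropna(subset=[outcome]).copy()
    fixed = [f for f in fixed if data[f].nunique() > 1]
    if not fixed:
        raise ValueError("no fixed factor has at least 2 levels")
    formula = f"{outcome} ~ " + " + ".join(f"C({f})" for f in fixed)

    vc = {}
    prev = None
    for level in nested:
        if level not in data.columns:
            continue
        key = level if prev is None else f"{prev}_{level}"
        if prev is None:
            vc[level] = f"0 + C({level})"
        else:
            data[key] = data[prev].astype(str) + ":" + data[level].astype(str)
            vc[level] = f"0 + C({key})"
        prev = key

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, data, groups=data[group], re_formula="1",
            vc_formula=vc if vc else None,
        )
        # powell is slower than lbfgs but does not silently misconverge when a
        # variance component sits on the zero boundary
        fit = model.fit(reml=True, method=["powell"])

    # containment degrees of freedom: effects constant within a group (mouse)
    # are tested against the number of groups, not the number of rows
    exog = pd.DataFrame(model.exog, columns=model.exog_names)
    exog["_g"] = data[group].to_numpy()
    n_groups = data[group].nunique()
    between = {
        name: (exog.groupby("_g")[name].nunique() == 1).all()
        for name in model.exog_names
    }
    n_between = sum(between.values())
    rows = {}
    for name in model.exog_names:
        est = float(fit.fe_params[name])
        se = float(fit.bse_fe[name])
        df_c = (n_groups - n_between) if between[name] else (len(data) - len(model.exog_names))
        df_c = max(df_c, 1)
        tval = est / se
        p = 2 * sps.t.sf(abs(tval), df_c)
        half = sps.t.ppf(0.975, df_c) * se
        rows[name] = {
            "estimate": est, "se": se, "df": df_c, "p": p,
            "ci_low": est - half, "ci_high": est + half,
        }
    fe = pd.DataFrame(rows).T

    vcomp = {"mouse": float(fit.cov_re.iloc[0, 0])}
    for i, name in enumerate(vc):
        vcomp[name] = float(fit.vcomp[i])
    vcomp["residual"] = float(fit.scale)
    singular = any(v < 1e-8 for v in vcomp.values())

    # marginal residuals (endog - X beta); avoids predicting random effects,
    # which fails when a variance component collapses to zero
    marginal = np.asarray(model.endog) - model.exog @ np.asarray(fit.fe_params)
    resid = np.sort(marginal)
    theo = sps.norm.ppf((np.arange(1, len(resid) + 1) - 0.5) / len(resid))
    qq_r = float(np.corrcoef(resid, theo)[0, 1])

    lev_p = None
    if levene_factor in data.columns and data[levene_factor].nunique() > 1:
        groups = [
            marginal[data[levene_factor].to_numpy() == lev]
            for lev in data[levene_factor].unique()
        ]
        _, lev_p = levene(groups)

    return MixedModelFit(
        fixed_effects=fe,
        variance_components=vcomp,
        loglike=float(fit.llf),
        qq_correlation=qq_r,
        levene_p=lev_p,
        converged=bool(fit.converged),
        singular=singular,
        model=fit,
    )


def tukey_hsd(
    table: pd.DataFrame, outcome: str, factor: str
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons across the levels of one factor.

    Studentized-range adjusted p-values on the observed (possibly per-mouse
    aggregated) data.
    """
    sub = table.dropna(subset=[outcome])
    levels = list(sub[factor].unique())
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    samples = [sub.loc[sub[factor] == lev, outcome].to_numpy(dtype=float) for lev in levels]
    res = sps.tukey_hsd(*samples)
    rows = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        rows.append(
            {
                "level_a": levels[i],
                "level_b": levels[j],
                "difference": float(np.mean(samples[i]) - np.mean(samples[j])),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return pd.DataFrame(rows)


def levene(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Levene test on absolute deviations from group means (mean-centered)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Levene test needs at least 2 groups")
    w, p = sps.levene(*groups, center="mean")
    return float(w), float(p)


# ---------------------------------------------------------------- regressions

def linreg(x: Sequence[float], y: Sequence[float]) -> dict:
    """Ordinary least squares y on x with slope t-test.

    Returns dict with slope, intercept, r, R2, p, stderr.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if len(x) == 2:
        warnings.warn("regression on 2 points is degenerate (R^2 = 1)")
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "R2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "stderr": float(res.stderr),
    }


def ancova_slopes(
    x: Sequence[float], y: Sequence[float], group: Sequence
) -> dict:
    """p-value of the group-by-x interaction in a two-group linear model."""
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "g": np.asarray(group)})
    counts = df.groupby("g").size()
    if (counts < 3).any():
        raise ValueError("each group needs at least 3 points for ANCOVA")
    fit = smf.ols("y ~ x * C(g)", data=df).fit()
    inter = [t for t in fit.params.index if t.startswith("x:")]
    if len(inter) != 1:
        raise ValueError("expected exactly two groups")
    term = inter[0]
    return {
        "interaction_estimate": float(fit.params[term]),
        "interaction_se": float(fit.bse[term]),
        "interaction_p": float(fit.pvalues[term]),
        "model": fit,
    }


# ------------------------------------------------------------ model selection

@dataclass
class ModelSelectionResult:
    selected: list
    coefficients: dict
    R2: float
    aicc: float
    trace: list  # (predictor set, AICc) visited in order


def _aicc_ols(y: np.ndarray, X: np.ndarray) -> tuple[float, object]:
    fit = sm.OLS(y, X).fit()
    k = X.shape[1] + 1  # coefficients (incl. intercept) + error variance
    n = len(y)
    aic = -2 * fit.llf + 2 * k
    if n - k - 1 <= 0:
        return np.inf, fit
    return aic + 2 * k * (k + 1) / (n - k - 1), fit


def stepwise_aicc(
    table: pd.DataFrame, response: str, candidates: Sequence[str]
) -> ModelSelectionResult:
    """Backward elimination minimizing AICc.

    Starts from the full candidate set and removes the predictor whose
    removal lowers AICc the most; stops when no removal lowers AICc.  Ties
    (within 1e-9) are broken in favor of the smaller model.
    """
    data = table.dropna(subset=[response, *candidates])
    y = data[response].to_numpy(dtype=float)
    current = list(candidates)

    def design(preds):
        X = np.column_stack([np.ones(len(y))] + [data[p].to_numpy(float) for p in preds])
        return X

    aicc, fit = _aicc_ols(y, design(current))
    trace = [(tuple(current), aicc)]
    while current:
        removals = []
        for p in current:
            reduced = [q for q in current if q != p]
            a, _ = _aicc_ols(y, design(reduced))
            trace.append((tuple(reduced), a))
            removals.append((a, p))
        best_aicc, best_candidate = min(removals, key=lambda t: t[0])
        # remove on ties as well: prefer the smaller model
        if best_aicc <= aicc + 1e-9:
            current.remove(best_candidate)
            aicc = best_aicc
        else:
            break

    _, fit = _aicc_ols(y, design(current))
    coefs = {"intercept": float(fit.params[0])}
    for i, p in enumerate(current):
        coefs[p] = float(fit.params[i + 1])
    r2 = float(fit.rsquared) if current else 0.0
    return ModelSelectionResult(
        selected=current, coefficients=coefs, R2=r2, aicc=aicc, trace=trace
    )


# ----------------------------------------------------------------- glucose

def lifetime_average_glucose(weekly: Sequence[float]) -> tuple[float, int]:
    """Mean of the available weekly glucose values; returns (mean, n_missing)."""
    arr = np.asarray(weekly, dtype=float)
    present = arr[~np.isnan(arr)]
    if present.size == 0:
        raise ValueError("no glucose measurements available")
    return float(present.mean()), int(np.isnan(arr).sum())


def diabetic_inclusion_filter(
    glucose: pd.DataFrame,
    threshold: float = 250.0,
    genotype_col: str = "genotype",
    diabetic_genotype: str = "TallyHO",
    mouse_col: str = "mouse",
    value_col: str = "glucose",
) -> list:
    """Mouse ids to retain: diabetic mice must keep every weekly glucose above
    the threshold; control mice are always retained.
    """
    keep = []
    for mouse, sub in glucose.groupby(mouse_col):
        if (sub[genotype_col] == diabetic_genotype).any():
            if sub[value_col].min() <= threshold:
                continue
        keep.append(mouse)
    return keep
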
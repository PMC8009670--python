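"""Estimation statistics: Hedges' g with BCa bootstrap intervals, Welch's
t, regression with slope CIs, ANCOVA with an interaction screen, and PCA
of the standardized feature table.

Effect sizes follow the estimation-statistics convention: the point
estimate is the small-sample-corrected standardized mean difference

    g = J(df) * (mean2 - mean1) / s_pooled,
    s_pooled = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / df),  df = n1 + n2 - 2,

with the exact gamma-ratio bias correction J (the classic 1 - 3/(4 df - 1)
approximation is also available).  95% confidence intervals are
bias-corrected and accelerated (BCa) bootstrap intervals over independent
per-group resampling, 5000 resamples by default.  Welch's t statistic is
reported alongside for information, as (mean1 - mean2)/SE with both the
Welch-Satterthwaite and the pooled degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "EffectSize",
    "RegressionResult",
    "PCAResult",
    "hedges_correction",
    "hedges_g_from_summary",
    "welch_from_summary",
    "hedges_g",
    "regress_with_ci",
    "regress_vs_age",
    "ancova_pic_conductance",
    "pca_features",
    "DegenerateSamplesError",
]

log = logging.getLogger("picquant.stats")

DAYS_PER_WEEK = 7.0


class DegenerateSamplesError(ValueError):
    """Zero pooled SD with unequal means: the effect size is infinite."""


def hedges_correction(df: float, method: str = "exact") -> float:
    """Small-sample bias correction J(df).

    ``exact``: gamma-ratio form J = Gamma(df/2) / (sqrt(df/2) Gamma((df-1)/2));
    ``approx``: 1 - 3/(4 df - 1).  They agree to 3 decimals for df >= 10.
    """
    if df <= 1:
        raise ValueError("correction needs df > 1")
    if method == "approx":
        return 1.0 - 3.0 / (4.0 * df - 1.0)
    if method == "exact":
        return math.exp(
            gammaln(df / 2.0) - gammaln((df - 1.0) / 2.0) - 0.5 * math.log(df / 2.0)
        )
    raise ValueError(f"unknown correction method {method!r}")


def hedges_g_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    correction: str = "exact",
) -> float:
    """Hedges' g of group 2 relative to group 1 from summary moments."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    s_pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    diff = mean2 - mean1
    if s_pooled == 0:
        if diff == 0:
            return 0.0
        raise DegenerateSamplesError(
            "zero pooled SD with unequal means: infinite effect size"
        )
    return hedges_correction(df, correction) * diff / s_pooled


def welch_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple:
    """Welch's t (as mean1 - mean2 over its SE), Welch-Satterthwaite df,
    and two-sided p."""
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = math.sqrt(v1 + v2)
    if se == 0:
        raise DegenerateSamplesError("zero variance in both groups")
    t = (mean1 - mean2) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p


@dataclass
class EffectSize:
    """Hedges' g with BCa bootstrap CI and Welch's t for one two-group
    comparison (group2 - group1 convention)."""

    g: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    welch_t: float
    welch_df: float
    df_pooled: int
    p: float
    n_boot: int
    bootstrap_distribution: Optional[np.ndarray] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k != "bootstrap_distribution"
        }
        return d


def _g_statistic(x, y, axis=-1):
    """Vectorized Hedges' g (exact correction) for bootstrap resampling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = x.shape[axis]
    n2 = y.shape[axis]
    df = n1 + n2 - 2
    m1 = np.mean(x, axis=axis)
    m2 = np.mean(y, axis=axis)
    v1 = np.var(x, axis=axis, ddof=1)
    v2 = np.var(y, axis=axis, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / df)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m2 - m1) / sp
    return hedges_correction(df) * d


def hedges_g(
    sample1: Sequence[float],
    sample2: Sequence[float],
    n_boot: int = 5000,
    seed: Optional[int] = None,
    keep_distribution: bool = False,
) -> EffectSize:
    """Hedges' g of ``sample2`` relative to ``sample1`` with a 95% BCa
    bootstrap confidence interval (independent per-group resampling)."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    m1, m2 = float(np.mean(x)), float(np.mean(y))
    s1, s2 = float(np.std(x, ddof=1)), float(np.std(y, ddof=1))
    g = hedges_g_from_summary(m1, s1, x.size, m2, s2, y.size)
    if s1 == 0 and s2 == 0:
        # fully degenerate with equal means: Welch undefined
        wt, wdf, p = float("nan"), float("nan"), float("nan")
    else:
        wt, wdf, p = welch_from_summary(m1, s1, x.size, m2, s2, y.size)
    rng = np.random.default_rng(seed)
    dist = None
    if s1 == 0 and s2 == 0:
        # degenerate with equal means (unequal means raised above)
        lo = hi = g
        if keep_distribution:
            dist = np.full(n_boot, g)
    else:
        res = sps.bootstrap(
            (x, y),
            _g_statistic,
            n_resamples=n_boot,
            vectorized=True,
            paired=False,
            method="BCa",
            confidence_level=0.95,
            rng=rng,
        )
        boot = res.bootstrap_distribution
        finite = boot[np.isfinite(boot)]
        if finite.size and np.ptp(finite) == 0:
            lo = hi = float(finite[0])
        else:
            lo = float(res.confidence_interval.low)
            hi = float(res.confidence_interval.high)
        if keep_distribution:
            dist = boot
    return EffectSize(
        g=g, ci_low=lo, ci_high=hi,
        n1=x.size, n2=y.size,
        mean1=m1, mean2=m2, sd1=s1, sd2=s2,
        welch_t=wt, welch_df=float(wdf), df_pooled=x.size + y.size - 2, p=float(p),
        n_boot=n_boot, bootstrap_distribution=dist,
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r2: float
    p: float
    n: int


def regress_with_ci(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with a 95% t-based CI on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant x: rank-deficient design")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = model.conf_int(alpha=0.05)[1]
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        ci_low=float(lo),
        ci_high=float(hi),
        r2=float(model.rsquared),
        p=float(model.pvalues[1]),
        n=int(x.size),
    )


def regress_vs_age(age_days: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Regression against age expressed in weeks (slope in units/week)."""
    return regress_with_ci(np.asarray(age_days, dtype=float) / DAYS_PER_WEEK, y)


def ancova_pic_conductance(
    table: pd.DataFrame,
    response: str = "pic_amplitude_asc",
    covariate: str = "input_conductance",
    alpha_interaction: float = 0.05,
) -> dict:
    """ANCOVA of PIC amplitude on input conductance by genotype.

    Fits ``response ~ covariate * genotype``; when the interaction is not
    significant at ``alpha_interaction`` the additive model is refit and
    the genotype effect (mSOD1 - WT at fixed conductance) reported with
    its CI.  The covariate is mean-centred so that, should the
    interaction be retained, the genotype coefficient is the group
    difference at the mean conductance rather than an extrapolation to
    zero conductance.
    """
    cols = [response, covariate, "genotype"]
    data = table[cols].dropna()
    counts = data["genotype"].value_counts()
    if len(counts) < 2 or counts.min() < 3:
        raise ValueError("ANCOVA needs both genotypes with >= 3 cells each")
    data = data.rename(columns={response: "_y", covariate: "_x"})
    data["_x"] = data["_x"] - data["_x"].mean()
    full = smf.ols('_y ~ _x * C(genotype, Treatment("WT"))', data=data).fit()
    inter = [t for t in full.params.index if ":" in t][0]
    report = {
        "interaction_t": float(full.tvalues[inter]),
        "interaction_p": float(full.pvalues[inter]),
        "interaction_df": int(full.df_resid),
        "interaction_coef": float(full.params[inter]),
    }
    if report["interaction_p"] >= alpha_interaction:
        model = smf.ols('_y ~ _x + C(genotype, Treatment("WT"))', data=data).fit()
        report["model"] = "additive"
    else:
        model = full
        report["model"] = "interaction"
    geno = [t for t in model.params.index if "genotype" in t and ":" not in t][0]
    lo, hi = model.conf_int().loc[geno]
    report.update(
        genotype_effect=float(model.params[geno]),
        genotype_ci_low=float(lo),
        genotype_ci_high=float(hi),
        genotype_t=float(model.tvalues[geno]),
        genotype_p=float(model.pvalues[geno]),
        df_resid=int(model.df_resid),
        n=int(len(data)),
    )
    return report


@dataclass
class PCAResult:
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # feature x component correlations
    scores: pd.DataFrame  # cell x component
    n_components: int
    n_dropped: int


def pca_features(
    table: pd.DataFrame,
    feature_columns: Optional[Sequence[str]] = None,
    n_components: int = 5,
) -> PCAResult:
    """PCA of the z-scored feature table (complete-case rows).

    Features are centred and scaled (ddof 1) before projection; loadings
    are the Pearson correlations between each feature and each component
    score, which is what a loading heatmap displays.
    """
    from sklearn.decomposition import PCA

    from .pipeline import FEATURE_COLUMNS

    feats = list(feature_columns) if feature_columns is not None else FEATURE_COLUMNS
    data = table[feats].dropna()
    n_dropped = len(table) - len(data)
    if n_dropped:
        log.info("PCA: dropped %d incomplete cells", n_dropped)
    if len(data) < 6:
        raise ValueError("PCA needs at least 6 complete-case cells")
    sds = data.std(ddof=1)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance feature(s): {', '.join(zero)}")
    z = (data - data.mean()) / sds
    k = min(n_components, len(feats), len(data) - 1)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(
        np.array(
            [[np.corrcoef(z[f], scores[:, j])[0, 1] for j in range(k)] for f in feats]
        ),
        index=feats,
        columns=comp_names,
    )
    # ratios over the total variance of all features, not just retained
    ratios = pca.explained_variance_ / z.var(ddof=1).sum()
    return PCAResult(
        explained_variance_ratio=np.asarray(ratios),
        loadings=loadings,
        scores=pd.DataFrame(scores, index=data.index, columns=comp_names),
        n_components=k,
        n_dropped=n_dropped,
    )
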
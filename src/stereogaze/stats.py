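"""Inferential layer: random-intercept regression, rank correlation,
paired t tests, and subject-intercept-corrected vergence error.

The random-intercept model ``y = b0 + b1 x + u_subject + e`` (Gaussian
random intercepts, REML) captures a per-subject fixation disparity as a
constant vergence offset while the fixed effects capture the tracker's
systematic behaviour.  Fitting delegates to statsmodels MixedLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .vergence import vergence_mae


@dataclass
class MixedFitResult:
    fixed_intercept: float
    fixed_intercept_se: float
    fixed_slope: float
    fixed_slope_se: float
    slope_ci95: tuple[float, float]
    random_intercept_sd: float
    subject_intercepts: dict = field(default_factory=dict)  # b0 + u_s per subject
    p_intercept: float = np.nan
    p_slope: float = np.nan
    converged: bool = True


def fit_random_intercept(x, y, subject) -> MixedFitResult:
    """Fit ``y ~ x`` with a Gaussian random intercept per subject (REML)."""
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "subject": np.asarray(subject)})
    df = df.dropna()
    groups = df["subject"].unique()
    if len(groups) < 2:
        raise ValueError("random-intercept fit needs at least 2 subjects")
    if df.groupby("subject").size().min() < 3:
        raise ValueError("each subject needs at least 3 observations")
    if np.allclose(df["x"].var(), 0.0):
        raise ValueError("singular design: x has no variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("y ~ x", df, groups=df["subject"])
        fit = model.fit(reml=True)
    b0 = float(fit.params["Intercept"])
    b1 = float(fit.params["x"])
    re_sd = float(np.sqrt(max(fit.cov_re.values[0, 0], 0.0)))
    se1 = float(fit.bse["x"])
    z = scipy.stats.norm.ppf(0.975)
    try:
        subj_int = {
            g: b0 + float(np.asarray(re).ravel()[0])
            for g, re in fit.random_effects.items()
        }
    except (np.linalg.LinAlgError, ValueError):
        # zero random-effect variance: conditional means collapse to b0
        subj_int = {g: b0 for g in groups}
    return MixedFitResult(
        fixed_intercept=b0,
        fixed_intercept_se=float(fit.bse["Intercept"]),
        fixed_slope=b1,
        fixed_slope_se=se1,
        slope_ci95=(b1 - z * se1, b1 + z * se1),
        random_intercept_sd=re_sd,
        subject_intercepts=subj_int,
        p_intercept=float(fit.pvalues["Intercept"]),
        p_slope=float(fit.pvalues["x"]),
        converged=bool(fit.converged),
    )


def subject_corrected_mae(
    alpha_measured, alpha_target, subject, fit: MixedFitResult | None = None
) -> float:
    """Vergence MAE after subtracting each subject's estimated intercept
    (fixed + random deviation) from the measured vergence — removing the
    constant-offset part of fixation disparity."""
    m = np.asarray(alpha_measured, float)
    t = np.asarray(alpha_target, float)
    s = np.asarray(subject)
    if fit is None:
        fit = fit_random_intercept(t, m, s)
    offsets = np.array([fit.subject_intercepts.get(g, fit.fixed_intercept) for g in s])
    return vergence_mae(m - offsets, t)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) and its p-value.
    Degenerate (constant) input gives (nan, nan) with a warning."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("spearman_rho needs at least 4 valid pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman correlation is undefined")
        return np.nan, np.nan
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def paired_t(a, b) -> tuple[float, float]:
    """Paired t test on the differences ``a - b``.

    Zero-variance differences are handled explicitly: identical series give
    (0, 1); a constant nonzero difference gives (+/-inf, 0) — a degenerate
    'certain' effect that scipy would report as NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired_t needs equal-length series")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2:
        raise ValueError("paired_t needs at least 2 valid pairs")
    d = a - b
    if np.allclose(np.std(d, ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), float(p)
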
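"""Group comparisons of ISC between conditions, segments and regions.

ISC values are correlations, so by default they are Fisher-z transformed
(variance stabilized) before entering t statistics or ANOVA; raw-scale
variants are available since averaging conventions differ across studies.
Multiple comparisons across ROIs are handled by a sign-flipping max-|t|
randomization: under the paired null each subject's difference row is
symmetric around zero, so flipping row signs regenerates the null, and
thresholding at the upper quantile of the maximum |t| across ROIs
controls the family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    AlignmentError,
    ConfigError,
    DegenerateInputError,
    DimensionError,
)
from .isc_core import IscMatrix, global_isc

__all__ = [
    "ContrastResult",
    "PairedTestResult",
    "AnovaResult",
    "paired_t",
    "sign_flip_maxT",
    "two_way_anova",
    "compare_global_isc",
]


@dataclass
class ContrastResult:
    """Per-ROI statistics with an FWER-corrected threshold from sign flipping."""

    roi_ids: tuple[str, ...]
    statistic_values: np.ndarray
    dof: float
    corrected_threshold: float
    significant: np.ndarray
    p_corrected: np.ndarray
    method: str
    n_randomizations: int


@dataclass
class PairedTestResult:
    """Outcome of a paired t comparison."""

    t: float
    dof: int
    p_value: float
    alternative: str
    mean_difference: float


@dataclass
class AnovaResult:
    """Two-way fixed-effects ANOVA summary (factors A, B and interaction)."""

    f_a: float
    f_b: float
    f_interaction: float | None
    dof_a: tuple[int, int]
    dof_b: tuple[int, int]
    dof_interaction: tuple[int, int] | None
    p_a: float
    p_b: float
    p_interaction: float | None


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Paired t statistic and its degrees of freedom.

    ``t = mean(a - b) / (sd(a - b) / sqrt(n))`` with the ``n - 1``
    denominator in the standard deviation; ``dof = n - 1``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DimensionError("paired_t expects two 1-D vectors of equal length")
    if a.size < 2:
        raise DegenerateInputError("paired_t needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    # relative tolerance: a constant difference leaves only rounding noise
    if not np.isfinite(sd) or sd <= 1e-12 * max(np.abs(d).max(), 1e-300):
        raise DegenerateInputError("paired differences have (near-)zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1)


def _columnwise_t(diff: np.ndarray) -> np.ndarray:
    """One-sample t per column of a (subjects x ROIs) difference matrix."""
    n = diff.shape[-2]
    mean = diff.mean(axis=-2)
    sd = diff.std(axis=-2, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return mean / (sd / np.sqrt(n))


def sign_flip_maxT(
    diff: np.ndarray,
    n_randomizations: int = 10000,
    q: float = 0.05,
    seed: int = 0,
    roi_ids: tuple[str, ...] = (),
    exact: bool = False,
) -> ContrastResult:
    """Paired t per ROI with max-|t| FWER correction by sign flipping.

    ``diff`` holds per-subject paired differences (subjects x ROIs; apply
    any Fisher-z transform upstream).  The null flips each subject's row
    sign at random and records the maximum |t| across ROIs; the corrected
    threshold is the upper ``1 - q`` quantile of those maxima and a ROI is
    significant iff its observed |t| strictly exceeds it.

    With ``exact=True`` all ``2^n_subjects`` sign patterns are enumerated
    (feasible for small groups); corrected p-values are then exact
    permutation probabilities ``#{max |t| >= observed} / 2^n`` (the
    identity pattern guarantees p > 0).  Otherwise Monte-Carlo sampling
    with add-one counting is used.
    """
    diff = np.asarray(diff, dtype=float)
    if diff.ndim != 2:
        raise DimensionError("diff must be a subjects x ROIs matrix")
    n_subjects, n_rois = diff.shape
    if n_subjects < 2:
        raise DegenerateInputError("need at least 2 subjects")
    sd = diff.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateInputError(
            f"ROI column(s) {np.nonzero(sd == 0)[0].tolist()} have zero variance"
        )
    if not (0 < q < 1):
        raise ConfigError(f"q must be in (0, 1), got {q}")
    roi_ids = roi_ids or tuple(f"roi-{i + 1:03d}" for i in range(n_rois))
    if len(roi_ids) != n_rois:
        raise DimensionError("roi_ids length does not match diff columns")

    t_obs = _columnwise_t(diff)
    abs_obs = np.abs(t_obs)

    if exact:
        if n_subjects > 20:
            raise ConfigError("exact enumeration limited to <= 20 subjects")
        n_patterns = 2**n_subjects
        bits = (np.arange(n_patterns)[:, None] >> np.arange(n_subjects)) & 1
        signs = 2.0 * bits - 1.0  # (patterns, subjects)
        max_abs_t = np.abs(
            _columnwise_t(signs[:, :, None] * diff[None])
        ).max(axis=-1)
        n_ge = (max_abs_t[:, None] >= abs_obs[None, :]).sum(axis=0)
        p = n_ge / n_patterns
        n_rand = n_patterns
        method = "sign-flip max-|t| (exact enumeration)"
    else:
        rng = np.random.default_rng(seed)
        max_abs_t = np.empty(n_randomizations)
        chunk = max(1, min(n_randomizations, 4_000_000 // max(1, diff.size)))
        pos = 0
        while pos < n_randomizations:
            b = min(chunk, n_randomizations - pos)
            signs = rng.integers(0, 2, size=(b, n_subjects)) * 2.0 - 1.0
            flipped = signs[:, :, None] * diff[None]
            max_abs_t[pos : pos + b] = np.abs(_columnwise_t(flipped)).max(axis=-1)
            pos += b
        n_ge = (max_abs_t[:, None] >= abs_obs[None, :]).sum(axis=0)
        p = (1.0 + n_ge) / (1.0 + n_randomizations)
        n_rand = n_randomizations
        method = "sign-flip max-|t| (Monte Carlo)"

    threshold = float(np.quantile(max_abs_t, 1.0 - q))
    return ContrastResult(
        roi_ids=roi_ids,
        statistic_values=t_obs,
        dof=float(n_subjects - 1),
        corrected_threshold=threshold,
        significant=abs_obs > threshold,
        p_corrected=p,
        method=method,
        n_randomizations=n_rand,
    )


def two_way_anova(
    values: np.ndarray, factor_a: Sequence, factor_b: Sequence
) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction.

    Observations are treated as independent across cells (no repeated-
    measures structure).  Sums of squares are sequential (Type I) in the
    order A, B, A:B; for balanced layouts all classical types coincide.
    If a factor has a single level the interaction is undefined and a
    one-way ANOVA on the other factor is returned in its slot.
    """
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.ndim == 1 and y.shape == fa.shape == fb.shape):
        raise DimensionError("values and factor labels must be equal-length vectors")
    levels_a, levels_b = np.unique(fa), np.unique(fb)
    if levels_a.size < 2 and levels_b.size < 2:
        raise DegenerateInputError("both factors have a single level")
    if np.ptp(y) == 0:
        # All observations identical: every sum of squares is zero, so all
        # F ratios are taken as 0 rather than 0/0.
        d_a, d_b = int(levels_a.size - 1), int(levels_b.size - 1)
        d_ab = d_a * d_b
        d_res = int(y.size - levels_a.size * levels_b.size)
        has_ab = d_a > 0 and d_b > 0
        return AnovaResult(
            f_a=0.0, f_b=0.0, f_interaction=0.0 if has_ab else None,
            dof_a=(d_a, d_res), dof_b=(d_b, d_res),
            dof_interaction=(d_ab, d_res) if has_ab else None,
            p_a=1.0, p_b=1.0, p_interaction=1.0 if has_ab else None,
        )

    frame = pd.DataFrame({"y": y, "a": fa.astype(str), "b": fb.astype(str)})
    if levels_a.size < 2 or levels_b.size < 2:
        # Single-level factor: collapse to a one-way ANOVA on the other.
        active = "a" if levels_a.size >= 2 else "b"
        model = ols(f"y ~ C({active})", data=frame).fit()
        table = sm.stats.anova_lm(model, typ=1)
        _check_residual(table)
        row = table.loc[f"C({active})"]
        resid = table.loc["Residual"]
        one_way = (
            float(row["F"]),
            (int(row["df"]), int(resid["df"])),
            float(row["PR(>F)"]),
        )
        f_a, dof_a, p_a = one_way if active == "a" else (np.nan, (0, 0), np.nan)
        f_b, dof_b, p_b = one_way if active == "b" else (np.nan, (0, 0), np.nan)
        return AnovaResult(
            f_a=f_a, f_b=f_b, f_interaction=None,
            dof_a=dof_a, dof_b=dof_b, dof_interaction=None,
            p_a=p_a, p_b=p_b, p_interaction=None,
        )

    model = ols("y ~ C(a) + C(b) + C(a):C(b)", data=frame).fit()
    import warnings as _warnings

    with _warnings.catch_warnings():
        # degenerate layouts divide by zero residual dof before we reject them
        _warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(model, typ=1)
    _check_residual(table)
    resid_df = int(table.loc["Residual", "df"])

    def _eff(name):
        row = table.loc[name]
        return float(row["F"]), (int(row["df"]), resid_df), float(row["PR(>F)"])

    f_a, dof_a, p_a = _eff("C(a)")
    f_b, dof_b, p_b = _eff("C(b)")
    f_ab, dof_ab, p_ab = _eff("C(a):C(b)")
    return AnovaResult(
        f_a=f_a, f_b=f_b, f_interaction=f_ab,
        dof_a=dof_a, dof_b=dof_b, dof_interaction=dof_ab,
        p_a=p_a, p_b=p_b, p_interaction=p_ab,
    )


def _check_residual(table) -> None:
    resid = table.loc["Residual"]
    if resid["df"] <= 0 or not np.isfinite(resid["sum_sq"]):
        raise DegenerateInputError("no residual degrees of freedom")
    if resid["sum_sq"] <= 0:
        raise DegenerateInputError("zero residual variance")


def compare_global_isc(
    m_a: IscMatrix,
    m_b: IscMatrix,
    use_fisher: bool = True,
    alternative: str = "two-sided",
) -> PairedTestResult:
    """Paired comparison of per-subject global (whole-brain mean) ISC.

    Each subject contributes one global ISC per matrix; the two samples
    are compared with a paired t-test, on the Fisher-z scale by default.
    """
    if m_a.subject_ids != m_b.subject_ids:
        raise AlignmentError("the two ISC matrices cover different subjects")
    if alternative not in ("two-sided", "greater", "less"):
        raise ConfigError(f"unknown alternative {alternative!r}")
    ga, gb = global_isc(m_a), global_isc(m_b)
    if use_fisher:
        ga, gb = np.arctanh(ga), np.arctanh(gb)
    t, dof = paired_t(ga, gb)
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), dof)
    elif alternative == "greater":
        p = stats.t.sf(t, dof)
    else:
        p = stats.t.cdf(t, dof)
    return PairedTestResult(
        t=t,
        dof=dof,
        p_value=float(p),
        alternative=alternative,
        mean_difference=float(np.mean(ga - gb)),
    )
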
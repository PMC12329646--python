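"""Sensitivity statistics: percent change, percentage-point difference,
cohort aggregation, paired t-tests and repeated-measures ANOVA.

The two sensitivity measures are

    %Change = |sigma_reduced - sigma_ref| / sigma_ref * 100         (per sample)
    PP_Difference = %Change_modified - %Change_normal               (per sample)

%Change is non-negative by definition (absolute value); a negative
PP_Difference therefore means the modified gait's stress response is LESS
sensitive to the strength reduction than normal gait, a positive one MORE
sensitive. Samples where the reference stress falls below a floor are masked
(NaN), not divided.

The repeated-measures ANOVA is the classical one-way within-subject
decomposition (subjects x conditions), with Bonferroni-corrected pairwise
paired t-tests as post hocs; for two conditions F equals the squared paired
t statistic. Significance is assessed at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidInputError

ALPHA = 0.05


def percent_change(sigma_reduced: np.ndarray, sigma_ref: np.ndarray,
                   floor: float = 0.01) -> np.ndarray:
    """Absolute percent change of a reduced-strength stress series relative
    to the reference series; NaN where the reference is at or below ``floor``
    (default 0.01 MPa)."""
    sigma_reduced = np.asarray(sigma_reduced, dtype=float)
    sigma_ref = np.asarray(sigma_ref, dtype=float)
    if sigma_reduced.shape != sigma_ref.shape:
        raise InvalidInputError("series must share a grid")
    out = np.full(sigma_ref.shape, np.nan)
    ok = sigma_ref > floor
    out[ok] = np.abs(sigma_reduced[ok] - sigma_ref[ok]) / sigma_ref[ok] * 100.0
    return out


def signed_percent_change(sigma_reduced: np.ndarray, sigma_ref: np.ndarray,
                          floor: float = 0.01) -> np.ndarray:
    """Signed counterpart of :func:`percent_change` (direction of effect)."""
    sigma_reduced = np.asarray(sigma_reduced, dtype=float)
    sigma_ref = np.asarray(sigma_ref, dtype=float)
    if sigma_reduced.shape != sigma_ref.shape:
        raise InvalidInputError("series must share a grid")
    out = np.full(sigma_ref.shape, np.nan)
    ok = sigma_ref > floor
    out[ok] = (sigma_reduced[ok] - sigma_ref[ok]) / sigma_ref[ok] * 100.0
    return out


def pp_difference(change_modified: np.ndarray,
                  change_normal: np.ndarray) -> np.ndarray:
    """Percentage-point difference between a modified gait's change curve and
    the normal gait's change curve (same strength condition)."""
    change_modified = np.asarray(change_modified, dtype=float)
    change_normal = np.asarray(change_normal, dtype=float)
    if change_modified.shape != change_normal.shape:
        raise InvalidInputError("change curves must share a grid")
    return change_modified - change_normal


@dataclass
class CohortCurves:
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int


def cohort_aggregate(curves: np.ndarray) -> CohortCurves:
    """Pointwise mean and t-based 95% CI across participants.

    ``curves`` is (n_participants, n_samples); NaN samples propagate.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise InsufficientDataError("need curves from >= 2 participants")
    n = curves.shape[0]
    mean = curves.mean(axis=0)
    se = curves.std(axis=0, ddof=1) / math.sqrt(n)
    tcrit = sps.t.ppf(0.975, n - 1)
    return CohortCurves(mean=mean, ci_low=mean - tcrit * se,
                        ci_high=mean + tcrit * se, n=n)


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    significant: bool
    infinite: bool = False


def paired_t(x: np.ndarray, y: np.ndarray) -> PairedTResult:
    """Two-sided paired t-test on the differences d = y - x.

    The sign convention makes t positive when y exceeds x on average.
    Zero-variance differences with a nonzero mean yield an infinite-t
    flagged result; identical inputs give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InsufficientDataError("need paired vectors of equal length >= 2")
    d = y - x
    n = d.size
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0, significant=False)
        t = math.inf if mean > 0 else -math.inf
        return PairedTResult(t=t, df=n - 1, p=0.0, significant=True,
                             infinite=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTResult(t=float(t), df=n - 1, p=float(p),
                         significant=bool(p < ALPHA))


@dataclass
class RmAnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    pairwise: dict[tuple[int, int], float]  # Bonferroni-adjusted p-values
    pairwise_raw: dict[tuple[int, int], float]
    significant: bool


def rm_anova_bonferroni(values: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a (participants x conditions)
    matrix, with Bonferroni-corrected pairwise paired-t post hocs.

    The F statistic uses the classical within-subject decomposition
    SS_total = SS_subjects + SS_conditions + SS_error; a zero condition sum
    of squares returns F = 0 (p = 1). Sphericity corrections are not applied.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise InvalidInputError("values must be a participants x conditions matrix")
    if np.any(~np.isfinite(values)):
        raise InvalidInputError("missing cells in the repeated-measures matrix")
    n, k = values.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need >= 2 participants and >= 2 conditions")
    grand = values.mean()
    cond_means = values.mean(axis=0)
    subj_means = values.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((values - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_num = k - 1
    df_den = (n - 1) * (k - 1)
    if ss_cond <= 1e-12 * max(ss_tot, 1.0):
        F, p = 0.0, 1.0
    else:
        ms_cond = ss_cond / df_num
        ms_err = max(ss_err, 0.0) / df_den
        if ms_err == 0.0:
            F, p = math.inf, 0.0
        else:
            F = ms_cond / ms_err
            p = float(sps.f.sf(F, df_num, df_den))
    n_pairs = k * (k - 1) // 2
    pairwise_raw: dict[tuple[int, int], float] = {}
    pairwise: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            res = paired_t(values[:, i], values[:, j])
            pairwise_raw[(i, j)] = res.p
            pairwise[(i, j)] = min(1.0, res.p * n_pairs)
    return RmAnovaResult(F=float(F), df_num=df_num, df_den=df_den, p=float(p),
                         pairwise=pairwise, pairwise_raw=pairwise_raw,
                         significant=bool(p < ALPHA))


def bonferroni(p_values: np.ndarray | list[float],
               n_comparisons: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: multiply by the comparison count, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    m = n_comparisons if n_comparisons is not None else p.size
    return np.minimum(1.0, p * m)
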
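"""Preset comparisons and dose-reduction potential.

Two reconstruction presets are compared metric-by-metric through the mean
(+/- population SD) of their per-dose relative differences.  The
dose-reduction potential of a preset is obtained by fitting its d'-dose
relation with a power law d' = a * dose**b and solving for the dose at
which it matches a reference d'; the reduction is quoted as a percentage
of the reference dose, rounded half-to-even to integer percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DoseCurve",
    "ComparisonSummary",
    "relative_difference",
    "summarize_pair",
    "fit_dose_curve",
    "dose_reduction_potential",
]


@dataclass
class DoseCurve:
    """Fitted d' vs dose relation for one (task, preset)."""

    doses: np.ndarray
    d_primes: np.ndarray
    a: float
    b: float
    residuals: np.ndarray        # log-space fit residuals
    task: str = ""
    preset: str = ""

    def predict(self, dose) -> np.ndarray:
        return self.a * np.asarray(dose, dtype=float) ** self.b


@dataclass
class ComparisonSummary:
    """Mean +/- SD of per-dose relative differences between two presets."""

    metric: str
    doses: np.ndarray
    diffs_pct: np.ndarray
    mean_pct: float
    sd_pct: float


def relative_difference(value: float, reference: float) -> float:
    """Relative difference in percent: 100 * (value - reference) / reference."""
    if reference == 0:
        raise ZeroDivisionError("reference value must be nonzero")
    return 100.0 * (value - reference) / reference


def summarize_pair(
    doses,
    values,
    reference_values,
    metric: str = "",
) -> ComparisonSummary:
    """Per-dose relative differences of ``values`` vs ``reference_values``.

    The SD is the population SD over the dose levels (typically n = 5).
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    reference_values = np.asarray(reference_values, dtype=float)
    if not (doses.shape == values.shape == reference_values.shape):
        raise ValueError("dose grids of the two presets differ")
    diffs = np.array([
        relative_difference(v, r) for v, r in zip(values, reference_values)
    ])
    return ComparisonSummary(
        metric=metric,
        doses=doses,
        diffs_pct=diffs,
        mean_pct=float(diffs.mean()),
        sd_pct=float(diffs.std()),
    )


def fit_dose_curve(doses, d_primes, task: str = "", preset: str = "") -> DoseCurve:
    """Least-squares power law d' = a * dose**b, fitted in log-log space."""
    doses = np.asarray(doses, dtype=float)
    d_primes = np.asarray(d_primes, dtype=float)
    if doses.size < 3:
        raise ValueError("need at least 3 points to fit a dose curve")
    if np.any(doses <= 0) or np.any(d_primes <= 0):
        raise ValueError("doses and d' values must be positive")
    lx, ly = np.log(doses), np.log(d_primes)
    b, log_a = np.polyfit(lx, ly, 1)
    residuals = ly - (log_a + b * lx)
    return DoseCurve(
        doses=doses,
        d_primes=d_primes,
        a=float(np.exp(log_a)),
        b=float(b),
        residuals=residuals,
        task=task,
        preset=preset,
    )


def round_half_even(x: float) -> int:
    """Round to the nearest integer, ties to the even neighbour.

    The input is first rounded to 9 decimals so that values intended as
    exact halves (e.g. -46.500000000000007 from percentage arithmetic)
    are treated as ties.
    """
    return int(np.rint(np.round(x, 9)))


def dose_reduction_potential(
    curve: DoseCurve,
    reference_dprime: float,
    reference_dose: float,
) -> dict:
    """Dose at which the fitted curve matches ``reference_dprime``.

    Returns the matched dose (mGy), the full-precision reduction relative
    to ``reference_dose`` in percent, the integer-rounded percentage, and
    whether the matched dose lies outside the fitted dose range
    (extrapolation flag).
    """
    if reference_dprime <= 0 or reference_dose <= 0:
        raise ValueError("reference d' and dose must be positive")
    if curve.b <= 0:
        raise ValueError("non-increasing dose curve: no matched dose exists")
    matched = (reference_dprime / curve.a) ** (1.0 / curve.b)
    reduction = relative_difference(matched, reference_dose)
    return {
        "matched_dose_mgy": float(matched),
        "reduction_pct": float(reduction),
        "reduction_pct_rounded": round_half_even(reduction),
        "extrapolated": bool(matched < curve.doses.min() or matched > curve.doses.max()),
    }


def reduction_from_matched_dose(matched_dose: float, reference_dose: float = 10.0) -> dict:
    """Reduction percentage implied by an already-matched dose."""
    reduction = relative_difference(matched_dose, reference_dose)
    return {
        "matched_dose_mgy": float(matched_dose),
        "reduction_pct": float(reduction),
        "reduction_pct_rounded": round_half_even(reduction),
    }
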
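"""Ionogram and dispersion-curve processing.

Raw DMS data arrive as ionograms: ion intensity versus compensation
voltage (CV) at a fixed separation voltage (SV).  This module extracts the
optimal CV and peak width at each SV by Gaussian fitting, assembles the
per-molecule dispersion curve, classifies its behavior into the
strong-clustering (A) / weak-clustering (B) / hard-sphere (C) / complex
taxonomy, locates the type-B turn-around, and scores the separability of
two species' curves.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import curve_fit

from .records import Behavior, BehaviorCall, Conditions, DispersionCurve, Ionogram, PeakFit

__all__ = [
    "fit_peak",
    "build_dispersion_curve",
    "classify_behavior",
    "turnaround_point",
    "separation_score",
]

logger = logging.getLogger(__name__)


def _gaussian(cv: np.ndarray, baseline: float, amplitude: float, center: float, sigma: float):
    return baseline + amplitude * np.exp(-((cv - center) ** 2) / (2.0 * sigma**2))


def fit_peak(ionogram: Ionogram) -> PeakFit:
    """Nonlinear least-squares Gaussian-plus-baseline fit of one ionogram.

    Initial guesses come from the intensity argmax (center), the minimum
    intensity (baseline) and the second moment of the background-subtracted
    signal (width).  A fit that cannot converge returns
    ``converged=False`` with a reason rather than raising.
    """
    cv = ionogram.cv
    intensity = ionogram.intensity
    span = float(intensity.max() - intensity.min())
    if span <= 0:
        return PeakFit(
            cv_opt=float("nan"), sigma=float("nan"), amplitude=0.0,
            baseline=float(intensity[0]), rmse=0.0, converged=False,
            message="flat signal: no peak to fit",
        )
    baseline0 = float(intensity.min())
    amp0 = span
    center0 = float(cv[int(np.argmax(intensity))])
    w = np.clip(intensity - baseline0, 0.0, None)
    sigma0 = float(np.sqrt(np.sum(w * (cv - center0) ** 2) / np.sum(w)))
    sigma0 = max(sigma0, 0.25 * float(np.min(np.diff(cv))))
    try:
        popt, _ = curve_fit(
            _gaussian,
            cv,
            intensity,
            p0=[baseline0, amp0, center0, sigma0],
            bounds=(
                [-np.inf, 0.0, cv[0] - (cv[-1] - cv[0]), 1e-6],
                [np.inf, np.inf, cv[-1] + (cv[-1] - cv[0]), 10.0 * (cv[-1] - cv[0])],
            ),
            maxfev=5000,
        )
    except (RuntimeError, ValueError) as exc:
        return PeakFit(
            cv_opt=center0, sigma=sigma0, amplitude=amp0, baseline=baseline0,
            rmse=float("nan"), converged=False, message=f"fit failed: {exc}",
        )
    baseline, amplitude, center, sigma = (float(v) for v in popt)
    resid = intensity - _gaussian(cv, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return PeakFit(
        cv_opt=center, sigma=abs(sigma), amplitude=amplitude,
        baseline=baseline, rmse=rmse, converged=True,
    )


def build_dispersion_curve(
    fits: list[tuple[float, PeakFit]],
    conditions: Conditions,
    molecule_id: str = "",
) -> DispersionCurve:
    """Assemble (SV, CV_opt, sigma) points from per-SV peak fits.

    Non-converged fits are dropped (with a logged count); the remaining
    points are sorted by SV.  Duplicate SV values are an error.
    """
    converged = [(sv, f) for sv, f in fits if f.converged]
    n_dropped = len(fits) - len(converged)
    if n_dropped:
        logger.info("build_dispersion_curve: dropped %d non-converged fits", n_dropped)
    if not converged:
        raise ValueError("no converged peak fits; cannot build a dispersion curve")
    converged.sort(key=lambda t: t[0])
    sv = np.array([s for s, _ in converged])
    dup = sv[np.flatnonzero(np.diff(sv) == 0)]
    if dup.size:
        raise ValueError(f"duplicate SV value {dup[0]:g} V in peak-fit list")
    return DispersionCurve(
        molecule_id=molecule_id,
        conditions=conditions,
        sv=sv,
        cv=np.array([f.cv_opt for _, f in converged]),
        sigma=np.array([f.sigma for _, f in converged]),
    )


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; points too close to an edge for a full
    window are left unsmoothed (truncated edge windows would drag the
    endpoints toward the interior and can invert short curves)."""
    out = values.astype(float).copy()
    if window <= 1:
        return out
    half = window // 2
    for i in range(half, values.size - half):
        out[i] = values[i - half : i + half + 1].mean()
    return out


def _parabola_vertex(x: np.ndarray, y: np.ndarray) -> float:
    """Vertex abscissa of the parabola through three points."""
    coeffs = np.polyfit(x, y, 2)
    a, b = coeffs[0], coeffs[1]
    if a <= 0:  # degenerate / not convex: fall back to the middle point
        return float(x[1])
    return float(-b / (2.0 * a))


def classify_behavior(
    curve: DispersionCurve,
    smoothing_window: int = 3,
    min_prominence: float = 0.5,
) -> BehaviorCall:
    """Classify a dispersion curve as type A, B, C or complex.

    After moving-average smoothing: a curve that never rises more than
    ``min_prominence`` above its running minimum is type A (monotone
    non-increasing within tolerance); one that never falls more than
    ``min_prominence`` below its running maximum is type C (a constant
    curve — zero differential mobility — is the hard-sphere limit and is
    also called C); an interior minimum with a rise of at least
    ``min_prominence`` on its high-SV side is type B, with the turn-around
    at the parabola-refined minimum; anything else is complex.
    """
    if len(curve) < 3:
        raise ValueError("classification requires at least 3 dispersion points")
    cv_s = _smooth(curve.cv, smoothing_window)
    span = float(cv_s.max() - cv_s.min())
    if span <= min_prominence:
        return BehaviorCall(Behavior.C, None, confidence=1.0 - span / max(min_prominence, 1e-12))

    running_min = np.minimum.accumulate(cv_s)
    running_max = np.maximum.accumulate(cv_s)
    rise_excursion = float(np.max(cv_s - running_min))
    fall_excursion = float(np.max(running_max - cv_s))

    if rise_excursion <= min_prominence:
        conf = min(1.0, (span - rise_excursion) / (2.0 * min_prominence))
        return BehaviorCall(Behavior.A, None, confidence=conf)
    if fall_excursion <= min_prominence:
        conf = min(1.0, (span - fall_excursion) / (2.0 * min_prominence))
        return BehaviorCall(Behavior.C, None, confidence=conf)

    im = int(np.argmin(cv_s))
    if 0 < im < cv_s.size - 1:
        rise_after = float(np.max(cv_s[im:]) - cv_s[im])
        fall_before = float(np.max(cv_s[:im + 1]) - cv_s[im])
        # beyond the turn-around the curve must keep rising, not dip again
        post = cv_s[im:]
        redip = float(np.max(np.maximum.accumulate(post) - post))
        if rise_after >= min_prominence and fall_before >= min_prominence and redip <= min_prominence:
            turn = _parabola_vertex(curve.sv[im - 1 : im + 2], curve.cv[im - 1 : im + 2])
            conf = min(1.0, min(rise_after, fall_before) / (2.0 * min_prominence))
            return BehaviorCall(Behavior.B, float(turn), confidence=conf)
    return BehaviorCall(Behavior.COMPLEX, None, confidence=0.5)


def turnaround_point(
    curve: DispersionCurve,
    call: BehaviorCall | None = None,
    smoothing_window: int = 3,
    min_prominence: float = 0.5,
) -> float | None:
    """SV of the type-B turn-around, or ``None`` for other behaviors.

    The turn-around is the vertex of the parabola through the raw minimum
    point and its two neighbors.  A minimum sitting on the grid boundary is
    not a turn-around.
    """
    if call is None:
        call = classify_behavior(curve, smoothing_window, min_prominence)
    if call.behavior is not Behavior.B:
        return None
    im = int(np.argmin(curve.cv))
    if im == 0 or im == len(curve) - 1:
        return None
    return _parabola_vertex(curve.sv[im - 1 : im + 2], curve.cv[im - 1 : im + 2])


def separation_score(
    curve1: DispersionCurve, curve2: DispersionCurve
) -> tuple[float, float]:
    """Peak-width-normalized maximum CV separation of two species.

    Both curves are interpolated onto the union of their SV points within
    the overlapping SV range; the score is the maximum over that grid of
    ``|CV1 - CV2| / sqrt(sigma1^2 + sigma2^2)`` — the number of combined
    peak widths separating the two ions at the most discriminating SV.
    Returns ``(score, sv_at_max)``; symmetric in its arguments.
    """
    lo = max(curve1.sv[0], curve2.sv[0])
    hi = min(curve1.sv[-1], curve2.sv[-1])
    common = np.union1d(curve1.sv, curve2.sv)
    common = common[(common >= lo) & (common <= hi)]
    if common.size < 3:
        raise ValueError(
            f"curves overlap at only {common.size} SV points; need >= 3"
        )
    cv1 = np.interp(common, curve1.sv, curve1.cv)
    cv2 = np.interp(common, curve2.sv, curve2.cv)
    s1 = np.interp(common, curve1.sv, curve1.sigma)
    s2 = np.interp(common, curve2.sv, curve2.sigma)
    z = np.abs(cv1 - cv2) / np.sqrt(s1**2 + s2**2)
    k = int(np.argmax(z))
    return float(z[k]), float(common[k])
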
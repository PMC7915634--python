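"""Retract-segment analysis: baseline, Z origin, rupture events, detachment work.

The algorithm mirrors standard single-cell force-spectroscopy practice:

1. estimate the baseline level and noise from the part of the curve far from
   the sample (furthest tail of the retract trace);
2. place the Z origin where the retract trace first crosses the baseline,
   scanning in retraction order (from the contact end outward);
3. smooth the trace with a Savitzky-Golay filter and take its first
   derivative with respect to z;
4. detect rupture events as prominent positive peaks of the derivative
   (under the adhesion-negative sign convention, bond ruptures step the force
   *up* toward the baseline);
5. take the last event as the final detachment point (Z_det, F_det);
6. integrate the baseline-subtracted force from Z = 0 to Z_det to obtain the
   detachment work W (positive for adhesive curves, in fJ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .curve_io import AnalysisError, CurveMetadata, ForceCurve, correct_bending

__all__ = [
    "AnalysisParams",
    "RuptureEvent",
    "DetachmentResult",
    "estimate_baseline",
    "find_origin",
    "smooth_derivative",
    "detect_discontinuities",
    "find_detachment_point",
    "compute_detachment_work",
    "analyze_curve",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the retract-segment analysis.

    tail_fraction : fraction of samples (furthest from the sample) used for
        the baseline estimate; median/MAD for robustness.
    sg_window, sg_order : Savitzky-Golay window (odd, samples) and polynomial
        order used for the smoothed first derivative.
    prominence_factor : a derivative peak qualifies as a rupture only if its
        prominence exceeds ``prominence_factor * noise_sd / window_span`` and
        its flank-median force jump exceeds ``prominence_factor * noise_sd``.
    distance : ``"separation"`` analyzes tip-sample separation (bending
        correction applied if the curve is not already corrected);
        ``"piezo"`` analyzes the raw z axis as stored.
    signed_derivative : detect ruptures on the signed (positive) derivative
        only; if False, peaks of ``|dF/dz|`` are used.
    """

    tail_fraction: float = 0.2
    sg_window: int = 21
    sg_order: int = 3
    prominence_factor: float = 5.0
    distance: str = "separation"
    signed_derivative: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.tail_fraction <= 0.5:
            raise ValueError("tail_fraction must be in (0, 0.5]")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order or self.sg_order < 1:
            raise ValueError("need odd sg_window > sg_order >= 1")
        if self.prominence_factor <= 0:
            raise ValueError("prominence_factor must be positive")
        if self.distance not in ("separation", "piezo"):
            raise ValueError("distance must be 'separation' or 'piezo'")


@dataclass(frozen=True)
class RuptureEvent:
    """One discontinuity of the retract trace.

    ``z_position`` is relative to the Z origin (μm); forces are
    baseline-subtracted (nN).  At a rupture the force relaxes toward the
    baseline, so ``post_force > pre_force`` and ``force_jump > 0``.
    """

    z_position: float
    force_jump: float
    pre_force: float
    post_force: float

    def __post_init__(self) -> None:
        if not self.force_jump > 0:
            raise ValueError("force_jump must be positive")
        if not self.post_force > self.pre_force:
            raise ValueError("post_force must exceed pre_force at a rupture")


@dataclass
class DetachmentResult:
    """Per-curve outputs of :func:`analyze_curve`.

    ``flag`` is ``None`` for a successful analysis; otherwise it names the
    failed stage (``"no contact"``, ``"no detachment"``, ...) and the numeric
    fields are NaN.  ``origin_z`` is in the raw z coordinates of the curve.
    """

    work: float = float("nan")
    z_det: float = float("nan")
    f_det: float = float("nan")
    events: tuple = ()
    max_adhesion: float = float("nan")
    baseline_level: float = float("nan")
    noise_sd: float = float("nan")
    origin_z: float = float("nan")
    metadata: CurveMetadata = field(default_factory=CurveMetadata)
    distance: str = "separation"
    flag: str | None = None

    @property
    def ok(self) -> bool:
        return self.flag is None


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

_MAD_TO_SD = 1.4826  # consistency factor, MAD -> Gaussian sigma


def estimate_baseline(curve: ForceCurve, tail_fraction: float = 0.2) -> tuple[float, float]:
    """Robust baseline level and noise from the far-from-sample tail.

    Returns ``(level, noise_sd)`` where ``level`` is the median force of the
    furthest ``tail_fraction`` of samples by z and ``noise_sd`` the MAD-scaled
    spread of the same window.
    """
    if not 0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5]")
    n_tail = int(np.ceil(tail_fraction * curve.n_samples))
    if n_tail < 16:
        raise AnalysisError(
            f"insufficient baseline: tail window has {n_tail} samples (< 16)"
        )
    tail = curve.force[-n_tail:]
    level = float(np.median(tail))
    noise_sd = float(_MAD_TO_SD * np.median(np.abs(tail - level)))
    return level, noise_sd


def find_origin(curve: ForceCurve, baseline_level: float) -> float:
    """z of the first baseline crossing, scanning in retraction order.

    Retraction order means from the contact (minimum-separation) end outward.
    The crossing is linearly interpolated between the bracketing samples.
    Raises :class:`AnalysisError` if the trace never crosses the baseline.
    """
    d = curve.force - baseline_level
    if d[0] == 0.0:
        return float(curve.z[0])
    sign_change = np.nonzero(np.diff(np.signbit(d)) | (d[1:] == 0.0))[0]
    if sign_change.size == 0:
        raise AnalysisError("no crossing: curve never crosses the baseline")
    i = int(sign_change[0])
    z0, z1 = curve.z[i], curve.z[i + 1]
    d0, d1 = d[i], d[i + 1]
    if d1 == d0:
        return float(z0)
    return float(z0 + (z1 - z0) * (-d0) / (d1 - d0))


def smooth_derivative(
    curve: ForceCurve, window: int = 21, polyorder: int = 3
) -> np.ndarray:
    """Savitzky-Golay first derivative dF/dz (nN/μm), same length as the curve.

    Non-uniform spacing is handled through the mean sample spacing; the filter
    reproduces derivatives of polynomials up to ``polyorder`` exactly on a
    uniform grid.
    """
    if window % 2 == 0 or window <= polyorder or polyorder < 1:
        raise ValueError("need odd window > polyorder >= 1")
    if window > curve.n_samples:
        raise ValueError("window exceeds number of samples")
    delta = float(np.mean(np.diff(curve.z)))
    return savgol_filter(curve.force, window, polyorder, deriv=1, delta=delta)


def detect_discontinuities(
    curve: ForceCurve,
    dfdz: np.ndarray,
    prominence_factor: float = 5.0,
    noise_sd: float = 0.0,
    *,
    window: int = 21,
    baseline_level: float = 0.0,
    origin_z: float | None = None,
    signed: bool = True,
) -> list[RuptureEvent]:
    """Rupture events from prominent peaks of the force derivative.

    A candidate is a peak of the (positive) derivative with prominence above
    ``prominence_factor * noise_sd / window_span`` where ``window_span`` is
    the Savitzky-Golay window extent in μm.  Candidates closer than one
    window are merged (leftmost/tallest wins via peak distance).  Each
    candidate is confirmed by the force jump between flank medians taken one
    half-window away on either side; the jump must be positive and exceed
    ``prominence_factor * noise_sd``, which rejects correlated noise peaks of
    the smoothed derivative.  Events are returned ordered by z, positions
    relative to ``origin_z`` (or the raw axis if None).
    """
    z = curve.z
    f = curve.force - baseline_level
    delta = float(np.mean(np.diff(z)))
    span = window * delta
    signal = np.asarray(dfdz, dtype=float)
    if not signed:
        signal = np.abs(signal)

    prom_threshold = prominence_factor * noise_sd / span
    if prom_threshold == 0.0:
        # noiseless input: ignore numerical ripple relative to the largest swing
        peak_scale = float(np.max(signal, initial=0.0))
        if peak_scale <= 0.0:
            return []
        prom_threshold = 1e-3 * peak_scale

    start = 0
    if origin_z is not None:
        start = int(np.searchsorted(z, origin_z))
    idx, _ = find_peaks(signal[start:], prominence=prom_threshold, distance=window)
    idx = idx + start

    hw = window // 2
    jump_threshold = prominence_factor * noise_sd
    events: list[RuptureEvent] = []
    n = z.size
    for i in idx:
        pre_lo, pre_hi = max(0, i - 2 * hw), max(1, i - hw)
        post_lo, post_hi = min(n - 1, i + hw), min(n, i + 2 * hw)
        if pre_hi <= pre_lo or post_hi <= post_lo:
            continue
        pre = float(np.median(f[pre_lo:pre_hi]))
        post = float(np.median(f[post_lo:post_hi]))
        jump = post - pre
        if jump <= jump_threshold or jump <= 0.0:
            continue
        z_pos = float(z[i]) - (origin_z if origin_z is not None else 0.0)
        events.append(
            RuptureEvent(z_position=z_pos, force_jump=jump, pre_force=pre, post_force=post)
        )
    events.sort(key=lambda e: e.z_position)
    return events


def find_detachment_point(
    events: Sequence[RuptureEvent], curve: ForceCurve | None = None
) -> tuple[float, float]:
    """(Z_det, F_det): position and pre-rupture force of the last event.

    Raises :class:`AnalysisError` when no events were detected — such curves
    are flagged and excluded from condition aggregates.
    """
    if not events:
        raise AnalysisError("no detachment detected: empty event list")
    last = events[-1]
    return last.z_position, last.pre_force


def compute_detachment_work(
    curve: ForceCurve,
    z_det: float,
    *,
    baseline_level: float = 0.0,
    origin_z: float = 0.0,
) -> float:
    """Detachment work W = -∫₀^{Z_det} (F - baseline) dz, in fJ.

    Trapezoidal rule on the sampled points with linear interpolation at both
    interval ends (Z = 0 and Z = Z_det may fall between samples).  Adhesive
    (negative) force contributes positively; repulsive excursions subtract.
    No floor at zero is applied.
    """
    if z_det <= 0:
        raise AnalysisError("z_det must be positive (relative to the origin)")
    Z = curve.z - origin_z
    if z_det > Z[-1]:
        raise AnalysisError("z_det lies beyond the last sample")
    frel = curve.force - baseline_level
    lo = np.searchsorted(Z, 0.0, side="right")
    hi = np.searchsorted(Z, z_det, side="left")
    zs = np.concatenate(([0.0], Z[lo:hi], [z_det]))
    fs = np.concatenate(
        ([np.interp(0.0, Z, frel)], frel[lo:hi], [np.interp(z_det, Z, frel)])
    )
    return float(-np.trapezoid(fs, zs))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _working_curve(curve: ForceCurve, params: AnalysisParams) -> ForceCurve:
    """Return the curve on the configured distance axis."""
    if params.distance == "separation" and not curve.corrected:
        sep = correct_bending(curve.z, curve.force, curve.metadata.spring_constant)
        order = np.argsort(sep, kind="stable")
        sep, force = sep[order], curve.force[order]
        keep = np.concatenate(([True], np.diff(sep) > 0))
        return ForceCurve(
            z=sep[keep], force=force[keep], metadata=curve.metadata, corrected=True
        )
    return curve


def analyze_curve(curve: ForceCurve, params: AnalysisParams = AnalysisParams()) -> DetachmentResult:
    """Run the full retract-segment pipeline on one curve.

    Deterministic for fixed inputs and parameters.  Curves failing any stage
    are returned as flagged results (``flag`` names the reason) rather than
    raising, so batch processing never silently drops a curve.
    """
    md = curve.metadata

    def flagged(reason: str, **kw) -> DetachmentResult:
        return DetachmentResult(metadata=md, distance=params.distance, flag=reason, **kw)

    if curve.n_samples < 64:
        return flagged(f"too short: {curve.n_samples} samples (< 64)")
    if params.sg_window > curve.n_samples:
        return flagged("SG window exceeds curve length")

    work_curve = _working_curve(curve, params)

    try:
        level, noise_sd = estimate_baseline(work_curve, params.tail_fraction)
    except AnalysisError as exc:
        return flagged(str(exc))

    frel = work_curve.force - level
    # contact check: require signal well above the noise floor somewhere
    if np.max(frel) <= 5 * noise_sd and -np.min(frel) <= 5 * noise_sd:
        return flagged("no contact: trace indistinguishable from baseline noise",
                       baseline_level=level, noise_sd=noise_sd)

    try:
        origin = find_origin(work_curve, level)
    except AnalysisError as exc:
        return flagged(str(exc), baseline_level=level, noise_sd=noise_sd)

    dfdz = smooth_derivative(work_curve, params.sg_window, params.sg_order)
    events = detect_discontinuities(
        work_curve,
        dfdz,
        params.prominence_factor,
        noise_sd,
        window=params.sg_window,
        baseline_level=level,
        origin_z=origin,
        signed=params.signed_derivative,
    )
    try:
        z_det, f_det = find_detachment_point(events, work_curve)
        work = compute_detachment_work(
            work_curve, z_det, baseline_level=level, origin_z=origin
        )
    except AnalysisError as exc:
        return flagged(str(exc), baseline_level=level, noise_sd=noise_sd, origin_z=origin)

    Z = work_curve.z - origin
    in_range = (Z >= 0) & (Z <= z_det)
    max_adhesion = float(-np.min(frel[in_range])) if np.any(in_range) else float("nan")
    if work < 0:
        return flagged(
            "negative work: curve violates adhesion assumptions",
            baseline_level=level, noise_sd=noise_sd, origin_z=origin,
        )
    return DetachmentResult(
        work=work,
        z_det=z_det,
        f_det=f_det,
        events=tuple(events),
        max_adhesion=max_adhesion,
        baseline_level=level,
        noise_sd=noise_sd,
        origin_z=origin,
        metadata=md,
        distance=params.distance,
    )
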
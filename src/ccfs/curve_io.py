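"""Reading, writing and correcting cell-cell force-spectroscopy curves.

The on-disk representation is the ``ccfs-txt`` dialect: a UTF-8 text file
whose header lines start with ``"# "`` and carry ``key: value`` pairs, followed
by tab-separated ``z_um<TAB>force_nN`` data rows.  One file holds one retract
segment; an optional approach segment may follow in a second block introduced
by ``# segment: approach``.

Units are fixed package-wide: distances in μm, forces in nN, work in fJ
(1 nN·μm = 1 fJ), speeds in μm/s, cantilever spring constant in N/m.
Attractive (adhesive) forces are negative; setpoint/contact forces positive.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger("ccfs")

__all__ = [
    "DelayMode",
    "CurveMetadata",
    "ForceCurve",
    "CurveFormatError",
    "AnalysisError",
    "read_curve_file",
    "write_curve_file",
    "correct_bending",
    "scan_folder",
    "export_results_csv",
    "RESULTS_CSV_COLUMNS",
    "METADATA_DEFAULTS",
]


class CurveFormatError(ValueError):
    """A curve file does not conform to the ccfs-txt dialect."""


class AnalysisError(RuntimeError):
    """A curve could not be analyzed (no contact, no detachment, ...)."""


class DelayMode(str, Enum):
    """Feedback mode during the dwell (contact) phase.

    ``constant_force``: the piezo compensates to hold the setpoint force while
    the cells remodel.  ``constant_height``: the piezo position is fixed and
    the interaction force is free to relax.
    """

    CONSTANT_HEIGHT = "constant_height"
    CONSTANT_FORCE = "constant_force"


#: Baseline acquisition condition applied when a header omits a key
#: (10 μm/s speeds, 45 s dwell, 1 nN setpoint, constant height, 0.03 N/m).
METADATA_DEFAULTS = {
    "approach_speed": 10.0,
    "retract_speed": 10.0,
    "delay_time": 45.0,
    "setpoint": 1.0,
    "delay_mode": DelayMode.CONSTANT_HEIGHT,
    "spring_constant": 0.03,
}


@dataclass
class CurveMetadata:
    """Acquisition parameters attached to a force curve.

    Parameters
    ----------
    approach_speed, retract_speed : float
        Piezo speeds in μm/s; both must be positive.
    delay_time : float
        Dwell (contact) time τ in s; non-negative.
    setpoint : float
        Maximum compressive force F0 in nN; positive.
    delay_mode : DelayMode
        Feedback mode during the dwell.
    spring_constant : float
        Cantilever spring constant k in N/m; positive.
    curve_length : float
        Total ramp length in μm (80 μm in the reference protocol, long enough
        for complete detachment).
    source_id : str
        Identifier of the originating file (stem of the filename).
    defaulted_fields : tuple of str
        Names of fields that were filled from :data:`METADATA_DEFAULTS`
        because the header omitted them.
    """

    approach_speed: float = 10.0
    retract_speed: float = 10.0
    delay_time: float = 45.0
    setpoint: float = 1.0
    delay_mode: DelayMode = DelayMode.CONSTANT_HEIGHT
    spring_constant: float = 0.03
    curve_length: float = 80.0
    source_id: str = ""
    defaulted_fields: tuple = ()

    def __post_init__(self) -> None:
        self.delay_mode = DelayMode(self.delay_mode)
        if self.approach_speed <= 0 or self.retract_speed <= 0:
            raise ValueError("approach/retract speeds must be positive")
        if self.delay_time < 0:
            raise ValueError("delay_time must be non-negative")
        if self.setpoint <= 0:
            raise ValueError("setpoint force must be positive")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")

    def value_of(self, variable: str):
        """Return the value of a sweep variable by name."""
        return getattr(self, variable)


@dataclass(eq=False)
class ForceCurve:
    """A sampled retract trace (optionally with its approach segment).

    ``z`` is strictly increasing with tip-sample separation (small z = in
    contact, large z = far from the sample); ``force`` is in nN with adhesion
    negative.  ``corrected`` flags that cantilever-bending and baseline-offset
    corrections have been applied, i.e. that ``z`` is tip-sample separation.
    """

    z: np.ndarray
    force: np.ndarray
    metadata: CurveMetadata = field(default_factory=CurveMetadata)
    corrected: bool = False
    approach_z: np.ndarray | None = None
    approach_force: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.force.shape:
            raise ValueError("z and force must be 1-d arrays of equal length")
        if self.z.size < 2:
            raise ValueError("a curve needs at least 2 samples")
        if not (np.isfinite(self.z).all() and np.isfinite(self.force).all()):
            raise ValueError("curve samples must be finite")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z must be strictly increasing")
        if self.approach_z is not None:
            self.approach_z = np.asarray(self.approach_z, dtype=float)
            self.approach_force = np.asarray(self.approach_force, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.z.size)

    def equals(self, other: "ForceCurve") -> bool:
        """Exact equality of samples and metadata (source_id included)."""
        same_meta = dataclasses.asdict(self.metadata) == dataclasses.asdict(other.metadata)
        same_approach = (self.approach_z is None) == (other.approach_z is None)
        if same_approach and self.approach_z is not None:
            same_approach = np.array_equal(self.approach_z, other.approach_z) and np.array_equal(
                self.approach_force, other.approach_force
            )
        return (
            same_meta
            and same_approach
            and self.corrected == other.corrected
            and np.array_equal(self.z, other.z)
            and np.array_equal(self.force, other.force)
        )


# ---------------------------------------------------------------------------
# ccfs-txt dialect
# ---------------------------------------------------------------------------

_HEADER_KEYS = {
    "approachSpeed_um_s": ("approach_speed", float),
    "retractSpeed_um_s": ("retract_speed", float),
    "delayTime_s": ("delay_time", float),
    "setpoint_nN": ("setpoint", float),
    "delayMode": ("delay_mode", DelayMode),
    "springConstant_N_m": ("spring_constant", float),
    "curveLength_um": ("curve_length", float),
    "corrected": ("corrected", None),
}
_MANDATORY_META = (
    "approach_speed",
    "retract_speed",
    "delay_time",
    "setpoint",
    "delay_mode",
    "spring_constant",
)


def read_curve_file(path) -> ForceCurve:
    """Parse one ccfs-txt file into a :class:`ForceCurve`.

    Missing optional header keys are filled from :data:`METADATA_DEFAULTS`,
    recorded in ``metadata.defaulted_fields`` and logged.  Malformed data rows
    raise :class:`CurveFormatError` naming the offending line.
    """
    path = Path(path)
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise IOError(f"cannot read curve file {path}: {exc}") from exc

    meta_kwargs: dict = {}
    corrected = False
    segment = "retract"
    data: dict[str, list[tuple[float, float]]] = {"retract": [], "approach": []}

    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if ":" not in body:
                continue
            key, value = (part.strip() for part in body.split(":", 1))
            if key == "segment":
                if value not in data:
                    raise CurveFormatError(f"{path} line {lineno}: unknown segment {value!r}")
                segment = value
            elif key == "corrected":
                corrected = value.lower() in ("1", "true", "yes")
            elif key in _HEADER_KEYS:
                field_name, conv = _HEADER_KEYS[key]
                try:
                    meta_kwargs[field_name] = conv(value)
                except ValueError as exc:
                    raise CurveFormatError(
                        f"{path} line {lineno}: bad value for {key}: {value!r}"
                    ) from exc
            # unknown header keys are tolerated
            continue
        parts = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(parts) < 2:
            raise CurveFormatError(
                f"{path} line {lineno}: expected 2 columns (z_um, force_nN), got {len(parts)}"
            )
        try:
            z_val, f_val = float(parts[0]), float(parts[1])
        except ValueError:
            raise CurveFormatError(f"{path} line {lineno}: non-numeric data {stripped!r}") from None
        data[segment].append((z_val, f_val))

    if not data["retract"]:
        raise CurveFormatError(f"{path}: no retract data rows")

    defaulted = tuple(k for k in _MANDATORY_META if k not in meta_kwargs)
    for name in defaulted:
        meta_kwargs[name] = METADATA_DEFAULTS[name]
    if defaulted:
        log.warning("%s: missing header keys, defaults applied for %s", path.name, defaulted)
    meta_kwargs.pop("corrected", None)
    metadata = CurveMetadata(source_id=path.stem, defaulted_fields=defaulted, **meta_kwargs)

    retract = np.asarray(data["retract"], dtype=float)
    approach = np.asarray(data["approach"], dtype=float) if data["approach"] else None
    try:
        return ForceCurve(
            z=retract[:, 0],
            force=retract[:, 1],
            metadata=metadata,
            corrected=corrected,
            approach_z=None if approach is None else approach[:, 0],
            approach_force=None if approach is None else approach[:, 1],
        )
    except ValueError as exc:
        raise CurveFormatError(f"{path}: {exc}") from exc


def write_curve_file(curve: ForceCurve, path) -> None:
    """Write ``curve`` to ``path`` in the ccfs-txt dialect.

    Floats are written with 17 significant digits so that
    ``read_curve_file(write_curve_file(c))`` reproduces ``c`` exactly.
    """
    if not (np.isfinite(curve.z).all() and np.isfinite(curve.force).all()):
        raise ValueError("refusing to write a curve with non-finite samples")
    md = curve.metadata
    lines = [
        f"# approachSpeed_um_s: {md.approach_speed!r}",
        f"# retractSpeed_um_s: {md.retract_speed!r}",
        f"# delayTime_s: {md.delay_time!r}",
        f"# setpoint_nN: {md.setpoint!r}",
        f"# delayMode: {md.delay_mode.value}",
        f"# springConstant_N_m: {md.spring_constant!r}",
        f"# curveLength_um: {md.curve_length!r}",
        f"# corrected: {'true' if curve.corrected else 'false'}",
        "# segment: retract",
    ]
    lines.extend(f"{z:.17g}\t{f:.17g}" for z, f in zip(curve.z, curve.force))
    if curve.approach_z is not None:
        lines.append("# segment: approach")
        lines.extend(
            f"{z:.17g}\t{f:.17g}" for z, f in zip(curve.approach_z, curve.approach_force)
        )
    path = Path(path)
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot write curve file {path}: {exc}") from exc


def correct_bending(z_piezo, force, k: float):
    """Convert piezo position to tip-sample separation.

    The cantilever deflects by F/k, so the true separation is
    ``z_tss = z_piezo - F/k`` (nN / (N/m) = nm, converted to μm).

    Parameters
    ----------
    z_piezo : array, μm
    force : array, nN
    k : float, N/m

    Returns
    -------
    separation : ndarray, μm
    """
    if k <= 0:
        raise ValueError("spring constant must be positive")
    z_piezo = np.asarray(z_piezo, dtype=float)
    force = np.asarray(force, dtype=float)
    if z_piezo.shape != force.shape:
        raise ValueError("z and force arrays must have the same shape")
    separation = z_piezo - (force / k) * 1e-3
    if separation.size > 1 and not np.all(np.diff(separation) > 0):
        log.warning("bending correction broke z monotonicity (large deflection steps)")
    return separation


def scan_folder(folder) -> list[ForceCurve]:
    """Load every parseable ``*.txt`` curve in ``folder``.

    Unparseable files are logged and skipped; the skip count is reported.  An
    empty folder yields an empty list with a warning, not an error.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise IOError(f"not a directory: {folder}")
    curves: list[ForceCurve] = []
    skipped = 0
    paths = sorted(p for p in folder.glob("*.txt") if p.name != "manifest.txt")
    for p in paths:
        try:
            curves.append(read_curve_file(p))
        except (CurveFormatError, IOError) as exc:
            skipped += 1
            log.warning("skipping %s: %s", p.name, exc)
    if skipped:
        log.info("scan_folder: loaded %d curves, skipped %d", len(curves), skipped)
    if not curves:
        log.warning("scan_folder: no parseable curves in %s", folder)
    return curves


#: Exact column order of the per-curve results CSV.
RESULTS_CSV_COLUMNS = [
    "source_id",
    "approach_speed_um_s",
    "retract_speed_um_s",
    "delay_time_s",
    "setpoint_nN",
    "delay_mode",
    "work_fJ",
    "z_det_um",
    "f_det_nN",
    "n_events",
    "max_adhesion_nN",
]


def export_results_csv(results: Iterable, path) -> None:
    """Write per-curve detachment results as CSV (one row per analyzed curve).

    Rows are sorted by ``source_id``; numeric fields round-trip at full float
    precision.  Flagged (failed) results are omitted — they belong in the QC
    report, not the results table.
    """
    import pandas as pd

    rows = []
    for r in results:
        if getattr(r, "flag", None):
            continue
        md = r.metadata
        rows.append(
            {
                "source_id": md.source_id,
                "approach_speed_um_s": md.approach_speed,
                "retract_speed_um_s": md.retract_speed,
                "delay_time_s": md.delay_time,
                "setpoint_nN": md.setpoint,
                "delay_mode": md.delay_mode.value,
                "work_fJ": r.work,
                "z_det_um": r.z_det,
                "f_det_nN": r.f_det,
                "n_events": len(r.events),
                "max_adhesion_nN": r.max_adhesion,
            }
        )
    frame = pd.DataFrame(rows, columns=RESULTS_CSV_COLUMNS)
    frame = frame.sort_values("source_id", kind="stable") if len(frame) else frame
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise IOError(f"cannot write results CSV {path}: {exc}") from exc
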
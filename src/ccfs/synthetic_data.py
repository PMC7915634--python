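"""Stochastic simulator of cell-cell force-spectroscopy experiments.

The simulator embodies the same first-order picture the models module
describes: two elastic (semi-)spheres are brought into contact at constant
approach speed until the force reaches the setpoint F0, held for a dwell
time τ (constant force, or constant height with phenomenological force
relaxation), and pulled apart at constant retract speed.  Bonds form as a
Poisson process with intensity proportional to the time-integral of the
Hertzian contact area, N ~ Poisson(k_on·∫S(t)dt).  During retraction each
bond loads linearly with separation and breaks at a random rupture force,
producing a discrete upward force step; a smooth viscous drag term shapes
the near-contact region and Gaussian noise is added on top.

Every synthesized curve carries a :class:`GroundTruth` record (bond count,
per-bond rupture position and force, exact noiseless detachment work) so the
analysis pipeline can be validated end to end without real data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .curve_io import CurveMetadata, DelayMode, ForceCurve, write_curve_file
from .models import (
    ContactTrajectory,
    HertzParams,
    bond_number_integral,
    hertz_contact_area,
    hertz_force,
    hertz_indentation,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_contact_phase",
    "draw_bond_count",
    "synthesize_retract_curve",
    "generate_experiment",
    "make_staircase",
    "random_staircase",
    "expected_bond_work",
    "expected_detachment_work",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated CCFS condition.

    The defaults emulate the reference protocol: 10 μm/s approach/retract,
    45 s constant-height dwell, 1 nN setpoint, 0.03 N/m cantilever, an 80 μm
    ramp sampled at 100 samples/μm.  Bond statistics (rupture force
    0.3 ± 0.1 nN truncated at 0.1 nN, rupture extension 8 ± 4 μm) are chosen
    at the scale typical of multi-bond rupture steps in cell-cell curves.
    """

    metadata: CurveMetadata = field(default_factory=CurveMetadata)
    hertz: HertzParams = field(default_factory=HertzParams)
    bond_rate: float = 0.05            # k_on, bonds/(μm²·s)
    mean_rupture_force: float = 0.3    # nN
    rupture_force_sd: float = 0.1      # nN
    min_rupture_force: float = 0.1     # nN, truncation of the force law
    mean_rupture_extension: float = 8.0  # μm
    extension_spread: float = 4.0      # μm (exponential scale; offset keeps the mean)
    drag_coefficient: float = 0.02     # nN/(μm/s)
    drag_decay_length: float = 2.0     # μm
    noise_sd: float = 0.02             # nN
    relaxation_time: float = 5.0       # s, constant-height dwell force decay
    dwell_plateau_fraction: float = 0.4  # constant-height dwell settles to this × F0
    sampling_rate: float = 100.0       # samples/μm along the retract ramp
    time_step: float = 0.05            # s, trajectory sampling
    bell_speed_scale: float | None = None  # optional log(v_r) scaling of rupture force
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bond_rate", "mean_rupture_force", "rupture_force_sd",
            "mean_rupture_extension", "extension_spread", "drag_decay_length",
            "relaxation_time", "sampling_rate", "time_step",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.drag_coefficient < 0:
            raise ValueError("noise_sd and drag_coefficient must be non-negative")
        if self.extension_spread > self.mean_rupture_extension:
            raise ValueError("extension_spread must not exceed mean_rupture_extension")
        if not 0 < self.dwell_plateau_fraction <= 1:
            raise ValueError("dwell_plateau_fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    """Generator-side record of one synthesized curve.

    ``rupture_z`` are absolute positions on the emitted z axis; ``true_work``
    is the exact (densely integrated) detachment work of the noiseless trace
    from its baseline crossing to the last rupture.  ``dwell_force`` is the
    force trace during the dwell phase (constant-height relaxation).
    """

    n_bonds: int
    rupture_z: np.ndarray
    rupture_force: np.ndarray
    true_work: float
    true_origin: float
    dwell_times: np.ndarray
    dwell_force: np.ndarray


# ---------------------------------------------------------------------------
# contact phase
# ---------------------------------------------------------------------------

def _dwell_force(cfg: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Force during the dwell: constant (constant-force) or relaxing."""
    F0 = cfg.metadata.setpoint
    if cfg.metadata.delay_mode is DelayMode.CONSTANT_FORCE:
        return np.full_like(t, F0)
    p = cfg.dwell_plateau_fraction
    return F0 * (p + (1.0 - p) * np.exp(-t / cfg.relaxation_time))


def simulate_contact_phase(cfg: SimulationConfig) -> ContactTrajectory:
    """Piecewise contact-area trajectory: approach ramp, dwell, retract unload.

    Approach: indentation grows at v_a from first contact to
    δ0 = hertz_indentation(F0) (duration δ0/v_a), S = πRδ(t).
    Dwell: constant-force holds S = πRδ0 for τ; constant-height relaxes the
    force toward ``dwell_plateau_fraction``·F0 with time constant
    ``relaxation_time``, S following the Hertz area of the relaxed force.
    Retract: the residual indentation unloads at v_r.
    """
    md, hp = cfg.metadata, cfg.hertz
    delta0 = hertz_indentation(md.setpoint, hp)
    dt = cfg.time_step

    def seg_times(duration: float) -> np.ndarray:
        n = max(3, int(np.ceil(duration / dt)) + 1)
        return np.linspace(0.0, duration, n)

    # approach: delta = v_a * t
    t_app = seg_times(delta0 / md.approach_speed)
    segs = [(t_app, hertz_contact_area(md.approach_speed * t_app, hp), "approach")]

    if md.delay_time > 0:
        t_dwell = seg_times(md.delay_time)
        f_dwell = _dwell_force(cfg, t_dwell)
        segs.append((t_dwell, hertz_contact_area(hertz_indentation(f_dwell, hp), hp), "dwell"))
        delta_end = hertz_indentation(float(f_dwell[-1]), hp)
    else:
        delta_end = delta0

    t_ret = seg_times(delta_end / md.retract_speed)
    segs.append(
        (t_ret, hertz_contact_area(np.maximum(delta_end - md.retract_speed * t_ret, 0.0), hp), "retract")
    )

    times, areas, phases = [], [], []
    offset = 0.0
    for t, s, label in segs:
        sel = slice(1, None) if times else slice(None)
        times.append(t[sel] + offset)
        areas.append(s[sel])
        phases.append(np.full(t[sel].size, label))
        offset += t[-1]
    return ContactTrajectory(
        times=np.concatenate(times),
        area=np.concatenate(areas),
        phase=np.concatenate(phases),
    )


def draw_bond_count(traj: ContactTrajectory, k_on: float, seed) -> int:
    """N ~ Poisson(k_on·∫S(t)dt), seeded (seed may be an int or a Generator)."""
    lam = bond_number_integral(traj, k_on)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return int(rng.poisson(lam))


# ---------------------------------------------------------------------------
# retract curve synthesis
# ---------------------------------------------------------------------------

def _rupture_force_mean(cfg: SimulationConfig) -> float:
    """Mean of the rupture-force law, optionally Bell-scaled with retract speed."""
    mu = cfg.mean_rupture_force
    if cfg.bell_speed_scale is not None:
        mu = mu * (1.0 + cfg.bell_speed_scale * np.log1p(cfg.metadata.retract_speed))
    return float(mu)


def _noiseless_force(
    z: np.ndarray,
    delta_start: float,
    f_start: float,
    bond_f: np.ndarray,
    bond_z: np.ndarray,
    cfg: SimulationConfig,
) -> np.ndarray:
    """Noiseless retract trace on absolute z: Hertz unload + bond ramps + drag."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    force = np.zeros_like(z)
    # repulsive Hertz unload while still indented
    contact = z < delta_start
    if np.any(contact):
        force[contact] = hertz_force(delta_start - z[contact], cfg.hertz) * (
            f_start / hertz_force(delta_start, cfg.hertz)
        )
    ext = z - delta_start
    pulled = ext >= 0.0
    if np.any(pulled):
        e = ext[pulled]
        adh = np.zeros_like(e)
        for fz, zr in zip(bond_f, bond_z):
            loading = e < zr
            adh[loading] -= fz * e[loading] / zr
        adh -= cfg.drag_coefficient * cfg.metadata.retract_speed * np.exp(
            -e / cfg.drag_decay_length
        )
        force[pulled] += adh
    return force


def synthesize_retract_curve(
    cfg: SimulationConfig, n_bonds: int, seed
) -> tuple[ForceCurve, GroundTruth]:
    """Build one retract trace with ``n_bonds`` stochastic rupture events.

    Each bond loads linearly from the contact point and breaks at a rupture
    force drawn from a truncated normal, at an extension drawn from an
    offset exponential around ``mean_rupture_extension``.  The emitted
    :class:`ForceCurve` is on the tip-sample separation axis (``corrected``)
    in the ccfs-txt unit convention; the paired :class:`GroundTruth` records
    every rupture and the exact noiseless work integral.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    md = cfg.metadata

    # dwell-end force sets the starting indentation of the retraction
    t_dwell = np.linspace(0.0, max(md.delay_time, 1e-9), 64)
    f_dwell = _dwell_force(cfg, t_dwell)
    f_start = float(f_dwell[-1]) if md.delay_time > 0 else md.setpoint
    delta_start = hertz_indentation(f_start, cfg.hertz)

    mu = _rupture_force_mean(cfg)
    sd = cfg.rupture_force_sd
    a = (cfg.min_rupture_force - mu) / sd
    bond_f = truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n_bonds, random_state=rng)
    z_min = cfg.mean_rupture_extension - cfg.extension_spread
    bond_z = z_min + rng.exponential(cfg.extension_spread, size=n_bonds)

    n = int(round(md.curve_length * cfg.sampling_rate)) + 1
    z = np.linspace(0.0, md.curve_length, n)
    clean = _noiseless_force(z, delta_start, f_start, bond_f, bond_z, cfg)
    force = clean + rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else clean

    curve = ForceCurve(z=z, force=force, metadata=md, corrected=True)

    # ground truth: origin = noiseless baseline crossing; work integrated on a
    # 10x-denser grid from the origin to the last rupture
    def f_of(zz: float) -> float:
        return float(
            _noiseless_force(np.array([zz]), delta_start, f_start, bond_f, bond_z, cfg)[0]
        )

    if n_bonds > 0 or cfg.drag_coefficient > 0:
        try:
            true_origin = brentq(f_of, 1e-9, delta_start + 1e-6)
        except ValueError:
            true_origin = delta_start
    else:
        true_origin = delta_start

    if n_bonds > 0:
        z_last = delta_start + float(np.max(bond_z))
        dense = np.linspace(true_origin, z_last, 10 * n + 1)
        vals = _noiseless_force(dense, delta_start, f_start, bond_f, bond_z, cfg)
        true_work = float(-np.trapezoid(vals, dense))
    else:
        true_work = 0.0

    truth = GroundTruth(
        n_bonds=n_bonds,
        rupture_z=delta_start + np.sort(bond_z),
        rupture_force=bond_f[np.argsort(bond_z)],
        true_work=true_work,
        true_origin=float(true_origin),
        dwell_times=t_dwell,
        dwell_force=f_dwell,
    )
    return curve, truth


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

def generate_experiment(
    cfg: SimulationConfig,
    variable: str,
    values,
    n_curves_per_condition: int,
    out_folder,
):
    """Write a full parameter sweep as ccfs-txt files plus a manifest.

    One file per curve, ``n_curves_per_condition`` per condition value, named
    ``{variable}_{condition:02d}_{curve:03d}.txt``.  Per-curve random streams
    are derived from the master seed by (condition index, curve index), so
    adding conditions never reshuffles existing curves, and the same master
    seed reproduces byte-identical folders.  Returns the manifest as a pandas
    DataFrame (also written to ``manifest.csv``).
    """
    import pandas as pd

    out_folder = Path(out_folder)
    try:
        out_folder.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output folder {out_folder}: {exc}") from exc

    rows = []
    for ci, value in enumerate(values):
        md = dataclasses.replace(cfg.metadata, **{variable: value})
        cond_cfg = dataclasses.replace(cfg, metadata=md)
        traj = simulate_contact_phase(cond_cfg)
        lam = bond_number_integral(traj, cond_cfg.bond_rate)
        for k in range(n_curves_per_condition):
            ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(ci, k))
            rng = np.random.default_rng(ss)
            n_bonds = int(rng.poisson(lam))
            name = f"{variable}_{ci:02d}_{k:03d}"
            curve, truth = synthesize_retract_curve(cond_cfg, n_bonds, rng)
            curve = dataclasses.replace(curve)
            curve.metadata = dataclasses.replace(md, source_id=name)
            write_curve_file(curve, out_folder / f"{name}.txt")
            rows.append(
                {
                    "file": f"{name}.txt",
                    "variable": variable,
                    "value": value if not hasattr(value, "value") else value.value,
                    "seed": f"{cfg.seed}:{ci}:{k}",
                    "true_n_bonds": n_bonds,
                    "true_W_fJ": truth.true_work,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_folder / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# expected-value helpers (analytic generator truth)
# ---------------------------------------------------------------------------

def expected_bond_work(cfg: SimulationConfig) -> float:
    """E[½·f·z] per bond: half the product of mean rupture force and extension.

    Rupture force and extension are drawn independently, so the expectation
    factorizes; the truncated-normal mean is computed exactly.
    """
    mu = _rupture_force_mean(cfg)
    a = (cfg.min_rupture_force - mu) / cfg.rupture_force_sd
    mean_f = float(truncnorm.mean(a, np.inf, loc=mu, scale=cfg.rupture_force_sd))
    return 0.5 * mean_f * cfg.mean_rupture_extension


def expected_detachment_work(cfg: SimulationConfig) -> float:
    """First-order E[W]: expected bonds × mean per-bond work + drag work."""
    traj = simulate_contact_phase(cfg)
    lam = bond_number_integral(traj, cfg.bond_rate)
    drag = cfg.drag_coefficient * cfg.metadata.retract_speed * cfg.drag_decay_length
    return lam * expected_bond_work(cfg) + drag


# ---------------------------------------------------------------------------
# staircase fixtures (controlled event-detection inputs)
# ---------------------------------------------------------------------------

def make_staircase(
    step_heights,
    step_positions,
    *,
    contact_z: float = 1.0,
    length: float = 30.0,
    sampling_rate: float = 100.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    metadata: CurveMetadata | None = None,
) -> ForceCurve:
    """Adhesion staircase: a repulsive ramp, then discrete upward force steps.

    The force starts at +1 nN, falls linearly to cross zero at ``contact_z``,
    drops to -Σheights, and steps up by ``step_heights[i]`` at each
    ``step_positions[i]`` (absolute z, all > contact_z), reaching 0 after the
    last step.  Optionally adds Gaussian noise.
    """
    heights = np.asarray(step_heights, dtype=float)
    positions = np.asarray(step_positions, dtype=float)
    if heights.shape != positions.shape or np.any(heights <= 0):
        raise ValueError("step heights/positions must match and be positive")
    if np.any(positions <= contact_z) or np.any(positions >= length):
        raise ValueError("step positions must lie inside (contact_z, length)")
    order = np.argsort(positions)
    heights, positions = heights[order], positions[order]

    n = int(round(length * sampling_rate)) + 1
    z = np.linspace(0.0, length, n)
    force = np.where(z < contact_z, 1.0 - z / contact_z, 0.0)
    depth = -np.sum(heights)
    beyond = z >= contact_z
    force[beyond] += depth
    for h, p in zip(heights, positions):
        force[z >= p] += h
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        force = force + rng.normal(0.0, noise_sd, size=n)
    return ForceCurve(
        z=z, force=force, metadata=metadata or CurveMetadata(), corrected=True
    )


def random_staircase(
    n_steps: int,
    rng: np.random.Generator,
    *,
    min_height: float = 0.2,
    max_height: float = 1.0,
    min_separation: float = 1.0,
    contact_z: float = 1.0,
    length: float = 30.0,
    sampling_rate: float = 100.0,
    noise_sd: float = 0.0,
) -> tuple[ForceCurve, np.ndarray]:
    """Draw a random staircase with well-separated steps; returns (curve, positions)."""
    lo, hi = contact_z + 2.0, length * 0.75
    for _ in range(1000):
        positions = np.sort(rng.uniform(lo, hi, size=n_steps))
        if n_steps < 2 or np.min(np.diff(positions)) >= min_separation:
            break
    else:
        positions = lo + np.arange(n_steps) * max(min_separation, (hi - lo) / n_steps)
    heights = rng.uniform(min_height, max_height, size=n_steps)
    curve = make_staircase(
        heights, positions, contact_z=contact_z, length=length,
        sampling_rate=sampling_rate, noise_sd=noise_sd, rng=rng,
    )
    return curve, positions
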
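"""Theoretical components: bond-number integral, Hertz contact, W-vs-parameter models.

The interpretation behind the pipeline is deliberately first-order: the
detachment work W is proportional to the number N of cell-cell bonds formed
during contact, and N in turn is proportional to the time-integral of the
instantaneous contact area,

    W ∝ N ∝ ∫ S(t) dt   over the interaction time,

with the contact area estimated from Hertz contact mechanics
(A = π a² = π R δ0, F0 ∝ δ0^{3/2}).  Four parametric forms describe how the
mean detachment work responds to each acquisition parameter:

- ``delay``:    W(τ)  = A + B·τ               (bond number grows linearly with dwell)
- ``setpoint``: W(F0) = A + B·F0^{2/3}        (Hertz area scaling)
- ``approach``: W(v_a) = A·τ·B/(B + v_a)      (contact time inversely related to
                approach speed, saturating at slow approach)
- ``retract``:  W(v_r) = A·g·v_r + B·ln(1 + v_r/v_ref)
                (viscous drag linear in speed + kinetic bond activation,
                logarithmic in speed; g and v_ref are fixed constants so the
                fit has two free parameters)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "HertzParams",
    "ContactTrajectory",
    "ModelSpec",
    "MODEL_REGISTRY",
    "DEFAULT_HERTZ",
    "RETRACT_GEOMETRY",
    "RETRACT_V_REF",
    "bond_number_integral",
    "hertz_indentation",
    "hertz_force",
    "hertz_contact_area",
    "hertz_contact_radius",
    "model_W_delay",
    "model_W_setpoint",
    "model_W_approach",
    "model_W_retract",
]


@dataclass(frozen=True)
class HertzParams:
    """Hertz contact parameters for two cells in contact.

    effective_radius : μm — effective radius R of the cell pair.
    effective_modulus : nN/μm² (numerically equal to kPa) — effective elastic
        modulus E* of the contact.
    """

    effective_radius: float = 10.0
    effective_modulus: float = 0.5

    def __post_init__(self) -> None:
        if self.effective_radius <= 0 or self.effective_modulus <= 0:
            raise ValueError("Hertz radius and modulus must be positive")

    @property
    def prefactor(self) -> float:
        """C in F = C·δ^{3/2}; standard form C = (4/3)·E*·√R."""
        return (4.0 / 3.0) * self.effective_modulus * math.sqrt(self.effective_radius)


DEFAULT_HERTZ = HertzParams()


@dataclass
class ContactTrajectory:
    """Time course of the instantaneous contact area S(t) during interaction.

    ``phase`` labels each sample as "approach", "dwell" or "retract".
    S(t) ≥ 0 with S = 0 outside contact; times strictly increasing (s).
    """

    times: np.ndarray
    area: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        self.phase = np.asarray(self.phase)
        if not (self.times.shape == self.area.shape == self.phase.shape):
            raise ValueError("times, area and phase must have equal shapes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.area < 0):
            raise ValueError("contact area must be non-negative")

    def concat(self, other: "ContactTrajectory") -> "ContactTrajectory":
        """Concatenate a later trajectory (its times shifted after this one)."""
        dt = float(np.mean(np.diff(self.times))) if self.times.size > 1 else 1e-6
        shift = self.times[-1] + dt - other.times[0]
        return ContactTrajectory(
            times=np.concatenate([self.times, other.times + shift]),
            area=np.concatenate([self.area, other.area]),
            phase=np.concatenate([self.phase, other.phase]),
        )


def bond_number_integral(traj: ContactTrajectory, rate_constant: float) -> float:
    """Expected bond count N = rate_constant · ∫ S(t) dt (trapezoidal).

    ``rate_constant`` is in bonds/(μm²·s); the integral runs over the whole
    trajectory (samples with S = 0 contribute nothing).
    """
    if rate_constant < 0:
        raise ValueError("rate constant must be non-negative")
    return float(rate_constant * np.trapezoid(traj.area, traj.times))


# ---------------------------------------------------------------------------
# Hertz contact relations
# ---------------------------------------------------------------------------

def hertz_indentation(F0, hp: HertzParams = DEFAULT_HERTZ):
    """Indentation δ0 = (F0/C)^{2/3} at peak force F0 (nN) — inverts F = C·δ^{3/2}."""
    F0 = np.asarray(F0, dtype=float)
    if np.any(F0 <= 0):
        raise ValueError("setpoint force must be positive")
    out = (F0 / hp.prefactor) ** (2.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def hertz_force(delta, hp: HertzParams = DEFAULT_HERTZ):
    """Hertz force F = C·δ^{3/2} (nN) at indentation δ (μm)."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be non-negative")
    out = hp.prefactor * delta**1.5
    return float(out) if out.ndim == 0 else out


def hertz_contact_area(delta0, hp: HertzParams = DEFAULT_HERTZ):
    """Contact area A = π·R·δ0 (μm²) from the Hertz contact radius a = √(R·δ0)."""
    delta0 = np.asarray(delta0, dtype=float)
    if np.any(delta0 < 0):
        raise ValueError("indentation must be non-negative")
    out = math.pi * hp.effective_radius * delta0
    return float(out) if out.ndim == 0 else out


def hertz_contact_radius(delta0, hp: HertzParams = DEFAULT_HERTZ):
    """Contact radius a = √(R·δ0) (μm)."""
    delta0 = np.asarray(delta0, dtype=float)
    if np.any(delta0 < 0):
        raise ValueError("indentation must be non-negative")
    out = np.sqrt(hp.effective_radius * delta0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# W-vs-parameter models
# ---------------------------------------------------------------------------

#: Fixed constants of the retract-speed model: a Stokes-like geometric factor
#: 6πR with R = 10 μm (units absorbed into the fitted drag coefficient A) and
#: the reference speed of the logarithmic kinetic term.
RETRACT_GEOMETRY = 6.0 * math.pi * 10.0
RETRACT_V_REF = 1.0


def model_W_delay(tau, A: float, B: float):
    """W(τ) = A + B·τ — work linear in dwell time (fJ; A fJ, B fJ/s)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("delay time must be non-negative")
    out = A + B * tau
    return float(out) if out.ndim == 0 else out


def model_W_setpoint(F0, A: float, B: float):
    """W(F0) = A + B·F0^{2/3} — Hertz contact-area scaling (F0 in nN)."""
    F0 = np.asarray(F0, dtype=float)
    if np.any(F0 < 0):
        raise ValueError("setpoint force must be non-negative")
    out = A + B * F0 ** (2.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def model_W_approach(v_a, A: float, B: float, tau: float = 45.0):
    """W(v_a) = A·τ_eff with τ_eff = τ·B/(B + v_a).

    The effective bond-formation time shrinks as the approach gets faster
    (half-saturation at v_a = B), with the finite limit A·τ as v_a → 0.
    """
    v_a = np.asarray(v_a, dtype=float)
    if np.any(v_a <= 0):
        raise ValueError("approach speed must be positive")
    out = A * tau * B / (B + v_a)
    return float(out) if out.ndim == 0 else out


def model_W_retract(
    v_r,
    A: float,
    B: float,
    geometry: float = RETRACT_GEOMETRY,
    v_ref: float = RETRACT_V_REF,
):
    """W(v_r) = A·geometry·v_r + B·ln(1 + v_r/v_ref).

    Linear viscous drag dominates at high speed; the logarithmic term models
    kinetic (Bell-type) bond activation at low speed.  ``geometry`` and
    ``v_ref`` are fixed so only A and B are free fit parameters.
    """
    v_r = np.asarray(v_r, dtype=float)
    if np.any(v_r <= 0):
        raise ValueError("retract speed must be positive")
    out = A * geometry * v_r + B * np.log1p(v_r / v_ref)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One registered W-vs-parameter model.

    ``func(x, A, B)`` evaluates the model; ``variable`` is the metadata field
    swept, ``csv_column`` the matching results-CSV column.  ``initial_guess``
    maps (x, y) data to a deterministic (A0, B0); ``bounds`` constrain the
    fit.  ``fixed`` holds non-fitted constants (τ for the approach model,
    geometry/v_ref for the retract model).
    """

    model_id: str
    func: Callable
    variable: str
    csv_column: str
    param_units: tuple
    initial_guess: Callable
    bounds: tuple = ((-np.inf, -np.inf), (np.inf, np.inf))
    fixed: dict = field(default_factory=dict)

    def __call__(self, x, A, B):
        return self.func(x, A, B, **self.fixed)


def _guess_delay(x, y):
    B = (y[-1] - y[0]) / (x[-1] - x[0]) if x[-1] != x[0] else 0.0
    return (float(y[0] - B * x[0]), float(max(B, 0.0)))


def _guess_setpoint(x, y):
    t = np.asarray(x, dtype=float) ** (2.0 / 3.0)
    B = (y[-1] - y[0]) / (t[-1] - t[0]) if t[-1] != t[0] else 0.0
    return (float(y[0] - B * t[0]), float(max(B, 0.0)))


def _guess_approach(x, y, tau: float = 45.0):
    B = float(np.median(x))
    A = float(max(np.max(y), 1e-12) * (B + np.min(x)) / (tau * B))
    return (A, B)


def _guess_retract(x, y, geometry: float = RETRACT_GEOMETRY, v_ref: float = RETRACT_V_REF):
    A = float(max(y[-1], 1e-12) / (x[-1] * geometry))
    B = float(max(y[0], 1e-12) / np.log1p(x[0] / v_ref))
    return (A, B)


MODEL_REGISTRY: dict[str, ModelSpec] = {
    "delay": ModelSpec(
        model_id="delay",
        func=model_W_delay,
        variable="delay_time",
        csv_column="delay_time_s",
        param_units=("fJ", "fJ/s"),
        initial_guess=_guess_delay,
        bounds=((-np.inf, 0.0), (np.inf, np.inf)),
    ),
    "setpoint": ModelSpec(
        model_id="setpoint",
        func=model_W_setpoint,
        variable="setpoint",
        csv_column="setpoint_nN",
        param_units=("fJ", "fJ/nN^(2/3)"),
        initial_guess=_guess_setpoint,
        bounds=((-np.inf, 0.0), (np.inf, np.inf)),
    ),
    "approach": ModelSpec(
        model_id="approach",
        func=model_W_approach,
        variable="approach_speed",
        csv_column="approach_speed_um_s",
        param_units=("fJ/s", "um/s"),
        initial_guess=_guess_approach,
        bounds=((0.0, 1e-9), (np.inf, np.inf)),
        fixed={"tau": 45.0},
    ),
    "retract": ModelSpec(
        model_id="retract",
        func=model_W_retract,
        variable="retract_speed",
        csv_column="retract_speed_um_s",
        param_units=("fJ·s/um (×geometry)", "fJ"),
        initial_guess=_guess_retract,
        bounds=((0.0, 0.0), (np.inf, np.inf)),
        fixed={"geometry": RETRACT_GEOMETRY, "v_ref": RETRACT_V_REF},
    ),
}
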
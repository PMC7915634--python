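import dataclasses

import numpy as np
import pytest

from ccfs import (
    CurveMetadata,
    ForceCurve,
    SimulationConfig,
    bond_number_integral,
    draw_bond_count,
    simulate_contact_phase,
    synthesize_retract_curve,
)


@pytest.fixture(scope="session")
def base_config() -> SimulationConfig:
    """Reference acquisition condition: 10 um/s, 45 s, 1 nN, constant height."""
    return SimulationConfig(seed=1234)


@pytest.fixture(scope="session")
def simulated_curve(base_config):
    """One deterministic simulated curve with its ground truth."""
    traj = simulate_contact_phase(base_config)
    rng = np.random.default_rng(42)
    n = draw_bond_count(traj, base_config.bond_rate, rng)
    return synthesize_retract_curve(base_config, n, rng)


def simulate_sweep(cfg: SimulationConfig, variable: str, values, n_per_condition: int):
    """In-memory parameter sweep: list of (curve, truth) with per-curve substreams."""
    out = []
    for ci, value in enumerate(values):
        md = dataclasses.replace(cfg.metadata, **{variable: value})
        ccfg = dataclasses.replace(cfg, metadata=md)
        traj = simulate_contact_phase(ccfg)
        lam = bond_number_integral(traj, ccfg.bond_rate)
        for k in range(n_per_condition):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(ci, k))
            )
            n = int(rng.poisson(lam))
            curve, truth = synthesize_retract_curve(ccfg, n, rng)
            curve.metadata = dataclasses.replace(md, source_id=f"{variable}_{ci}_{k}")
            out.append((curve, truth))
    return out


def flat_tail_curve(adhesion_depth=1.0, n=2000, length=20.0, metadata=None):
    """Simple triangular adhesion well with a flat zero tail (deterministic)."""
    z = np.linspace(0.0, length, n)
    force = np.where(z < 1.0, 1.0 - z, 0.0)
    well = (z >= 1.0) & (z <= 5.0)
    force[well] = -adhesion_depth * (1.0 - np.abs(z[well] - 3.0) / 2.0)
    return ForceCurve(z=z, force=force, metadata=metadata or CurveMetadata(), corrected=True)
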
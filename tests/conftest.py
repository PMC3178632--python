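"""Shared fixtures.

Heavy simulations are session-scoped and shared across tests: one long
standard-model run (the translocation workhorse) and one ensemble of
independently built, briefly equilibrated free ParB polymers.
"""

from __future__ import annotations

import numpy as np
import pytest

from parabd.builder import build_parb_polymer, build_system, scenario
from parabd.simulate import Simulation

# desk-scale standard system: 7-filament bundle, 30 subunits each,
# 60-subunit ParB polymer with a 50-subunit central binding strip
STANDARD_GEO = {
    "n_filaments": 7, "filament_length": 30,
    "parb_total_length": 60, "parb_binding_length": 50,
}
STANDARD_CHEM = {"k_d": 0.006, "k_h": 30.0}

# smaller matched system for replicate-heavy comparisons
SMALL_GEO = {
    "n_filaments": 4, "filament_length": 12,
    "parb_total_length": 40, "parb_binding_length": 30,
    "parb_relax_steps": 10_000, "prebind_steps": 12_000,
}
SMALL_CHEM = {"k_d": 0.02, "k_h": 30.0}


def make_run(name="standard", geometry=None, chemistry=None, forcefield=None,
             seed=0, n_steps=500_000, sample_stride=1000, traj_stride=0,
             bound_energy_cut=1.0):
    """Build and run one scenario; returns (config, initial state, result)."""
    cfg = scenario(name, geometry=geometry or {}, chemistry=chemistry or {})
    for k, v in (forcefield or {}).items():
        setattr(cfg.forcefield, k, v)
    cfg.integrator.seed = seed
    system = build_system(cfg)
    state0 = system.copy()
    sim = Simulation(system, cfg.forcefield_params(), cfg.chemistry_params(),
                     cfg.integrator_params(), bound_energy_cut=bound_energy_cut,
                     config=cfg)
    res = sim.run(n_steps, sample_stride=sample_stride, traj_stride=traj_stride)
    return cfg, state0, res


@pytest.fixture(scope="session")
def standard_run():
    """Long regime-I standard run (k_max * tau ~ 0.05), with frames."""
    cfg, state0, res = make_run(
        geometry=dict(STANDARD_GEO), chemistry=dict(STANDARD_CHEM),
        seed=101, n_steps=3_200_000, sample_stride=2000, traj_stride=10_000)
    return {"cfg": cfg, "state0": state0, "res": res}


@pytest.fixture(scope="session")
def free_polymer_ensemble():
    """64 independently built + briefly relaxed free ParB polymers.

    Returns per-replicate gyration-tensor diagonals of the whole polymer and
    the x-variance of its 5-subunit terminal (peripheral) segments.
    """
    cfg = scenario("standard", geometry=dict(STANDARD_GEO))
    ff = cfg.forcefield_params()
    gx, gy, gz, seg = [], [], [], []
    for k in range(64):
        rng = np.random.default_rng(5000 + k)
        p = build_parb_polymer(cfg.geometry, ff, rng)
        d = p.pos - p.pos.mean(axis=0)
        gx.append((d[:, 0] ** 2).mean())
        gy.append((d[:, 1] ** 2).mean())
        gz.append((d[:, 2] ** 2).mean())
        for sl in (slice(0, 5), slice(55, 60)):
            x = p.pos[sl, 0]
            seg.append(((x - x.mean()) ** 2).mean())
    return {"rg2_x": np.array(gx), "rg2_y": np.array(gy),
            "rg2_z": np.array(gz), "segment_rg2_x": np.array(seg)}


@pytest.fixture(scope="session")
def tiny_system():
    """A small built system with binding contacts, for force-path tests."""
    cfg = scenario("standard", geometry={
        "n_filaments": 4, "filament_length": 10,
        "parb_total_length": 20, "parb_binding_length": 14,
        "parb_relax_steps": 2000, "prebind_steps": 4000})
    cfg.integrator.seed = 7
    system = build_system(cfg)
    return cfg, system
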
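"""Stochastic chemistry: eligibility, event statistics, topology invariants."""

import numpy as np
import pytest

from parabd import state as st
from parabd.builder import build_system, scenario
from parabd.chemistry import (BindingMode, ChemistryParams, DisassemblyMode,
                              apply_depolymerization, apply_sever,
                              audit_topology, depolymerization_step,
                              eligible_binders, hydrolysis_step,
                              severing_step)
from parabd.simulate import Simulation


def make_bundle(n_fil=4, length=25, anchored=True):
    """Bare ParA bundle (no ParB), straight filaments along x."""
    n = n_fil * length
    pos = np.zeros((n, 3))
    chains = []
    for f in range(n_fil):
        ids = list(range(f * length, (f + 1) * length))
        chains.append(ids)
        for k, sid in enumerate(ids):
            pos[sid] = (k, 2.0 * f, 0.0)
    anch = np.zeros(n, bool)
    if anchored:
        for c in chains:
            anch[c[-1]] = True
    sys_ = st.SystemState(
        pos=pos, pol=np.tile([0.0, 1.0, 0.0], (n, 1)),
        species=np.zeros(n, np.int8), nucleotide=np.zeros(n, np.int8),
        alpha=np.ones(n), anchored=anch, polymerized=np.ones(n, bool),
        has_pol=np.ones(n, bool), chains=chains,
        chain_is_parA=[True] * n_fil, crosslinks=None)
    ff = scenario("standard").forcefield_params()
    sys_.rebuild_topology(ff)
    return sys_, ff


def test_eligible_binders_side_vs_tip_counts():
    sys_, ff = make_bundle(4, 25)
    side = eligible_binders(sys_, ChemistryParams(binding_mode=BindingMode.SIDE))
    tip = eligible_binders(sys_, ChemistryParams(binding_mode=BindingMode.TIP_ONLY))
    assert len(side) == 100
    assert len(tip) == 4
    assert all(sys_.is_tip[i] for i in tip)


def test_eligible_binders_tracks_tip_after_depolymerization():
    sys_, ff = make_bundle(4, 25)
    chain0 = list(sys_.chains[0])
    for i in chain0[:3]:
        sys_.nucleotide[i] = st.ADP
        apply_depolymerization(sys_, i)
    sys_.rebuild_topology(ff, tip_only_binding=True)
    tip = eligible_binders(sys_, ChemistryParams(binding_mode=BindingMode.TIP_ONLY))
    assert chain0[3] in tip
    assert not any(i in tip for i in chain0[:3])
    side = eligible_binders(sys_, ChemistryParams(binding_mode=BindingMode.SIDE))
    assert not any(i in side for i in chain0[:3])  # monomers never eligible


def test_hydrolysis_binomial_statistics():
    # 1e4 bound subunits at k_h dt = 0.01: event count within 4 sigma
    sys_, ff = make_bundle(1, 10_000, anchored=False)
    params = ChemistryParams(k_h=1.0, eps_threshold=5.0)
    energies = {(i, 0): -6.0 for i in range(10_000)}    # all above threshold
    events = hydrolysis_step(sys_, energies, params, dt=0.01,
                             rng=np.random.default_rng(2))
    p = 1 - np.exp(-0.01)
    mean, sd = 1e4 * p, np.sqrt(1e4 * p * (1 - p))
    assert abs(len(events) - mean) < 4 * sd
    assert np.all(sys_.nucleotide[[e.subunit_id for e in events]] == st.ADP)


def test_hydrolysis_requires_threshold_and_no_parb():
    sys_, ff = make_bundle(2, 10)
    params = ChemistryParams(k_h=1e9, eps_threshold=5.0)
    # no ParB in range -> no events, always
    assert hydrolysis_step(sys_, {}, params, 0.01, np.random.default_rng(0)) == []
    # below-threshold energies never hydrolyze
    weak = {(i, 0): -4.9 for i in range(5)}
    assert hydrolysis_step(sys_, weak, params, 0.01, np.random.default_rng(0)) == []
    # saturation: k_h -> infinity hydrolyzes every bound subunit this step
    strong = {(i, 0): -5.0 for i in range(5)}
    events = hydrolysis_step(sys_, strong, params, 0.01, np.random.default_rng(0))
    assert len(events) == 5


def test_depolymerization_tip_rule_and_saturation():
    sys_, ff = make_bundle(1, 25)
    chain = list(sys_.chains[0])
    sys_.nucleotide[:] = st.ADP           # pre-hydrolyze everything
    params = ChemistryParams(k_d=1e9)
    rng = np.random.default_rng(3)
    for k in range(24):                   # anchored terminal never leaves
        events = depolymerization_step(sys_, params, 1.0, rng)
        sys_.rebuild_topology(ff)
        assert len(events) == 1
        assert events[0].subunit_id == chain[k]   # strictly from the free tip
    assert depolymerization_step(sys_, params, 1.0, rng) == []
    assert audit_topology(sys_, expect_anchored=True)


def test_atp_tip_never_depolymerizes():
    sys_, ff = make_bundle(2, 10)
    params = ChemistryParams(k_d=1e9)
    assert depolymerization_step(sys_, params, 1.0, np.random.default_rng(0)) == []


def test_depolymerization_exponential_waiting_time():
    # mean lifetime of a hydrolyzed tip = 1/k_d within 5% (1000 replicates)
    k_d, dt = 0.05, 0.1
    rng = np.random.default_rng(4)
    p = 1 - np.exp(-k_d * dt)
    lifetimes = []
    for _ in range(1000):
        steps = 0
        while rng.random() >= p:          # same Bernoulli rule as the engine
            steps += 1
        lifetimes.append((steps + 1) * dt)
    mean = np.mean(lifetimes)
    # discrete geometric mean: dt/p ~ 1/k_d + dt/2
    assert abs(mean - 1.0 / k_d) / (1.0 / k_d) < 0.05


def test_severing_topology_and_fragment_binding():
    sys_, ff = make_bundle(2, 25)
    chain0 = list(sys_.chains[0])
    victim = chain0[10]
    sys_.nucleotide[victim] = st.ADP
    apply_sever(sys_, victim)
    sys_.rebuild_topology(ff)
    # 10-subunit tip-side fragment + freed monomer + 14-subunit anchored rest
    assert not sys_.polymerized[victim]
    frag = [c for c, f in zip(sys_.chains, sys_.chain_is_fragment) if f]
    assert len(frag) == 1 and len(frag[0]) == 10
    rest = sys_.chains[0]
    assert len(rest) == 14 and sys_.anchored[rest[-1]]
    # fragment subunits stay eligible for side binding, but not "in bundle"
    side = eligible_binders(sys_, ChemistryParams(binding_mode=BindingMode.SIDE))
    assert set(frag[0]) <= side
    assert not sys_.in_bundle[frag[0]].any()
    assert audit_topology(sys_)


def test_severing_step_requires_mode_and_interior_adp():
    sys_, ff = make_bundle(2, 10)
    with pytest.raises(ValueError):
        severing_step(sys_, ChemistryParams(), 0.1, np.random.default_rng(0))
    params = ChemistryParams(disassembly_mode=DisassemblyMode.SEVERING, k_d=1e9)
    # no interior ADP -> no severing, ever
    assert severing_step(sys_, params, 1.0, np.random.default_rng(0)) == []
    with pytest.raises(RuntimeError):
        apply_sever(sys_, sys_.chains[0][0])      # tips cannot sever


def test_audit_detects_broken_states():
    sys_, ff = make_bundle(2, 10)
    assert audit_topology(sys_, expect_anchored=True)
    bad = sys_.copy()
    bad.rebuild_topology(ff)
    bad.polymerized[bad.chains[0][3]] = False     # chain references a monomer
    res = audit_topology(bad)
    assert not res.ok and res.diagnostics


def test_conservation_and_tip_ordering_through_simulation():
    # mixed chemistry over many engine steps: count conserved, no interior
    # gaps in any filament's polymerized run, audit passes
    cfg = scenario("standard", geometry={
        "n_filaments": 4, "filament_length": 12, "parb_total_length": 30,
        "parb_binding_length": 24, "parb_relax_steps": 4000,
        "prebind_steps": 4000}, chemistry={"k_d": 0.1, "k_h": 30.0})
    cfg.integrator.seed = 17
    sys_ = build_system(cfg)
    n0 = sys_.n
    sim = Simulation(sys_, cfg.forcefield_params(), cfg.chemistry_params(),
                     cfg.integrator_params(), config=cfg)
    for _ in range(10):
        sim.run(20_000, sample_stride=0)
        assert sys_.n == n0                       # subunit count conserved
        assert audit_topology(sys_, expect_anchored=True)
        for chain, is_a in zip(sys_.chains, sys_.chain_is_parA):
            if is_a:
                assert all(sys_.polymerized[i] for i in chain)
    assert any(not sys_.polymerized[i] for i in range(n0)
               if sys_.species[i] == st.PARA)     # something depolymerized


def test_no_disassembly_negative_control():
    cfg = scenario("standard", geometry={
        "n_filaments": 3, "filament_length": 8, "parb_total_length": 20,
        "parb_binding_length": 16, "parb_relax_steps": 2000,
        "prebind_steps": 2000}, chemistry={"k_h": 0.0, "k_d": 0.1})
    cfg.integrator.seed = 18
    sys_ = build_system(cfg)
    sim = Simulation(sys_, cfg.forcefield_params(), cfg.chemistry_params(),
                     cfg.integrator_params(), config=cfg)
    res = sim.run(50_000, sample_stride=5000)
    assert len(res.events) == 0
    assert res.series.n_polymerized[-1] == res.series.n_polymerized[0]


def test_parameter_validation():
    with pytest.raises(ValueError):
        ChemistryParams(k_h=-1.0)
    with pytest.raises(ValueError):
        ChemistryParams(eps_threshold=0.0)
    with pytest.raises(ValueError):
        ChemistryParams(k_h=1000.0).validate_dt(1e-3)


def test_monomer_culling_is_optional_and_logged():
    from parabd.chemistry import cull_monomers

    sys_, ff = make_bundle(2, 10)
    # detach two tip subunits and move one far away
    for i in (0, 1):
        sys_.nucleotide[i] = st.ADP
        apply_depolymerization(sys_, i)
    sys_.rebuild_topology(ff)
    sys_.pos[0] += 100.0
    n = cull_monomers(sys_, distance=50.0)
    assert n == 1
    assert not sys_.active[0] and sys_.active[1]
    # conservation audit passes when culling is declared
    assert audit_topology(sys_, culling_enabled=True)
    assert not audit_topology(sys_).ok
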
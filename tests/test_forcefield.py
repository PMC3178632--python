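"""Force-field correctness: closed forms, gradients, symmetries, aggregation."""

import numpy as np
import pytest

from parabd import forcefield as ff_mod
from parabd.forcefield import (BindingForm, ForceFieldParams, bending, binding,
                               bond, crosslink, excluded_volume,
                               helical_coupling, polarization_alignment,
                               total_forces, total_forces_reference)

FF = ForceFieldParams()
RNG = np.random.default_rng(42)


def unit(v):
    return v / np.linalg.norm(v)


def rand_unit(rng):
    return unit(rng.normal(size=3))


# ---------------------------------------------------------------------------
# closed-form values
# ---------------------------------------------------------------------------

def test_excluded_volume_contact_behavior():
    # no overlap and exact contact carry zero energy and force
    for r in (1.5, 1.0):
        res = excluded_volume(np.array([r, 0.0, 0.0]), FF)
        assert res.energy == 0.0
        assert np.all(res.force_on_i == 0.0)
    res = excluded_volume(np.array([0.9, 0.0, 0.0]), FF)
    assert res.energy > 0.0
    assert res.force_on_i[0] > 0.0            # repulsive, along +r_ij
    assert np.allclose(res.force_on_j, -res.force_on_i)
    with pytest.raises(ValueError):
        excluded_volume(np.zeros(3), FF)


def test_bond_and_crosslink_closed_forms():
    p = ForceFieldParams(k_bond=100.0, k_crosslink=50.0, d0=2.0)
    assert bond(np.array([1.0, 0, 0]), p).energy == 0.0
    assert bond(np.array([1.1, 0, 0]), p).energy == pytest.approx(0.5)
    assert crosslink(np.array([2.0, 0, 0]), p).energy == 0.0
    assert crosslink(np.array([2.2, 0, 0]), p).energy == pytest.approx(1.0)
    # restoring direction
    assert bond(np.array([1.1, 0, 0]), p).force_on_i[0] < 0
    assert bond(np.array([0.9, 0, 0]), p).force_on_i[0] > 0


def test_bending_straight_and_symmetry():
    e0, forces = bending([0, 0, 0], [1, 0, 0], [2, 0, 0], FF)
    assert e0 == pytest.approx(0.0)
    assert all(np.allclose(f, 0) for f in forces)
    e1, _ = bending([0, 0, 0], [1, 0, 0], [1, 1, 0], FF)
    e2, _ = bending([0, 0, 0], [1, 0, 0], [1, -1, 0], FF)
    assert e1 > 0
    assert e1 == pytest.approx(e2)
    with pytest.raises(ValueError):
        bending([0, 0, 0], [0, 0, 0], [1, 0, 0], FF)


def test_alignment_minimum_and_extremum():
    b = [np.array([1.0, 0, 0]), np.array([-1.0, 0, 0])]
    e_perp, tq, _ = polarization_alignment(np.array([0, 0, 1.0]), b, FF)
    assert e_perp == pytest.approx(0.0)
    assert np.allclose(tq, 0.0)
    # parallel orientation is the energy maximum over sampled orientations
    rng = np.random.default_rng(0)
    e_par, _, _ = polarization_alignment(np.array([1.0, 0, 0]), b, FF)
    for _ in range(200):
        e, _, _ = polarization_alignment(rand_unit(rng), b, FF)
        assert e <= e_par + 1e-12
    with pytest.raises(ValueError):
        polarization_alignment(np.array([0, 0, 1.0]), [np.zeros(3)], FF)


def test_helical_coupling_minimum_and_nonhelical_limit():
    psi = np.deg2rad(FF.psi_nn_parA_deg)
    p_i = np.array([0, 1.0, 0])
    p_j = np.array([0, np.cos(psi), np.sin(psi)])
    e, tq_i, tq_j = helical_coupling(p_i, p_j, "nn", FF)
    assert e == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(tq_i, 0, atol=1e-12) and np.allclose(tq_j, 0, atol=1e-12)
    flat = ForceFieldParams(psi_nn_parA_deg=0.0)
    e0, _, _ = helical_coupling(p_i, p_i, "nn", flat)
    assert e0 == pytest.approx(0.0)
    with pytest.raises(ValueError):
        helical_coupling(p_i, p_j, "next", FF)


def test_binding_normalization_and_cutoff():
    # optimal geometry: r = r_b, polarizations facing each other along r_hat
    r_ij = np.array([-FF.r_b, 0.0, 0.0])     # ParB at +x of ParA
    p_i = np.array([1.0, 0, 0])              # ParA site points at ParB
    p_j = np.array([-1.0, 0, 0])             # ParB site points back
    res = binding(r_ij, p_i, p_j, FF)
    assert res.energy == pytest.approx(-FF.eps_b)
    far = binding(np.array([-1.6, 0, 0]), p_i, p_j, FF)
    assert far.energy == 0.0
    assert np.all(far.force_on_i == 0.0)


def test_binding_bounded_below_by_well_depth():
    # energy >= -eps_b over a large random sample of geometries
    rng = np.random.default_rng(1)
    n = 120_000
    rvec = rng.uniform(-1.6, 1.6, size=(n, 3))
    for form in (BindingForm.ORIENTED, BindingForm.SIDE_NO_PARB_POLAR):
        p = ForceFieldParams(binding_form=form)
        # vectorized closed-form evaluation of the same expression
        r = np.linalg.norm(rvec, axis=1)
        ok = (r > 1e-9)
        u_hat = -(rvec[ok].T / r[ok]).T
        pi = rng.normal(size=(ok.sum(), 3))
        pi = (pi.T / np.linalg.norm(pi, axis=1)).T
        pj = rng.normal(size=(ok.sum(), 3))
        pj = (pj.T / np.linalg.norm(pj, axis=1)).T
        delta = p.range_b - p.r_b
        s = (r[ok] - p.r_b) / delta
        f = np.where(np.abs(s) < 1, (1 - s ** 2) ** 2, 0.0)
        k1, k2, k3 = p.ang_widths
        h = np.exp(-(1 - np.sum(pi * u_hat, axis=1)) ** 2 / (2 * k1 ** 2))
        if form is BindingForm.ORIENTED:
            h = h * np.exp(-(1 + np.sum(pj * u_hat, axis=1)) ** 2 / (2 * k2 ** 2))
            h = h * np.exp(-(1 + np.sum(pi * pj, axis=1)) ** 2 / (2 * k3 ** 2))
        u = -p.eps_b * f * h
        assert u.min() >= -p.eps_b - 1e-12
        # spot-check the vectorized sample against the scalar implementation
        for idx in rng.integers(0, ok.sum(), 50):
            res = binding(rvec[ok][idx], pi[idx], pj[idx], p)
            assert res.energy == pytest.approx(u[idx], abs=1e-12)


# ---------------------------------------------------------------------------
# finite-difference oracles: every force/torque is the exact gradient
# ---------------------------------------------------------------------------

def fd_force(efunc, x0, h=1e-6):
    """Central-difference gradient of a scalar energy function."""
    g = np.zeros_like(x0, dtype=float)
    for k in range(len(x0)):
        dx = np.zeros_like(g)
        dx[k] = h
        g[k] = (efunc(x0 + dx) - efunc(x0 - dx)) / (2 * h)
    return -g


def fd_torque(efunc_of_p, p0, h=1e-6):
    """Rotational gradient: torque components about the lab axes."""
    t = np.zeros(3)
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        def rot(theta):
            w = axis * theta
            return p0 + np.cross(w, p0)  # first-order rotation, renormalized
        pp = rot(h)
        pm = rot(-h)
        t[k] = -(efunc_of_p(pp / np.linalg.norm(pp))
                 - efunc_of_p(pm / np.linalg.norm(pm))) / (2 * h)
    return t


@pytest.mark.parametrize("kind", ["ev", "bond", "crosslink"])
def test_radial_pair_forces_match_finite_difference(kind):
    func = {"ev": excluded_volume, "bond": bond, "crosslink": crosslink}[kind]
    rng = np.random.default_rng(3)
    for _ in range(20):
        rv = rng.uniform(0.5, 2.4) * rand_unit(rng)
        res = func(rv, FF)
        g = fd_force(lambda x: func(x, FF).energy, rv)
        scale = max(1.0, np.abs(res.force_on_i).max())
        assert np.allclose(res.force_on_i, g, atol=1e-5 * scale)


def test_bending_forces_match_finite_difference():
    rng = np.random.default_rng(4)
    for _ in range(15):
        pts = rng.normal(size=(3, 3)) * 1.2
        _, forces = bending(*pts, FF)
        for bead in range(3):
            def e_of(x, bead=bead):
                q = pts.copy()
                q[bead] = x
                return bending(*q, FF)[0]
            g = fd_force(e_of, pts[bead], h=1e-6)
            assert np.allclose(forces[bead], g, atol=1e-5 * max(1, np.abs(g).max()))
        assert np.allclose(sum(forces), 0.0, atol=1e-9)


def test_alignment_gradients_match_finite_difference():
    rng = np.random.default_rng(5)
    for _ in range(15):
        p = rand_unit(rng)
        b = [rng.normal(size=3) for _ in range(2)]
        e, tq, tip_f = polarization_alignment(p, b, FF)
        t_fd = fd_torque(lambda pp: polarization_alignment(pp, b, FF)[0], p)
        assert np.allclose(tq, t_fd, atol=1e-5 * max(1, np.abs(tq).max()))
        for n_b in range(2):
            def e_of(x, n_b=n_b):
                bb = [v.copy() for v in b]
                bb[n_b] = x
                return polarization_alignment(p, bb, FF)[0]
            g = fd_force(e_of, b[n_b])
            assert np.allclose(tip_f[n_b], g, atol=1e-5 * max(1, np.abs(g).max()))


def test_helical_torques_match_finite_difference():
    rng = np.random.default_rng(6)
    for order in ("nn", "nnn"):
        for _ in range(10):
            p_i, p_j = rand_unit(rng), rand_unit(rng)
            _, tq_i, tq_j = helical_coupling(p_i, p_j, order, FF)
            ti = fd_torque(lambda p: helical_coupling(p, p_j, order, FF)[0], p_i)
            tj = fd_torque(lambda p: helical_coupling(p_i, p, order, FF)[0], p_j)
            assert np.allclose(tq_i, ti, atol=1e-5 * max(1, np.abs(tq_i).max()))
            assert np.allclose(tq_j, tj, atol=1e-5 * max(1, np.abs(tq_j).max()))


@pytest.mark.parametrize("form", [BindingForm.ORIENTED,
                                  BindingForm.TIP_NO_PARB_POLAR])
def test_binding_gradients_match_finite_difference(form):
    p = ForceFieldParams(binding_form=form)
    rng = np.random.default_rng(7)
    done = 0
    while done < 15:
        rv = rng.uniform(0.6, 1.45) * rand_unit(rng)
        p_i, p_j = rand_unit(rng), rand_unit(rng)
        res = binding(rv, p_i, p_j, p)
        if res.energy == 0.0:
            continue
        done += 1
        g = fd_force(lambda x: binding(x, p_i, p_j, p).energy, rv)
        assert np.allclose(res.force_on_i, g, atol=1e-5 * max(1, np.abs(g).max()))
        t_i = fd_torque(lambda q: binding(rv, q, p_j, p).energy, p_i)
        assert np.allclose(res.torque_on_i, t_i,
                           atol=1e-5 * max(1, np.abs(t_i).max()))
        t_j = fd_torque(lambda q: binding(rv, p_i, q, p).energy, p_j)
        assert np.allclose(res.torque_on_j, t_j,
                           atol=1e-5 * max(1, np.abs(t_j).max()))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_total_forces_engine_matches_brute_force(tiny_system):
    cfg, system = tiny_system
    ffp = cfg.forcefield_params()
    e1, f1, t1, table1 = total_forces(system, ffp)
    e2, f2, t2, table2 = total_forces_reference(system, ffp)
    assert e1 == pytest.approx(e2, rel=1e-12)
    assert np.allclose(f1, f2, atol=1e-9)
    assert np.allclose(t1, t2, atol=1e-9)
    assert set(table1) == set(table2)
    for k in table1:
        assert table1[k] == pytest.approx(table2[k], rel=1e-10)
    # internal forces sum to zero (no anchors contribute reaction here:
    # sum over ALL subunits including anchored ones)
    assert np.allclose(f1.sum(axis=0), 0.0, atol=1e-8)


def test_total_forces_neighbor_list_invariance(tiny_system):
    cfg, system = tiny_system
    ffp = cfg.forcefield_params()
    from parabd.engine import evaluate_forces

    e1, f1, *_ = evaluate_forces(system, ffp, use_neighbor_list=True)
    e2, f2, *_ = evaluate_forces(system, ffp, use_neighbor_list=False)
    assert e1 == pytest.approx(e2, abs=1e-10)
    assert np.allclose(f1, f2, atol=1e-10)


def test_total_forces_flags_nan(tiny_system):
    cfg, system = tiny_system
    bad = system.copy()
    bad.rebuild_topology(cfg.forcefield_params())
    bad.pos[3, 1] = np.nan
    with pytest.raises(FloatingPointError, match="3"):
        total_forces(bad, cfg.forcefield_params())


from hypothesis import given, settings
from hypothesis import strategies as hst


@settings(max_examples=60, deadline=None, derandomize=True)
@given(hst.lists(hst.floats(-2.0, 2.0), min_size=9, max_size=9))
def test_pair_energy_bounds_and_antisymmetry_property(raw):
    """For arbitrary geometries: finite energies, Newton's third law, and the
    binding well never deeper than -eps_b."""
    v = np.asarray(raw)
    rv, pi_raw, pj_raw = v[:3], v[3:6], v[6:9]
    if np.linalg.norm(rv) < 1e-3:
        rv = np.array([1.0, 0.0, 0.0])
    if np.linalg.norm(pi_raw) < 1e-3 or np.linalg.norm(pj_raw) < 1e-3:
        return
    p_i, p_j = unit(pi_raw), unit(pj_raw)
    for func in (excluded_volume, bond, crosslink):
        res = func(rv, FF)
        assert np.isfinite(res.energy)
        assert np.allclose(res.force_on_j, -res.force_on_i)
    res = binding(rv, p_i, p_j, FF)
    assert -FF.eps_b - 1e-12 <= res.energy <= 0.0
    assert np.allclose(res.force_on_j, -res.force_on_i)


def test_parameter_validation():
    with pytest.raises(ValueError):
        ForceFieldParams(k_bond=-1.0)
    with pytest.raises(ValueError):
        ForceFieldParams(r_b=2.0, range_b=1.5)
    with pytest.raises(ValueError):
        ForceFieldParams(d0=0.5)
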
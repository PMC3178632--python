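"""Interaction energies, forces and torques.

This module is the *reference* implementation of every interaction in the
model: plain numpy, one function per interaction, each returning energies
together with exact analytic gradients.  The fused numba kernel in
:mod:`parabd.engine` reimplements the same mathematics for speed and is tested
against this module (see ``total_forces_reference``).

Interaction kinds
-----------------
excluded volume
    purely repulsive soft harmonic sphere overlap ``(k_ev/2)(r - a)**2`` for
    ``r < a``, zero at and beyond contact; every pair of subunits feels it.
    A bounded-force soft core keeps the Brownian integrator stable at
    practical time steps while making overlaps much deeper than thermal
    (~0.1 a at the default stiffness) prohibitively costly.
bond / crosslink
    harmonic springs with rest lengths ``a`` and ``d0`` respectively.
bending
    ``k_bend * (1 - cos(theta))`` on consecutive bond-vector pairs, minimised
    at the straight configuration.
polarization alignment
    keeps each subunit's binding-site direction ``p`` at a target angle to the
    adjacent bond vectors (perpendicular in the standard, side-binding model).
helical couplings
    nearest- and next-nearest-neighbour couplings between polarization
    vectors; their target angles set the pitch of the helix of binding sites.
binding
    short-ranged, orientation-selective ParA-ParB attraction with well depth
    ``eps_b`` at separation ``r_b``; variants without ParB orientation drop
    the ParB angular factors.

Angular potentials are harmonic in the *cosine* of the angle, which shares
the minima and symmetries of an angle-harmonic form but is smooth at the
parallel/antiparallel configurations, so forces and torques are exact
gradients everywhere.

Sign conventions: ``r_ij = r_i - r_j`` for pair terms (force returned for
subunit *i*; the force on *j* is its negative); ``torque = -p x dU/dp``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BindingForm",
    "ForceFieldParams",
    "PairInteractionResult",
    "excluded_volume",
    "bond",
    "crosslink",
    "bending",
    "polarization_alignment",
    "helical_coupling",
    "binding",
    "total_forces",
    "total_forces_reference",
]


class BindingForm(enum.Enum):
    """Functional form of the ParA-ParB binding potential."""

    ORIENTED = "oriented"                  # full form: both polarizations enter
    TIP_NO_PARB_POLAR = "tip_no_parb_polar"    # ParB carries no polarization
    SIDE_NO_PARB_POLAR = "side_no_parb_polar"  # ParB carries no polarization


@dataclass
class ForceFieldParams:
    """All interaction constants, in reduced units (lengths in a, energies in kT).

    Defaults make filaments effectively rigid on bundle scales and keep bond
    fluctuations well below a subunit diameter; every value is overridable
    through the run configuration.
    """

    subunit_diameter_a: float = 1.0
    k_ev: float = 100.0            # kT / a^2, soft-core repulsion stiffness
    k_bond: float = 100.0          # kT / a^2
    k_crosslink: float = 50.0      # kT / a^2
    d0: float = 2.0                # crosslink rest length = initial filament spacing
    k_bend_parA: float = 50.0      # kT
    k_bend_parB: float = 0.0       # kT (flexible ParB polymer in the standard model)
    k_align: float = 10.0          # kT
    theta0_deg: float = 90.0       # binding site perpendicular to the chain (side-binding)
    k_helix_nn: float = 10.0       # kT
    k_helix_nnn: float = 10.0      # kT
    psi_nn_parA_deg: float = 60.0   # ~6 binding sites per turn
    psi_nnn_parA_deg: float = 120.0
    psi_nn_parB_deg: float = 30.0   # looser ParB helix
    psi_nnn_parB_deg: float = 60.0
    eps_b: float = 10.0            # kT, binding well depth
    r_b: float = 1.0               # a, binding minimum (at contact)
    range_b: float = 1.5           # a, binding cutoff
    ang_widths: tuple = (0.6, 0.6, 0.6)  # cosine-space selectivity widths
    binding_form: BindingForm = BindingForm.ORIENTED

    def __post_init__(self) -> None:
        if isinstance(self.binding_form, str):
            self.binding_form = BindingForm(self.binding_form)
        self.ang_widths = tuple(float(w) for w in self.ang_widths)
        for name in ("k_ev", "k_bond", "k_crosslink", "k_bend_parA",
                     "k_bend_parB", "k_align", "k_helix_nn", "k_helix_nnn",
                     "eps_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.r_b > self.range_b:
            raise ValueError("r_b must not exceed range_b")
        if self.d0 < self.subunit_diameter_a:
            raise ValueError("d0 must be >= subunit diameter")


@dataclass
class PairInteractionResult:
    """Energy, force on subunit i, and torques for a single pair term.

    ``force_on_j`` is always ``-force_on_i``; torques are exactly zero for
    orientation-independent potentials.
    """

    energy: float
    force_on_i: np.ndarray
    torque_on_i: np.ndarray = field(default_factory=lambda: np.zeros(3))
    torque_on_j: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def force_on_j(self) -> np.ndarray:
        return -self.force_on_i


# ---------------------------------------------------------------------------
# pair potentials
# ---------------------------------------------------------------------------

def _softcore(r: float, a: float, k: float):
    """Soft-sphere overlap energy and dU/dr, zero at and beyond contact."""
    if r >= a:
        return 0.0, 0.0
    return 0.5 * k * (r - a) ** 2, k * (r - a)


def excluded_volume(r_ij: np.ndarray, params: ForceFieldParams) -> PairInteractionResult:
    """Steric repulsion between overlapping subunits (zero for r >= a)."""
    r_ij = np.asarray(r_ij, dtype=float)
    r = float(np.linalg.norm(r_ij))
    if r == 0.0:
        raise ValueError("overlapping subunit centers (r = 0) are unphysical")
    u, dudr = _softcore(r, params.subunit_diameter_a, params.k_ev)
    return PairInteractionResult(u, -dudr * r_ij / r)


def _harmonic(r_ij: np.ndarray, k: float, r0: float) -> PairInteractionResult:
    r_ij = np.asarray(r_ij, dtype=float)
    r = float(np.linalg.norm(r_ij))
    if r == 0.0:
        raise ValueError("overlapping subunit centers (r = 0) are unphysical")
    u = 0.5 * k * (r - r0) ** 2
    return PairInteractionResult(u, -k * (r - r0) * r_ij / r)


def bond(r_ij: np.ndarray, params: ForceFieldParams) -> PairInteractionResult:
    """Harmonic chain bond with rest length a."""
    return _harmonic(r_ij, params.k_bond, params.subunit_diameter_a)


def crosslink(r_ij: np.ndarray, params: ForceFieldParams) -> PairInteractionResult:
    """Harmonic inter-filament crosslink with rest length d0."""
    return _harmonic(r_ij, params.k_crosslink, params.d0)


# ---------------------------------------------------------------------------
# bending
# ---------------------------------------------------------------------------

def bending(r_prev, r_mid, r_next, params: ForceFieldParams, k: float | None = None):
    """Bending energy k*(1 - cos theta) on a bonded triple and its forces.

    Returns ``(energy, (f_prev, f_mid, f_next))``; the three forces sum to
    zero.  ``k`` defaults to ``k_bend_parA``.
    """
    if k is None:
        k = params.k_bend_parA
    b1 = np.asarray(r_mid, float) - np.asarray(r_prev, float)
    b2 = np.asarray(r_next, float) - np.asarray(r_mid, float)
    l1 = float(np.linalg.norm(b1))
    l2 = float(np.linalg.norm(b2))
    if l1 == 0.0 or l2 == 0.0:
        raise ValueError("degenerate bending angle: coincident points")
    b1h, b2h = b1 / l1, b2 / l2
    c = float(b1h @ b2h)
    u = k * (1.0 - c)
    dc_db1 = (b2h - c * b1h) / l1
    dc_db2 = (b1h - c * b2h) / l2
    # U = k(1-c): dU/dc = -k
    f_prev = -k * dc_db1
    f_next = k * dc_db2
    f_mid = -(f_prev + f_next)
    return u, (f_prev, f_mid, f_next)


# ---------------------------------------------------------------------------
# polarization potentials
# ---------------------------------------------------------------------------

def polarization_alignment(p_i, bond_vectors, params: ForceFieldParams,
                           cos_theta0: float | None = None):
    """Alignment of a polarization vector to the adjacent bond vectors.

    ``U = (k_align/2) * sum_b (p.b_hat - cos(theta0))**2`` over the supplied
    bond vectors (each pointing from the subunit to a chain neighbour).

    Returns ``(energy, torque_on_p, forces_on_bond_tips)`` where the n-th
    force acts on the far endpoint of the n-th bond vector (the equal and
    opposite force acts on the subunit itself).
    """
    p = np.asarray(p_i, float)
    if abs(np.linalg.norm(p) - 1.0) > 1e-8:
        raise ValueError("polarization vector must be unit length")
    if cos_theta0 is None:
        cos_theta0 = float(np.cos(np.deg2rad(params.theta0_deg)))
    k = params.k_align
    u = 0.0
    grad_p = np.zeros(3)
    tip_forces = []
    for b in bond_vectors:
        b = np.asarray(b, float)
        l = float(np.linalg.norm(b))
        if l == 0.0:
            raise ValueError("degenerate (zero-length) bond vector")
        bh = b / l
        c = float(p @ bh)
        u += 0.5 * k * (c - cos_theta0) ** 2
        grad_p += k * (c - cos_theta0) * bh
        du_db = k * (c - cos_theta0) * (p - c * bh) / l
        # b = r_tip - r_self: force on tip = -dU/dr_tip = -dU/db
        tip_forces.append(-du_db)
    torque = -np.cross(p, grad_p)
    return u, torque, tip_forces


def helical_coupling(p_i, p_j, neighbor_order: str, params: ForceFieldParams,
                     species: str = "parA"):
    """Pitch-setting coupling between two polarization vectors.

    ``U = (k/2) * (p_i.p_j - cos(psi))**2`` with the pitch angle psi chosen by
    ``neighbor_order`` ("nn" or "nnn") and ``species`` ("parA" or "parB").
    Returns ``(energy, torque_on_i, torque_on_j)``.
    """
    p_i = np.asarray(p_i, float)
    p_j = np.asarray(p_j, float)
    if neighbor_order == "nn":
        k = params.k_helix_nn
        psi = params.psi_nn_parA_deg if species == "parA" else params.psi_nn_parB_deg
    elif neighbor_order == "nnn":
        k = params.k_helix_nnn
        psi = params.psi_nnn_parA_deg if species == "parA" else params.psi_nnn_parB_deg
    else:
        raise ValueError("neighbor_order must be 'nn' or 'nnn'")
    c0 = float(np.cos(np.deg2rad(psi)))
    c = float(p_i @ p_j)
    u = 0.5 * k * (c - c0) ** 2
    grad_i = k * (c - c0) * p_j
    grad_j = k * (c - c0) * p_i
    return u, -np.cross(p_i, grad_i), -np.cross(p_j, grad_j)


# ---------------------------------------------------------------------------
# ParA-ParB binding
# ---------------------------------------------------------------------------

def _radial_bump(r: float, r_b: float, range_b: float):
    """Quartic bump: 1 at r_b, C1-smooth to 0 at |r - r_b| = range_b - r_b."""
    delta = range_b - r_b
    s = (r - r_b) / delta
    if abs(s) >= 1.0:
        return 0.0, 0.0
    f = (1.0 - s * s) ** 2
    dfdr = -4.0 * s * (1.0 - s * s) / delta
    return f, dfdr


def _ang(c: float, kappa: float):
    """Bounded angular factor exp(-(1-c)^2 / (2 kappa^2)), max 1 at c = 1."""
    h = np.exp(-((1.0 - c) ** 2) / (2.0 * kappa * kappa))
    dhdc = h * (1.0 - c) / (kappa * kappa)
    return float(h), float(dhdc)


def binding(r_ij, p_i, p_j, params: ForceFieldParams) -> PairInteractionResult:
    """Site-specific short-ranged ParA-ParB attraction.

    *i* is the ParA subunit, *j* the ParB subunit, ``r_ij = r_i - r_j``.
    The well depth is exactly ``-eps_b``, attained at separation ``r_b`` with
    the two polarizations antiparallel and pointing at each other; the
    potential vanishes smoothly at ``range_b``.  For the no-ParB-polarization
    variants only the ParA orientation factor is kept.
    """
    r_ij = np.asarray(r_ij, float)
    r = float(np.linalg.norm(r_ij))
    if r == 0.0:
        raise ValueError("overlapping subunit centers (r = 0) are unphysical")
    f, dfdr = _radial_bump(r, params.r_b, params.range_b)
    if f == 0.0:
        return PairInteractionResult(0.0, np.zeros(3))
    u_hat = -r_ij / r  # from ParA (i) towards ParB (j)
    p_i = np.asarray(p_i, float)
    k1, k2, k3 = params.ang_widths
    c1 = float(p_i @ u_hat)
    h1, dh1 = _ang(c1, k1)
    oriented = params.binding_form is BindingForm.ORIENTED
    if oriented:
        p_j = np.asarray(p_j, float)
        c2 = float(-(p_j @ u_hat))
        c3 = float(-(p_i @ p_j))
        h2, dh2 = _ang(c2, k2)
        h3, dh3 = _ang(c3, k3)
    else:
        h2 = h3 = 1.0
        dh2 = dh3 = 0.0
    eps = params.eps_b
    u = -eps * f * h1 * h2 * h3
    # radial part
    du_dr = -eps * dfdr * h1 * h2 * h3
    # dU/dc gradients
    du_dc1 = -eps * f * dh1 * h2 * h3
    # position gradient: r depends on r_i via +r_hat(ij); u_hat = -(r_i - r_j)/r
    # d u_hat / d r_i = -(I - u u^T)/r  (with u = u_hat)
    perp_i = (p_i - c1 * u_hat)
    grad_i = du_dr * (r_ij / r) + du_dc1 * (-(perp_i) / r)
    torque_i = np.zeros(3)
    torque_j = np.zeros(3)
    grad_p_i = du_dc1 * u_hat
    if oriented:
        du_dc2 = -eps * f * h1 * dh2 * h3
        du_dc3 = -eps * f * h1 * h2 * dh3
        perp_j = (p_j - (p_j @ u_hat) * u_hat)
        grad_i += du_dc2 * (perp_j / r)
        grad_p_i += du_dc3 * (-p_j)
        grad_p_j = du_dc2 * (-u_hat) + du_dc3 * (-p_i)
        torque_j = -np.cross(p_j, grad_p_j)
    torque_i = -np.cross(p_i, grad_p_i)
    return PairInteractionResult(u, -grad_i, torque_i, torque_j)


# ---------------------------------------------------------------------------
# system-level aggregation (reference path)
# ---------------------------------------------------------------------------

def total_forces_reference(state, params: ForceFieldParams):
    """Brute-force all-pairs evaluation of every interaction in a system.

    Slow, loop-based aggregation used as the oracle for the fused numba
    kernel.  Returns ``(energy, forces, torques, bind_table)`` where
    ``bind_table`` maps ``(parA_id, parB_id) -> binding energy`` for every
    eligible pair within ``range_b``.
    """
    from . import state as state_mod  # local import to avoid a cycle

    n = state.n
    pos = state.pos
    pol = state.pol
    forces = np.zeros((n, 3))
    torques = np.zeros((n, 3))
    energy = 0.0
    if np.isnan(pos).any():
        bad = int(np.argwhere(np.isnan(pos))[0][0])
        raise FloatingPointError(f"NaN coordinate on subunit {bad}: integration blow-up")

    # excluded volume: all pairs
    for i in range(n):
        for j in range(i + 1, n):
            rij = pos[i] - pos[j]
            if np.linalg.norm(rij) < params.subunit_diameter_a:
                res = excluded_volume(rij, params)
                energy += res.energy
                forces[i] += res.force_on_i
                forces[j] -= res.force_on_i

    # bonds, bending, alignment, helix from topology
    for i, j in state.bonds:
        res = bond(pos[i] - pos[j], params)
        energy += res.energy
        forces[i] += res.force_on_i
        forces[j] -= res.force_on_i
    for i, j in state.crosslinks:
        if not (state.polymerized[i] and state.polymerized[j]):
            raise RuntimeError(
                f"stale topology: crosslink ({i},{j}) references a depolymerized subunit")
        res = crosslink(pos[i] - pos[j], params)
        energy += res.energy
        forces[i] += res.force_on_i
        forces[j] -= res.force_on_i
    for (i, j, k_id), kb in zip(state.angles, state.angle_k):
        if kb == 0.0:
            continue
        u, (fp, fm, fn) = bending(pos[i], pos[j], pos[k_id], params, k=kb)
        energy += u
        forces[i] += fp
        forces[j] += fm
        forces[k_id] += fn
    for (i, j), c0 in zip(state.align_pairs, state.align_c0):
        b = pos[j] - pos[i]
        u, tq, tip_f = polarization_alignment(pol[i], [b], params, cos_theta0=c0)
        energy += u
        torques[i] += tq
        forces[j] += tip_f[0]
        forces[i] -= tip_f[0]
    for (i, j), kh, c0 in zip(state.helix_pairs, state.helix_k, state.helix_c0):
        c = float(pol[i] @ pol[j])
        u = 0.5 * kh * (c - c0) ** 2
        gi = kh * (c - c0) * pol[j]
        gj = kh * (c - c0) * pol[i]
        energy += u
        torques[i] += -np.cross(pol[i], gi)
        torques[j] += -np.cross(pol[j], gj)

    # binding: eligible ParA x ParB binding strip
    bind_table = {}
    elig = state.bind_eligible
    for i in range(n):
        if not elig[i]:
            continue
        for j in range(n):
            if state.species[j] != state_mod.PARB_BIND:
                continue
            rij = pos[i] - pos[j]
            r = np.linalg.norm(rij)
            if r >= params.range_b:
                continue
            res = binding(rij, pol[i], pol[j], params)
            if res.energy != 0.0:
                bind_table[(i, j)] = res.energy
            energy += res.energy
            forces[i] += res.force_on_i
            forces[j] -= res.force_on_i
            torques[i] += res.torque_on_i
            torques[j] += res.torque_on_j
    return energy, forces, torques, bind_table


def total_forces(state, params: ForceFieldParams, integ=None):
    """Forces, torques and the ParA-ParB binding-energy table for a system.

    Fast path through the numba engine; semantics identical to
    :func:`total_forces_reference`.
    """
    from .engine import evaluate_forces

    return evaluate_forces(state, params)
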
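"""Programmatic construction of initial systems and scenario presets.

``build_bundle`` lays parallel ParA filaments along +x (anchored end at large
x, free disassembling tips at x = 0), crosslinks a configured fraction of
subunits to the nearest neighbouring filament, and initializes the helical
binding-site polarizations.  ``build_parb_polymer`` grows a self-avoiding
ParB chain, relaxes it with chemistry off, and labels its central binding
strip.  ``build_system`` assembles the two, placing the ParB center of mass
one radius of gyration from the bundle tips and pre-binding it with a short
chemistry-off relaxation.  ``scenario`` is the catalog of presets.

Everything is deterministic given a configuration and a seed; this module is
the package's fixture generator.
"""

from __future__ import annotations

import numpy as np

from . import state as st
from .config import GeometryModel, RunConfig
from .forcefield import ForceFieldParams

__all__ = ["GeometrySpec", "build_bundle", "build_parb_polymer",
           "build_system", "scenario", "SCENARIOS"]

# the geometry schema doubles as the in-memory spec
GeometrySpec = GeometryModel


# ---------------------------------------------------------------------------
# lattice helpers
# ---------------------------------------------------------------------------

def _hex_sites(n: int, spacing: float) -> np.ndarray:
    """First n sites of a triangular lattice, sorted radially (1 + 6 + 12...)."""
    pts = []
    m = int(np.ceil(np.sqrt(n))) + 2
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            y = spacing * (i + 0.5 * j)
            z = spacing * (np.sqrt(3.0) / 2.0) * j
            pts.append((np.hypot(y, z), np.arctan2(z, y), y, z))
    pts.sort()
    return np.array([(y, z) for _, _, y, z in pts[:n]])


def _tube_sites(n: int, spacing: float) -> np.ndarray:
    if n == 1:
        return np.zeros((1, 2))
    radius = spacing / (2.0 * np.sin(np.pi / n))
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_bundle(spec: GeometrySpec, ff: ForceFieldParams,
                 rng: np.random.Generator):
    """ParA filament positions, polarizations, chains and crosslink list.

    Returns ``(pos, pol, chains, crosslinks, anchored)`` with subunit ids
    numbered filament-major, chain order tip -> anchor.
    """
    nf, L = spec.n_filaments, spec.filament_length
    a = ff.subunit_diameter_a
    sites = (_hex_sites if spec.arrangement == "packed_bundle" else _tube_sites)(
        nf, spec.spacing)
    pos = np.empty((nf * L, 3))
    pol = np.empty((nf * L, 3))
    anchored = np.zeros(nf * L, dtype=bool)
    chains = []
    psi = np.deg2rad(ff.psi_nn_parA_deg)
    outward = ff.theta0_deg > 135.0   # tip-binding variant: sites point out the tip
    for f in range(nf):
        ids = list(range(f * L, (f + 1) * L))
        chains.append(ids)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        for k, sid in enumerate(ids):
            pos[sid] = (k * a, sites[f, 0], sites[f, 1])
            if outward:
                pol[sid] = (-1.0, 0.0, 0.0)
            else:
                ang = phase + k * psi
                pol[sid] = (0.0, np.cos(ang), np.sin(ang))
        if spec.anchored:
            anchored[ids[-1]] = True

    # crosslinks: a random fraction of subunits, each tied to the same-index
    # subunit of the nearest neighbouring filament
    crosslinks = []
    n_x = int(round(spec.crosslink_fraction * nf * L))
    if n_x and nf > 1:
        d2 = ((sites[None, :, :] - sites[:, None, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        nearest = d2.argmin(axis=1)
        chosen = rng.choice(nf * L, size=n_x, replace=False)
        for sid in np.sort(chosen):
            f, k = divmod(int(sid), L)
            crosslinks.append((sid, nearest[f] * L + k))
    return pos, pol, chains, np.asarray(crosslinks, dtype=np.int32).reshape(-1, 2), anchored


def _self_avoiding_walk(n: int, a: float, rng: np.random.Generator) -> np.ndarray:
    """Random-walk chain with bond length a and hard-core rejection at 0.9 a."""
    for _attempt in range(200):
        pos = np.zeros((n, 3))
        ok = True
        for k in range(1, n):
            placed = False
            for _try in range(60):
                v = rng.normal(size=3)
                v *= a / np.linalg.norm(v)
                cand = pos[k - 1] + v
                if k < 2 or np.min(np.linalg.norm(pos[:k - 1] - cand, axis=1)) > 0.9 * a:
                    pos[k] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return pos
    raise RuntimeError("self-avoiding walk failed to place the ParB chain")


def _chain_polarizations(pos: np.ndarray, psi_deg: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Unit vectors perpendicular to the local chain direction, twisted by psi."""
    n = len(pos)
    pol = np.empty((n, 3))
    psi = np.deg2rad(psi_deg)
    for k in range(n):
        lo, hi = max(0, k - 1), min(n - 1, k + 1)
        t = pos[hi] - pos[lo]
        t /= np.linalg.norm(t)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(t @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(t, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        ang = k * psi
        pol[k] = np.cos(ang) * e1 + np.sin(ang) * e2
    return pol


def _parb_state(spec: GeometrySpec, ff: ForceFieldParams,
                rng: np.random.Generator) -> st.SystemState:
    n = spec.parb_total_length
    nb = spec.parb_binding_length
    start = (n - nb) // 2
    species = np.full(n, st.PARB_INERT, dtype=np.int8)
    species[start:start + nb] = st.PARB_BIND
    alpha = np.where(species == st.PARB_BIND, spec.alpha_parb_bind,
                     spec.alpha_inert).astype(float)
    pos = _self_avoiding_walk(n, ff.subunit_diameter_a, rng)
    pol = _chain_polarizations(pos, ff.psi_nn_parB_deg, rng)
    sys_ = st.SystemState(
        pos=pos, pol=pol, species=species,
        nucleotide=np.full(n, st.NA, dtype=np.int8),
        alpha=alpha, anchored=np.zeros(n, dtype=bool),
        polymerized=np.ones(n, dtype=bool),
        has_pol=np.ones(n, dtype=bool),
        chains=[list(range(n))], chain_is_parA=[False],
        crosslinks=np.empty((0, 2), np.int32))
    return sys_


def build_parb_polymer(spec: GeometrySpec, ff: ForceFieldParams,
                       rng: np.random.Generator, integ=None,
                       relax: bool = True) -> st.SystemState:
    """Free ParB polymer: 'inert | binding strip | inert', briefly equilibrated."""
    from .dynamics import IntegratorParams
    from .simulate import Simulation

    sys_ = _parb_state(spec, ff, rng)
    sys_.rebuild_topology(ff)
    if relax and spec.parb_relax_steps > 0:
        if integ is None:
            integ = IntegratorParams(dt=1e-3, seed=int(rng.integers(2 ** 31)))
        from .chemistry import ChemistryParams

        chem = ChemistryParams(k_h=0.0, k_d=0.0, eps_threshold=1.0)
        sim = Simulation(sys_, ff, chem, integ)
        sim.run(spec.parb_relax_steps, sample_stride=0)
    return sys_


def build_system(config: RunConfig, rng: np.random.Generator | int | None = None
                 ) -> st.SystemState:
    """Full initial state for a run configuration (bundle + attached ParB)."""
    from .chemistry import BindingMode, ChemistryParams
    from .simulate import Simulation

    spec = config.geometry
    ff = config.forcefield_params()
    integ = config.integrator_params()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(integ.seed if rng is None else int(rng))

    apos, apol, achains, xlinks, aanch = build_bundle(spec, ff, rng)
    na = len(apos)
    parb = build_parb_polymer(spec, ff, rng,
                              integ=_relax_integrator(integ, rng))
    nb = parb.n

    # place ParB: COM on the bundle axis, one Rg_x (or the configured offset)
    # ahead of the free tips in -x
    com = parb.pos.mean(axis=0)
    rg_x = float(np.sqrt(np.mean((parb.pos[:, 0] - com[0]) ** 2)))
    offset = spec.parb_start_offset if spec.parb_start_offset is not None else rg_x
    parb_pos = parb.pos - com + np.array([-offset, 0.0, 0.0])

    pos = np.vstack([apos, parb_pos])
    pol = np.vstack([apol, parb.pol])
    species = np.concatenate([np.zeros(na, np.int8), parb.species])
    nucleotide = np.concatenate([np.zeros(na, np.int8),
                                 np.full(nb, st.NA, np.int8)])
    alpha = np.concatenate([np.full(na, spec.alpha_parA), parb.alpha])
    anchored = np.concatenate([aanch, np.zeros(nb, bool)])
    oriented = ff.binding_form.value == "oriented"
    has_pol = np.concatenate([np.ones(na, bool), np.full(nb, oriented)])
    chains = [list(c) for c in achains] + [[i + na for i in parb.chains[0]]]
    chain_is_parA = [True] * len(achains) + [False]

    sys_ = st.SystemState(
        pos=pos, pol=pol, species=species, nucleotide=nucleotide,
        alpha=alpha, anchored=anchored,
        polymerized=np.ones(na + nb, bool), has_pol=has_pol,
        chains=chains, chain_is_parA=chain_is_parA, crosslinks=xlinks)
    parb_chain = chains[-1]
    sys_.ext_force_ids = np.array([parb_chain[0], parb_chain[-1]], dtype=np.int64)
    tip_only = config.chemistry.binding_mode == "tip_only"
    sys_.rebuild_topology(ff, tip_only_binding=tip_only)

    if spec.prebind_steps > 0:
        chem_off = ChemistryParams(
            k_h=0.0, k_d=0.0, eps_threshold=1.0,
            binding_mode=BindingMode("tip_only" if tip_only else "side"))
        sim = Simulation(sys_, ff, chem_off,
                         _relax_integrator(integ, rng), config=config)
        sim.run(spec.prebind_steps, sample_stride=0)
    return sys_


def _relax_integrator(integ, rng):
    from .dynamics import IntegratorParams

    return IntegratorParams(dt=min(integ.dt, 1e-3), kT=integ.kT,
                            gamma0=integ.gamma0, gamma_rot=integ.gamma_rot,
                            seed=int(rng.integers(2 ** 31)))


# ---------------------------------------------------------------------------
# scenario catalog
# ---------------------------------------------------------------------------

def _std() -> dict:
    return {
        "geometry": {},
        "forcefield": {},
        "chemistry": {},
        "integrator": {"dt": 1e-3, "n_steps": 2_000_000},
        "output": {},
    }


SCENARIOS: dict = {
    # side-binding with tip-only disassembly
    "standard": {},
    # ParB binds only filament tips; binding sites point out of the tip
    "tip_binding": {
        "chemistry": {"binding_mode": "tip_only"},
        "forcefield": {"binding_form": "tip_no_parb_polar", "theta0_deg": 180.0,
                       "k_helix_nn": 0.0, "k_helix_nnn": 0.0,
                       # a tip presents one axial interface: narrow selectivity
                       "ang_widths": (0.3, 0.6, 0.6)},
    },
    # side binding, but hydrolyzed interior subunits cut their filament
    "severing": {"chemistry": {"disassembly_mode": "severing"}},
    # binding energy near the detachment threshold
    "weak_binding": {"forcefield": {"eps_b": 2.0}},
    # disassembly fast enough to outrun polymer relaxation
    "fast_disassembly": {"chemistry": {"k_d": 0.1}},
    # baseline for sweeping the inert-segment (total ParB) drag
    "drag_sweep": {},
    # longer ParB polymer at fixed binding-strip size
    "length_sweep": {"geometry": {"parb_total_length": 150}},
    # bundle localized but not anchored at the pole
    "unanchored": {"geometry": {"anchored": False}},
    # filaments arranged cylindrically
    "tube": {"geometry": {"arrangement": "tube"}},
    # 4x the standard filament spacing; some filaments survive crossing
    "sparse_bundle": {"geometry": {"spacing": 8.0}},
    # constant opposing force on both ParB ends
    "force_velocity": {"geometry": {"external_force": 2.0}},
    # baseline for sweeping the binding-strip length
    "binding_strip_sweep": {},
    # semiflexible ParB polymer
    "stiff_parb": {"forcefield": {"k_bend_parB": 10.0}},
    # fewer filaments at wider spacing (similar bundle diameter)
    "density_sweep": {"geometry": {"n_filaments": 3, "spacing": 4.0}},
}


def scenario(name: str, **overrides) -> RunConfig:
    """A complete validated run configuration for a named preset.

    ``overrides`` maps section names to dicts of field overrides applied on
    top of the preset, e.g. ``scenario("standard", chemistry={"k_d": 0.01})``.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; valid names: "
                       f"{sorted(SCENARIOS)}")
    base = _std()
    for section, fields in SCENARIOS[name].items():
        base[section].update(fields)
    for section, fields in overrides.items():
        if section not in base:
            raise KeyError(f"unknown config section {section!r}")
        base[section].update(fields)
    cfg = RunConfig.model_validate(base)
    cfg.scenario_name = name
    return cfg
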
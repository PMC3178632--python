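"""Stochastic biochemistry: ParB-stimulated hydrolysis and ParA disassembly.

The cycle per ParA subunit is: bind ParB (binding energy magnitude at or
above ``eps_threshold``) -> hydrolyze ATP -> ADP at rate ``k_h`` -> leave the
filament.  In the standard model a hydrolyzed subunit can only depolymerize
from a free filament tip, at rate ``k_d``; the severing variant additionally
lets any *interior* hydrolyzed subunit cut its filament.

Per step, each eligible subunit converts with probability
``1 - exp(-k dt)`` (Bernoulli discretization of a Poisson process; valid for
``k dt << 1``, which the parameter invariants require).

Conventions (documented so the topology oracles are exact):

* a depolymerized subunit becomes a free monomer that keeps only excluded
  volume -- it cannot re-bind ParB and never repolymerizes;
* a sever event frees the hydrolyzed subunit itself as a monomer and splits
  the remaining run into two chains; the tip-side fragment loses its
  crosslinks to the rest of the bundle (it is released), remains polymerized,
  and can still bind ParB;
* anchored terminal subunits never depolymerize.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import state as st

__all__ = [
    "BindingMode", "DisassemblyMode", "ChemistryParams", "TopologyEvent",
    "eligible_binders", "hydrolysis_step", "depolymerization_step",
    "severing_step", "apply_depolymerization", "apply_sever", "audit_topology",
]


class BindingMode(enum.Enum):
    SIDE = "side"
    TIP_ONLY = "tip_only"


class DisassemblyMode(enum.Enum):
    TIP_ONLY = "tip_only"
    SEVERING = "severing"


@dataclass
class ChemistryParams:
    k_h: float = 20.0            # hydrolysis rate per bound ATP subunit, 1/tau0
    k_d: float = 2e-3            # depolymerization/severing rate, 1/tau0
    eps_threshold: float = 5.0   # kT; |U_bind| licensing hydrolysis
    binding_mode: BindingMode = BindingMode.SIDE
    disassembly_mode: DisassemblyMode = DisassemblyMode.TIP_ONLY
    remove_monomer_distance: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.binding_mode, str):
            self.binding_mode = BindingMode(self.binding_mode)
        if isinstance(self.disassembly_mode, str):
            self.disassembly_mode = DisassemblyMode(self.disassembly_mode)
        if self.k_h < 0 or self.k_d < 0:
            raise ValueError("rates must be >= 0")
        if self.eps_threshold <= 0:
            raise ValueError("eps_threshold must be positive")

    def validate_dt(self, dt: float) -> None:
        if max(self.k_h, self.k_d) * dt > 0.1:
            raise ValueError("k_h dt and k_d dt must be << 1 for the Bernoulli "
                             "chemistry discretization")


@dataclass
class TopologyEvent:
    time: float
    kind: str        # "HYDROLYSIS" | "DEPOLYMERIZATION" | "SEVER"
    subunit_id: int
    filament_id: int


def _bernoulli_p(k: float, dt: float) -> float:
    return min(1.0, 1.0 - np.exp(-k * dt)) if k * dt < 700 else 1.0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def eligible_binders(state: st.SystemState, params: ChemistryParams) -> set:
    """ParA subunit ids that ParB may currently bind.

    SIDE: every polymerized ParA subunit; TIP_ONLY: only free-tip subunits.
    Depolymerized monomers are never eligible.
    """
    ids = np.flatnonzero((state.species == st.PARA) & state.polymerized & state.active)
    if params.binding_mode is BindingMode.TIP_ONLY:
        ids = ids[state.is_tip[ids]]
    return set(int(i) for i in ids)


def hydrolysis_step(state: st.SystemState, pair_binding_energies: dict,
                    params: ChemistryParams, dt: float,
                    rng: np.random.Generator) -> list[TopologyEvent]:
    """Convert bound ATP subunits to ADP with probability 1 - exp(-k_h dt).

    ``pair_binding_energies`` maps ``(parA_id, parB_id) -> U`` (U <= 0); a
    subunit is "bound" if its strongest |U| is at or above ``eps_threshold``.
    ADP is permanent.
    """
    strongest: dict[int, float] = {}
    for (ia, _ib), u in pair_binding_energies.items():
        au = abs(u)
        if au > strongest.get(ia, 0.0):
            strongest[ia] = au
    p = _bernoulli_p(params.k_h, dt)
    events = []
    for ia, au in sorted(strongest.items()):
        if au < params.eps_threshold:
            continue
        if state.nucleotide[ia] != st.ATP or not state.polymerized[ia]:
            continue
        if rng.random() < p:
            state.nucleotide[ia] = st.ADP
            events.append(TopologyEvent(0.0, "HYDROLYSIS", int(ia),
                                        int(state.chain_id[ia])))
    return events


def depolymerization_step(state: st.SystemState, params: ChemistryParams,
                          dt: float, rng: np.random.Generator) -> list[TopologyEvent]:
    """Detach hydrolyzed free-tip subunits with probability 1 - exp(-k_d dt)."""
    p = _bernoulli_p(params.k_d, dt)
    cand = np.flatnonzero(state.is_tip & (state.nucleotide == st.ADP)
                          & state.polymerized & ~state.anchored)
    events = []
    for i in cand:
        if rng.random() < p:
            events.append(TopologyEvent(0.0, "DEPOLYMERIZATION", int(i),
                                        int(state.chain_id[i])))
    for ev in events:
        apply_depolymerization(state, ev.subunit_id)
    return events


def severing_step(state: st.SystemState, params: ChemistryParams,
                  dt: float, rng: np.random.Generator) -> list[TopologyEvent]:
    """Sever filaments at interior hydrolyzed subunits (severing variant)."""
    if params.disassembly_mode is not DisassemblyMode.SEVERING:
        raise ValueError("severing_step requires disassembly_mode = SEVERING")
    p = _bernoulli_p(params.k_d, dt)
    cand = np.flatnonzero((state.species == st.PARA) & state.polymerized
                          & (state.nucleotide == st.ADP) & ~state.is_tip
                          & ~state.anchored)
    events = []
    for i in cand:
        if rng.random() < p:
            events.append(TopologyEvent(0.0, "SEVER", int(i),
                                        int(state.chain_id[i])))
    for ev in events:
        if state.polymerized[ev.subunit_id]:
            apply_sever(state, ev.subunit_id)
    return events


# ---------------------------------------------------------------------------
# topology mutations
# ---------------------------------------------------------------------------

def _release_monomer(state: st.SystemState, i: int) -> None:
    state.polymerized[i] = False
    if len(state.crosslinks):
        keep = (state.crosslinks[:, 0] != i) & (state.crosslinks[:, 1] != i)
        state.crosslinks = state.crosslinks[keep]


def apply_depolymerization(state: st.SystemState, i: int) -> None:
    """Remove subunit ``i`` from the tip of its chain."""
    cid = int(state.chain_id[i])
    chain = state.chains[cid]
    if chain[0] != i and chain[-1] != i:
        raise RuntimeError(f"subunit {i} is not a tip of chain {cid}: "
                           "tip-only depolymerization contract violated")
    if state.anchored[i]:
        raise RuntimeError(f"anchored subunit {i} cannot depolymerize")
    chain.remove(i)
    _release_monomer(state, i)
    if len(chain) == 1 and not state.anchored[chain[0]]:
        _release_monomer(state, chain[0])
        chain.clear()
    if not chain:
        del state.chains[cid]
        del state.chain_is_parA[cid]
        del state.chain_is_fragment[cid]


def apply_sever(state: st.SystemState, i: int) -> None:
    """Cut a chain at interior subunit ``i``.

    ``i`` becomes a free monomer; the tip-side piece becomes a separate,
    unanchored chain released from the bundle (its crosslinks are dropped);
    the anchor-side piece keeps the chain slot.
    """
    cid = int(state.chain_id[i])
    chain = state.chains[cid]
    idx = chain.index(i)
    if idx == 0 or idx == len(chain) - 1:
        raise RuntimeError(f"subunit {i} is a tip; severing applies to interior "
                           "subunits only")
    tip_side = chain[:idx]
    anchor_side = chain[idx + 1:]
    _release_monomer(state, i)
    # release the tip-side fragment from the bundle
    if len(state.crosslinks):
        frag = set(tip_side)
        keep = np.array([(a not in frag) and (b not in frag)
                         for a, b in state.crosslinks], dtype=bool)
        state.crosslinks = state.crosslinks[keep]
    state.chains[cid] = anchor_side
    if len(anchor_side) == 1 and not state.anchored[anchor_side[0]]:
        _release_monomer(state, anchor_side[0])
        state.chains[cid] = []
    if len(tip_side) >= 2:
        state.chains.append(tip_side)
        state.chain_is_parA.append(True)
        state.chain_is_fragment.append(True)
    elif len(tip_side) == 1:
        _release_monomer(state, tip_side[0])
    if not state.chains[cid]:
        del state.chains[cid]
        del state.chain_is_parA[cid]
        del state.chain_is_fragment[cid]


def cull_monomers(state: st.SystemState, distance: float) -> int:
    """Deactivate monomers farther than ``distance`` from every polymer.

    Speed knob, OFF by default; culled subunits are excluded from the
    conservation audit (callers log the count).
    """
    mono = np.flatnonzero((state.species == st.PARA) & ~state.polymerized
                          & state.active)
    if not len(mono):
        return 0
    poly = np.flatnonzero(state.polymerized | (state.species != st.PARA))
    n_culled = 0
    for i in mono:
        d = np.min(np.linalg.norm(state.pos[poly] - state.pos[i], axis=1))
        if d > distance:
            state.active[i] = False
            n_culled += 1
    return n_culled


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------

@dataclass
class AuditResult:
    ok: bool
    diagnostics: list

    def __bool__(self) -> bool:
        return self.ok


def audit_topology(state: st.SystemState, expect_anchored: bool | None = None,
                   culling_enabled: bool = False) -> AuditResult:
    """Structural invariants: conservation, live references, anchoring, ATP.

    Checks that the total subunit count is conserved since t = 0 (unless
    culling is enabled), that bonds and crosslinks reference polymerized
    subunits, that every ParA chain has exactly one anchored end when built
    anchored, and that no ATP subunit is detached.
    """
    diags = []
    if not culling_enabled and state.n != state.n_initial:
        diags.append(f"subunit count changed: {state.n} != {state.n_initial}")
    if not culling_enabled and not state.active.all():
        diags.append("inactive subunits present without culling enabled")
    in_chain = np.zeros(state.n, dtype=bool)
    seen = set()
    for chain, is_a in zip(state.chains, state.chain_is_parA):
        if not chain:
            diags.append("empty chain present")
            continue
        for sid in chain:
            if sid in seen:
                diags.append(f"subunit {sid} appears in more than one chain")
            seen.add(sid)
            in_chain[sid] = True
            if not state.polymerized[sid]:
                diags.append(f"chain references depolymerized subunit {sid}")
        if is_a and expect_anchored is True:
            n_anch = int(state.anchored[chain].sum()) if len(chain) else 0
            if n_anch != 1 or not state.anchored[chain[-1]]:
                diags.append(f"ParA chain without exactly one anchored end: {chain[:3]}...")
    if (state.polymerized & ~in_chain).any():
        bad = np.flatnonzero(state.polymerized & ~in_chain)
        diags.append(f"polymerized subunits outside any chain: {bad[:5]}")
    for a, b in state.crosslinks:
        if not (state.polymerized[a] and state.polymerized[b]):
            diags.append(f"crosslink ({a},{b}) references a depolymerized subunit")
    detached_atp = (state.species == st.PARA) & ~state.polymerized \
        & (state.nucleotide == st.ATP)
    if detached_atp.any():
        diags.append(f"detached ATP subunits: {np.flatnonzero(detached_atp)[:5]}")
    return AuditResult(not diags, diags)
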
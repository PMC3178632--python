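"""System state: positions, orientations, species, and chain topology.

A :class:`SystemState` holds flat numpy arrays for every subunit that has ever
existed in the run (depolymerized monomers keep their rows with
``polymerized = False``) together with the chain structure, from which the
interaction topology arrays consumed by the force kernels are derived.

Conventions
-----------
* translocation axis = +x; each ParA filament's +x terminal subunit is the
  anchored ("swarmer pole") end, the -x terminal subunit the free,
  disassembling tip; chains are stored tip -> anchor.
* species codes: 0 = PARA, 1 = PARB_BIND, 2 = PARB_INERT.
* nucleotide codes: 0 = ATP, 1 = ADP, 2 = NA (non-ParA subunits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PARA = 0
PARB_BIND = 1
PARB_INERT = 2

ATP = 0
ADP = 1
NA = 2

SPECIES_NAMES = {PARA: "PARA", PARB_BIND: "PARB_BIND", PARB_INERT: "PARB_INERT"}
SPECIES_CODES = {v: k for k, v in SPECIES_NAMES.items()}
NUC_NAMES = {ATP: "ATP", ADP: "ADP", NA: "NA"}
NUC_CODES = {v: k for k, v in NUC_NAMES.items()}


@dataclass
class Subunit:
    """Read-only view of a single subunit (convenience for tests/inspection)."""

    id: int
    species: str
    position: np.ndarray
    polarization: np.ndarray | None
    nucleotide: str
    drag_factor: float
    anchored: bool
    chain_id: int
    chain_index: int


@dataclass
class SystemState:
    pos: np.ndarray                 # (N, 3) float
    pol: np.ndarray                 # (N, 3) float, unit vectors where has_pol
    species: np.ndarray             # (N,) int8
    nucleotide: np.ndarray          # (N,) int8
    alpha: np.ndarray               # (N,) float drag factors
    anchored: np.ndarray            # (N,) bool
    polymerized: np.ndarray         # (N,) bool
    has_pol: np.ndarray             # (N,) bool
    chains: list                    # list[list[int]]  (ParA: tip -> anchor)
    chain_is_parA: list             # list[bool]
    chain_is_fragment: list = None  # list[bool]; severing-created fragments
    crosslinks: np.ndarray = None   # (C, 2) int32
    active: np.ndarray = None       # (N,) bool; False only for culled monomers
    n_initial: int = 0
    # derived topology (filled by rebuild_topology)
    bonds: np.ndarray = None
    angles: np.ndarray = None
    angle_k: np.ndarray = None
    align_pairs: np.ndarray = None
    align_c0: np.ndarray = None
    helix_pairs: np.ndarray = None
    helix_k: np.ndarray = None
    helix_c0: np.ndarray = None
    bind_eligible: np.ndarray = None
    is_tip: np.ndarray = None
    in_bundle: np.ndarray = None    # polymerized member of an original chain
    chain_id: np.ndarray = None
    chain_index: np.ndarray = None
    ext_force_ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def __post_init__(self) -> None:
        self.pos = np.ascontiguousarray(self.pos, dtype=np.float64)
        self.pol = np.ascontiguousarray(self.pol, dtype=np.float64)
        if self.active is None:
            self.active = np.ones(self.n, dtype=bool)
        if self.n_initial == 0:
            self.n_initial = self.n
        if self.chain_is_fragment is None:
            self.chain_is_fragment = [False] * len(self.chains)
        if self.crosslinks is None or len(self.crosslinks) == 0:
            self.crosslinks = np.empty((0, 2), dtype=np.int32)
        self.crosslinks = np.asarray(self.crosslinks, dtype=np.int32).reshape(-1, 2)

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def subunit(self, i: int) -> Subunit:
        return Subunit(
            id=i,
            species=SPECIES_NAMES[int(self.species[i])],
            position=self.pos[i].copy(),
            polarization=self.pol[i].copy() if self.has_pol[i] else None,
            nucleotide=NUC_NAMES[int(self.nucleotide[i])],
            drag_factor=float(self.alpha[i]),
            anchored=bool(self.anchored[i]),
            chain_id=int(self.chain_id[i]),
            chain_index=int(self.chain_index[i]),
        )

    # ------------------------------------------------------------------
    # topology derivation
    # ------------------------------------------------------------------
    def rebuild_topology(self, ff, tip_only_binding: bool = False) -> None:
        """Recompute bond/angle/alignment/helix arrays and eligibility masks.

        Must be called after construction and after every chemistry event
        that changes the chain structure.
        """
        n = self.n
        bonds, angles, angle_k = [], [], []
        align_pairs, align_c0 = [], []
        helix_pairs, helix_k, helix_c0 = [], [], []
        chain_id = np.full(n, -1, dtype=np.int32)
        chain_index = np.full(n, -1, dtype=np.int32)
        is_tip = np.zeros(n, dtype=bool)
        in_bundle = np.zeros(n, dtype=bool)

        from .forcefield import BindingForm

        oriented = ff.binding_form is BindingForm.ORIENTED
        c0_align = float(np.cos(np.deg2rad(ff.theta0_deg)))

        for cid, (chain, is_a) in enumerate(zip(self.chains, self.chain_is_parA)):
            frag = self.chain_is_fragment[cid]
            for idx, sid in enumerate(chain):
                chain_id[sid] = cid
                chain_index[sid] = idx
                if is_a and not frag:
                    in_bundle[sid] = True
            for u, v in zip(chain[:-1], chain[1:]):
                bonds.append((u, v))
            kb = ff.k_bend_parA if is_a else ff.k_bend_parB
            if kb > 0:
                for u, v, w in zip(chain[:-2], chain[1:-1], chain[2:]):
                    angles.append((u, v, w))
                    angle_k.append(kb)
            pol_chain = is_a or oriented
            if pol_chain and ff.k_align > 0:
                for idx, sid in enumerate(chain):
                    if idx > 0:
                        align_pairs.append((sid, chain[idx - 1]))
                        align_c0.append(c0_align)
                    if idx < len(chain) - 1:
                        align_pairs.append((sid, chain[idx + 1]))
                        align_c0.append(c0_align)
            if pol_chain:
                psi_nn = ff.psi_nn_parA_deg if is_a else ff.psi_nn_parB_deg
                psi_nnn = ff.psi_nnn_parA_deg if is_a else ff.psi_nnn_parB_deg
                if ff.k_helix_nn > 0:
                    for u, v in zip(chain[:-1], chain[1:]):
                        helix_pairs.append((u, v))
                        helix_k.append(ff.k_helix_nn)
                        helix_c0.append(float(np.cos(np.deg2rad(psi_nn))))
                if ff.k_helix_nnn > 0:
                    for u, v in zip(chain[:-2], chain[2:]):
                        helix_pairs.append((u, v))
                        helix_k.append(ff.k_helix_nnn)
                        helix_c0.append(float(np.cos(np.deg2rad(psi_nnn))))
            if is_a and len(chain) >= 1:
                # free tips: any non-anchored terminal subunit
                if not self.anchored[chain[0]]:
                    is_tip[chain[0]] = True
                if len(chain) > 1 and not self.anchored[chain[-1]]:
                    is_tip[chain[-1]] = True

        self.bonds = np.asarray(bonds, dtype=np.int32).reshape(-1, 2)
        self.angles = np.asarray(angles, dtype=np.int32).reshape(-1, 3)
        self.angle_k = np.asarray(angle_k, dtype=np.float64)
        self.align_pairs = np.asarray(align_pairs, dtype=np.int32).reshape(-1, 2)
        self.align_c0 = np.asarray(align_c0, dtype=np.float64)
        self.helix_pairs = np.asarray(helix_pairs, dtype=np.int32).reshape(-1, 2)
        self.helix_k = np.asarray(helix_k, dtype=np.float64)
        self.helix_c0 = np.asarray(helix_c0, dtype=np.float64)
        self.chain_id = chain_id
        self.chain_index = chain_index
        self.is_tip = is_tip
        self.in_bundle = in_bundle

        elig = (self.species == PARA) & self.polymerized & self.active
        if tip_only_binding:
            elig &= is_tip
        self.bind_eligible = elig

        # prune crosslinks that reference depolymerized subunits
        if len(self.crosslinks):
            keep = self.polymerized[self.crosslinks[:, 0]] & self.polymerized[self.crosslinks[:, 1]]
            self.crosslinks = self.crosslinks[keep]

    def copy(self) -> "SystemState":
        new = SystemState(
            pos=self.pos.copy(), pol=self.pol.copy(),
            species=self.species.copy(), nucleotide=self.nucleotide.copy(),
            alpha=self.alpha.copy(), anchored=self.anchored.copy(),
            polymerized=self.polymerized.copy(), has_pol=self.has_pol.copy(),
            chains=[list(c) for c in self.chains],
            chain_is_parA=list(self.chain_is_parA),
            chain_is_fragment=list(self.chain_is_fragment),
            crosslinks=self.crosslinks.copy(), active=self.active.copy(),
            n_initial=self.n_initial,
        )
        new.ext_force_ids = self.ext_force_ids.copy()
        return new

    def state_hash(self) -> str:
        """Deterministic hash of the full mechanical state (for provenance)."""
        import hashlib

        h = hashlib.sha256()
        for arr in (self.pos, self.pol, self.species, self.nucleotide,
                    self.alpha, self.anchored.astype(np.uint8),
                    self.polymerized.astype(np.uint8), self.crosslinks):
            h.update(np.ascontiguousarray(arr).tobytes())
        for chain in self.chains:
            h.update(np.asarray(chain, dtype=np.int64).tobytes())
        return h.hexdigest()
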
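"""Simulation unit system.

All computations use reduced units:

* length   — the subunit diameter ``a``
* energy   — the thermal energy ``kT``
* drag     — the translational friction ``gamma0 = kT / D0`` of a reference
  subunit (``alpha = 1``), so the reference diffusion coefficient is ``D0 = 1``
* time     — the diffusive time ``tau0 = a**2 / D0``

The constants below are a documentation-level conversion table to physical
units for reporting; they are never used in any computation.  ``A_NM`` is a
plausible ParA subunit diameter and ``D0_UM2_PER_S`` a cytoplasmic protein
diffusion coefficient of the order measured for GFP in bacteria.
"""

#: nominal subunit diameter in nanometres (reporting only)
A_NM = 5.0

#: nominal reference diffusion coefficient in um^2/s (reporting only)
D0_UM2_PER_S = 1.0

#: nominal tau0 in seconds implied by the two constants above (reporting only)
TAU0_S = (A_NM * 1e-3) ** 2 / D0_UM2_PER_S


def tau0_seconds(a_nm: float = A_NM, d0_um2_s: float = D0_UM2_PER_S) -> float:
    """Convert the reduced time unit to seconds for a given physical scale."""
    return (a_nm * 1e-3) ** 2 / d0_um2_s
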
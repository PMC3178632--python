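"""Closed-form companion theory of depolymerization-driven translocation.

The simulation's behaviour is organised by two quantities:

* the stretching relaxation time ``tau`` of a peripheral (non-binding) ParB
  segment — the ratio of its internal drag ``n_segment * gamma`` to the
  entropic spring constant ``kT / Rg_x**2``;
* the maximum per-filament disassembly rate ``k_max``, which grows linearly
  with the hydrolysis rate ``k_h`` at small ``k_h`` and saturates at the
  depolymerization rate ``k_d``, implemented as the serial-rate form

      k_max = [ 1/k_d + 1/(k_h * (delta_max / lam)) ]^(-1)

  with ``lam`` a fit length scale (default: one subunit diameter).

Their product ``k_max * tau`` selects the translocation regime:
I (``<<1``): the polymer keeps its coil shape and moves at ``v = a * k_max``;
II (order 1): the polymer stretches and v drops below ``a * k_max``;
III (``>>1``): the polymer elongates until it detaches (v = 0).

Detachment under load is modelled as Kramers escape of the polymer's center
of mass from the effective potential

    U_eff(x) = -eps_b * N_B * Phi(-x / Rg_x) - F * x

(bundle occupying the half-line x <= 0; Phi the standard normal CDF, i.e.
the Gaussian-weighted fraction of the ParB cloud overlapping the bundle; F
the applied force, which pulls toward +x and opposes binding).  The
detachment force is the F for which the escape time equals the time needed
to translocate across the cell.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TheoryInputs", "TheoryResult", "Regime", "KramersResult",
    "relaxation_time", "max_disassembly_rate", "velocity_regime",
    "effective_potential", "kramers_escape_time", "detachment_force",
    "unanchored_ratio", "evaluate",
]


class Regime(enum.Enum):
    I = "I"
    II = "II"
    III = "III"


@dataclass
class TheoryInputs:
    """Inputs in reduced units (lengths in a, energies in kT, times in tau0)."""

    n_segment: int = 25           # peripheral-segment length, subunits
    gamma_per_subunit: float = 5.0
    kT: float = 1.0
    Rg_x: float = 2.0             # equilibrium x radius of gyration of segment
    a: float = 1.0
    k_h: float = 20.0
    k_d: float = 2e-3
    delta_max: float = 2.0        # saturated penetration depth
    lam: float = 1.0              # fit length scale in k_max
    N_B: int = 50                 # binding-strip size
    eps_b: float = 10.0
    t_trans: float = 1e4          # required crossing time
    gamma_A: float = 280.0        # whole-body drags (unanchored force balance)
    gamma_B: float = 300.0
    tau_prefactor: float = 1.0
    regime_low: float = 0.1       # k_max*tau thresholds for the regime labels
    regime_high: float = 10.0

    def __post_init__(self) -> None:
        for name in ("gamma_per_subunit", "kT", "Rg_x", "a", "N_B", "eps_b",
                     "n_segment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def d_segment(self) -> float:
        """Diffusion coefficient of the whole peripheral segment."""
        return self.kT / (self.n_segment * self.gamma_per_subunit)


@dataclass
class TheoryResult:
    tau: float
    k_max: float
    kD_tau: float
    regime: str
    v_pred: float
    v_is_upper_bound: bool
    detached: bool
    t_esc: float | None = None
    F_detach: float | None = None
    v_ratio_unanchored: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tau", "k_max", "kD_tau", "regime", "v_pred",
                 "v_is_upper_bound", "detached", "t_esc", "F_detach",
                 "v_ratio_unanchored")}


# ---------------------------------------------------------------------------

def relaxation_time(inputs: TheoryInputs) -> float:
    """tau = internal drag / entropic spring constant = n gamma Rg_x^2 / kT."""
    return (inputs.tau_prefactor * inputs.n_segment * inputs.gamma_per_subunit
            * inputs.Rg_x ** 2 / inputs.kT)


def max_disassembly_rate(inputs: TheoryInputs) -> float:
    """Serial-rate k_max: linear in k_h at small k_h, saturating at k_d."""
    if inputs.k_h == 0.0 or inputs.k_d == 0.0:
        return 0.0
    return 1.0 / (1.0 / inputs.k_d + inputs.lam / (inputs.k_h * inputs.delta_max))


def velocity_regime(inputs: TheoryInputs):
    """Regime label and predicted velocity for the given parameter set."""
    tau = relaxation_time(inputs)
    k_max = max_disassembly_rate(inputs)
    x = k_max * tau
    if x < inputs.regime_low:
        return Regime.I, inputs.a * k_max
    if x > inputs.regime_high:
        return Regime.III, 0.0
    return Regime.II, inputs.a * k_max   # upper bound in regime II


def effective_potential(x_com, F: float, inputs: TheoryInputs):
    """U_eff(x) = -eps_b N_B Phi(-x/Rg_x) - F x  (kT units)."""
    x = np.asarray(x_com, dtype=float)
    u = -inputs.eps_b * inputs.N_B * stats.norm.cdf(-x / inputs.Rg_x) - F * x
    return u if u.ndim else float(u)


@dataclass
class KramersResult:
    t_esc: float
    barrier: float
    x_well: float
    x_barrier: float
    no_barrier: bool
    low_barrier_warning: bool


def kramers_escape_time(u_func, drag: float, kT: float,
                        x_range: tuple = (-40.0, 40.0)) -> KramersResult:
    """Overdamped Kramers escape time from the well of ``u_func``.

    Standard two-curvature form ``t = 2 pi drag / sqrt(k_well * |k_barr|) *
    exp(dU / kT)``.  When the applied force has erased the barrier the
    result falls back to the drift time across the scan range and is
    flagged.
    """
    xs = np.linspace(*x_range, 4001)
    us = np.array([u_func(x) for x in xs])
    # well: leftmost interior local minimum (the bound state); barrier: the
    # highest point beyond it in the escape direction (+x).  The global
    # minimum is not usable: under strong force the tilted potential dips
    # below the well far downhill.
    interior = np.flatnonzero((us[1:-1] <= us[:-2]) & (us[1:-1] <= us[2:])) + 1
    if len(interior) == 0:
        iw = int(np.argmin(us))
        ib = iw
        barrier = 0.0
        no_barrier = True
    else:
        iw = int(interior[0])
        ib = iw + int(np.argmax(us[iw:]))
        barrier = float(us[ib] - us[iw])
        no_barrier = ib <= iw + 1 or barrier <= 1e-9
    if no_barrier:
        # drift-dominated escape: t ~ drag * L / max|slope|
        slope = np.max(np.abs(np.gradient(us, xs)))
        t = drag * (x_range[1] - x_range[0]) / max(slope, 1e-300)
        return KramersResult(float(t), 0.0, float(xs[iw]), float(xs[iw]),
                             True, True)
    h = xs[1] - xs[0]

    def curv(i):
        return (u_func(xs[i] + h) - 2 * u_func(xs[i]) + u_func(xs[i] - h)) / h ** 2

    # refine stationary points
    xw = optimize.minimize_scalar(
        u_func, bounds=(xs[max(iw - 2, 0)], xs[min(iw + 2, len(xs) - 1)]),
        method="bounded").x
    xb = optimize.minimize_scalar(
        lambda x: -u_func(x),
        bounds=(xs[max(ib - 2, 0)], xs[min(ib + 2, len(xs) - 1)]),
        method="bounded").x
    kw = (u_func(xw + h) - 2 * u_func(xw) + u_func(xw - h)) / h ** 2
    kb = (u_func(xb + h) - 2 * u_func(xb) + u_func(xb - h)) / h ** 2
    barrier = float(u_func(xb) - u_func(xw))
    kw = max(kw, 1e-12)
    kb = min(kb, -1e-12)
    t = 2.0 * np.pi * drag / np.sqrt(kw * abs(kb)) * np.exp(barrier / kT)
    return KramersResult(float(t), barrier, float(xw), float(xb), False,
                         barrier < 2.0 * kT)


def detachment_force(inputs: TheoryInputs, t_trans: float | None = None,
                     f_bracket: tuple | None = None) -> float:
    """Force at which the Kramers escape time equals the crossing time.

    Solved by bisection on ``log(t_esc(F)) = log(t_trans)``; raises a
    ``ValueError`` naming the bracket if no root exists there.
    """
    if t_trans is None:
        t_trans = inputs.t_trans
    drag = inputs.N_B * inputs.gamma_per_subunit  # COM drag of the bound strip
    f_erase = inputs.eps_b * inputs.N_B / (inputs.Rg_x * np.sqrt(2.0 * np.pi))

    def log_resid(F):
        res = kramers_escape_time(lambda x: effective_potential(x, F, inputs),
                                  drag, inputs.kT)
        return np.log(res.t_esc) - np.log(t_trans)

    lo, hi = f_bracket if f_bracket else (1e-4 * f_erase, 0.999 * f_erase)
    rlo, rhi = log_resid(lo), log_resid(hi)
    if rlo < 0.0:
        raise ValueError(
            f"no detachment-force root: escape already faster than t_trans at "
            f"F={lo:.3g} (t_esc residual {rlo:.3g}); bracket=({lo:.3g},{hi:.3g})")
    if rhi > 0.0:
        raise ValueError(
            f"no detachment-force root: escape still slower than t_trans at "
            f"F={hi:.3g}; bracket=({lo:.3g},{hi:.3g})")
    return float(optimize.brentq(log_resid, lo, hi, xtol=1e-6 * f_erase))


def unanchored_ratio(gamma_A: float, gamma_B: float) -> float:
    """|v_B| / |v_A| = gamma_A / gamma_B (momentum balance, opposite signs)."""
    if gamma_A <= 0 or gamma_B <= 0:
        raise ValueError("drags must be positive")
    return gamma_A / gamma_B


def evaluate(inputs: TheoryInputs, with_detachment_force: bool = True) -> TheoryResult:
    """Full analytic characterisation of a parameter set."""
    tau = relaxation_time(inputs)
    k_max = max_disassembly_rate(inputs)
    regime, v = velocity_regime(inputs)
    t_esc = None
    f_d = None
    if with_detachment_force:
        drag = inputs.N_B * inputs.gamma_per_subunit
        t_esc = kramers_escape_time(
            lambda x: effective_potential(x, 1e-3 * inputs.eps_b, inputs),
            drag, inputs.kT).t_esc
        try:
            f_d = detachment_force(inputs)
        except ValueError:
            f_d = None
    return TheoryResult(
        tau=tau, k_max=k_max, kD_tau=k_max * tau, regime=regime.value,
        v_pred=v, v_is_upper_bound=(regime is Regime.II),
        detached=(regime is Regime.III), t_esc=t_esc, F_detach=f_d,
        v_ratio_unanchored=unanchored_ratio(inputs.gamma_A, inputs.gamma_B))
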
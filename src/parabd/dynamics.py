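"""Overdamped Langevin (Brownian dynamics) time stepping.

Positions follow the first-order Euler-Maruyama update

    dr_i = F_i dt / (alpha_i gamma0) + xi_i,
    <xi> = 0,  <xi^2> = 2 (kT / (alpha_i gamma0)) dt   per component,

and each polarization vector is rotated by the deterministic angular velocity
``T_i / gamma_rot`` plus rotational white noise of variance
``2 (kT / gamma_rot) dt`` per axis, then renormalized to unit length (the
rotation is applied as a small rotation about axes perpendicular to ``p``, so
the unit constraint is preserved exactly to first order).

:func:`bd_step` is the plain-numpy single-step reference; production runs use
the fused loop in :mod:`parabd.engine`, which implements the identical update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["IntegratorParams", "sample_thermal_kicks", "bd_step"]


@dataclass
class IntegratorParams:
    """Time stepping parameters, in reduced units (see :mod:`parabd.units`)."""

    dt: float = 1e-4          # tau0
    kT: float = 1.0
    gamma0: float = 1.0       # kT / D0
    gamma_rot: float = 1.0 / 3.0   # rotational drag of a sphere of diameter a
    seed: int = 0
    n_steps: int = 100_000
    max_step_displacement: float = 0.1   # stability monitor threshold, in a

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def tau0(self, a: float = 1.0) -> float:
        """Characteristic diffusive time a^2 / D0 = a^2 gamma0 / kT."""
        return a * a * self.gamma0 / self.kT

    def check_stability(self, stiffest_k: float) -> bool:
        """True if dt resolves the fastest harmonic relaxation (dt << gamma/k)."""
        if stiffest_k <= 0:
            return True
        return self.dt < 0.2 * self.gamma0 / stiffest_k


def sample_thermal_kicks(n: int, variance: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. zero-mean Gaussian increments with the requested variance."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0.0:
        return np.zeros(n)
    return rng.normal(0.0, np.sqrt(variance), size=n)


_warned_dt = False


def bd_step(state, forces, torques, params: IntegratorParams,
            rng: np.random.Generator):
    """Advance a system by one Brownian-dynamics step (reference path).

    Mutates ``state.pos`` and ``state.pol`` in place and returns the state.
    Anchored subunits are frozen; inactive (culled) subunits are skipped.
    """
    global _warned_dt
    if np.isnan(forces).any():
        bad = int(np.argwhere(np.isnan(forces))[0][0])
        raise FloatingPointError(f"NaN force on subunit {bad}")
    dt, kT, g0, gr = params.dt, params.kT, params.gamma0, params.gamma_rot
    mobile = (~state.anchored) & state.active
    mob = g0 * state.alpha[mobile]
    det = forces[mobile] * dt / mob[:, None]
    if det.size and np.abs(det).max() > params.max_step_displacement and not _warned_dt:
        warnings.warn("per-step deterministic displacement exceeds the stability "
                      "threshold; decrease dt", RuntimeWarning, stacklevel=2)
        _warned_dt = True
    noise = sample_thermal_kicks(det.size, 1.0, rng).reshape(det.shape)
    noise *= np.sqrt(2.0 * kT * dt / mob)[:, None]
    state.pos[mobile] += det + noise

    rot = mobile & state.has_pol
    if rot.any():
        w = torques[rot] * dt / gr
        w += sample_thermal_kicks(w.size, 2.0 * kT * dt / gr, rng).reshape(w.shape)
        p = state.pol[rot]
        p = p + np.cross(w, p)
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        state.pol[rot] = p
    return state
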
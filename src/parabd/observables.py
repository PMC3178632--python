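"""Measured quantities: velocity, shape, penetration, gradients, detachment.

All estimators operate on the sampled :class:`ObservableSeries` (one row per
sample time) or on stored trajectory frames plus the chemistry event log.

Definitions (artifact conventions, configurable where noted):

* translocation velocity: least-squares slope of the ParB center-of-mass x
  coordinate, with a block-bootstrap standard error;
* penetration depth ``delta = max(0, x_q90(bound ParB) - mean tip x)`` — the
  90th percentile is used instead of the maximum for noise robustness;
* detachment: ``n_bound = 0`` sustained for a dwell time while the ParB
  center of mass stays farther than ``range_b + a`` from every polymerized
  ParA subunit;
* crossing: ParB COM advance by the initial bundle length (the censoring
  horizon for detachment statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ObservableSeries", "ConcentrationProfile", "translocation_velocity",
    "gyration_anisotropy", "penetration_depth", "concentration_profile",
    "detachment_statistics", "first_detachment_time", "crossing_time",
    "force_velocity", "unanchored_speeds", "polymerized_mask_at",
]


@dataclass
class ObservableSeries:
    """Per-run time series on a common sampling grid."""

    times: np.ndarray          # (S,)
    parb_com: np.ndarray       # (S, 3)
    parA_com: np.ndarray       # (S, 3)
    gyration: np.ndarray       # (S, 6): xx yy zz xy xz yz of the ParB polymer
    n_bound: np.ndarray        # (S,) ParB subunits bound to any polymerized ParA
    n_bound_bundle: np.ndarray  # (S,) ... bound to the main (non-fragment) bundle
    tip_x: np.ndarray          # (S,) mean x of the bundle's free-tip subunits
    q90_x: np.ndarray          # (S,) 90th-percentile x of bundle-bound ParB
    min_dist: np.ndarray       # (S,) ParB COM to nearest polymerized ParA
    min_dist_bundle: np.ndarray  # (S,) ... to nearest bundle subunit
    n_polymerized: np.ndarray  # (S,)

    @property
    def attached(self) -> np.ndarray:
        return self.n_bound > 0

    @property
    def attached_bundle(self) -> np.ndarray:
        """Attached to the main bundle (fragments do not count)."""
        return self.n_bound_bundle > 0

    @property
    def delta(self) -> np.ndarray:
        """Penetration depth series (0 where nothing is bound)."""
        d = self.q90_x - self.tip_x
        d = np.where(np.isfinite(d), np.clip(d, 0.0, None), 0.0)
        return np.where(self.attached, d, 0.0)

    def window(self, t0: float | None = None, t1: float | None = None) -> np.ndarray:
        m = np.ones(len(self.times), dtype=bool)
        if t0 is not None:
            m &= self.times >= t0
        if t1 is not None:
            m &= self.times <= t1
        return m

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time": self.times,
            "parb_com_x": self.parb_com[:, 0],
            "parb_com_y": self.parb_com[:, 1],
            "parb_com_z": self.parb_com[:, 2],
            "parA_com_x": self.parA_com[:, 0],
            "rg2_x": self.gyration[:, 0],
            "rg2_y": self.gyration[:, 1],
            "rg2_z": self.gyration[:, 2],
            "n_bound": self.n_bound,
            "n_bound_bundle": self.n_bound_bundle,
            "tip_x": self.tip_x,
            "q90_x": self.q90_x,
            "min_dist": self.min_dist,
            "min_dist_bundle": self.min_dist_bundle,
            "n_polymerized": self.n_polymerized,
            "delta": self.delta,
            "attached": self.attached,
        })
        return df


@dataclass
class ConcentrationProfile:
    """Mean polymerized-ParA density vs x relative to the ParB COM."""

    bin_centers: np.ndarray
    mean_density: np.ndarray    # subunits per unit length
    window: tuple

    @property
    def total_count(self) -> float:
        if len(self.bin_centers) < 2:
            return 0.0
        width = self.bin_centers[1] - self.bin_centers[0]
        return float(self.mean_density.sum() * width)


# ---------------------------------------------------------------------------
# velocity and shape
# ---------------------------------------------------------------------------

def translocation_velocity(series: ObservableSeries,
                           window: tuple | None = None,
                           n_boot: int = 200, n_blocks: int = 10,
                           rng: np.random.Generator | None = None):
    """COM x velocity: least-squares slope with block-bootstrap error."""
    m = series.window(*window) if window else np.ones(len(series.times), bool)
    t = series.times[m]
    x = series.parb_com[m, 0]
    if len(t) < 10:
        raise ValueError("velocity window must contain at least 10 samples")
    v = float(np.polyfit(t, x, 1)[0])
    if rng is None:
        rng = np.random.default_rng(0)
    blocks = np.array_split(np.arange(len(t)), n_blocks)
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([blocks[i] for i in
                              rng.integers(0, n_blocks, n_blocks)])
        slopes[b] = np.polyfit(t[idx], x[idx], 1)[0]
    return v, float(slopes.std())


def gyration_anisotropy(series: ObservableSeries,
                        window: tuple | None = None) -> float:
    """Time-averaged <Rg_x^2> / <Rg_y^2> of the ParB polymer."""
    m = series.window(*window) if window else np.ones(len(series.times), bool)
    if m.sum() < 100:
        raise ValueError("anisotropy requires at least 100 frames")
    return float(series.gyration[m, 0].mean() / series.gyration[m, 1].mean())


def penetration_depth(state, ff, bound_cut: float = 1.0):
    """Instantaneous penetration depth of the ParB polymer into the bundle.

    Returns ``(delta, anything_bound)``; delta is 0 when nothing is bound.
    """
    from .forcefield import total_forces

    _e, _f, _t, table = total_forces(state, ff)
    strongest: dict[int, float] = {}
    for (_ia, ib), u in table.items():
        strongest[ib] = max(strongest.get(ib, 0.0), abs(u))
    bound = [j for j, au in strongest.items() if au >= bound_cut]
    tips = np.flatnonzero(state.is_tip & state.polymerized)
    if not bound or not len(tips):
        return 0.0, False
    q90 = float(np.quantile(state.pos[bound, 0], 0.9))
    return max(0.0, q90 - float(state.pos[tips, 0].mean())), True


# ---------------------------------------------------------------------------
# concentration profile
# ---------------------------------------------------------------------------

def polymerized_mask_at(state0, events, time: float) -> np.ndarray:
    """Which subunits are still polymerized at ``time``, from the event log."""
    mask = state0.polymerized.copy()
    for ev in events:
        if ev.time <= time and ev.kind in ("DEPOLYMERIZATION", "SEVER"):
            mask[ev.subunit_id] = False
    return mask


def concentration_profile(frames, frame_times, state0, events,
                          window: tuple | None = None,
                          bin_width: float = 1.0,
                          x_range: tuple = (-30.0, 30.0)) -> ConcentrationProfile:
    """Histogram of polymerized ParA x positions relative to the ParB COM,
    averaged over the frames in ``window``."""
    parb = state0.species != 0
    parA = state0.species == 0
    t0, t1 = window if window else (frame_times[0], frame_times[-1])
    sel = [k for k, t in enumerate(frame_times) if t0 <= t <= t1]
    if not sel:
        raise ValueError("no frames in window")
    edges = np.arange(x_range[0], x_range[1] + bin_width, bin_width)
    acc = np.zeros(len(edges) - 1)
    for k in sel:
        mask = polymerized_mask_at(state0, events, frame_times[k]) & parA
        com_x = frames[k][parb, 0].mean()
        acc += np.histogram(frames[k][mask, 0] - com_x, bins=edges)[0]
    density = acc / len(sel) / bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ConcentrationProfile(centers, density, (t0, t1))


# ---------------------------------------------------------------------------
# detachment and crossing
# ---------------------------------------------------------------------------

def first_detachment_time(series: ObservableSeries, dwell_time: float,
                          min_dist_threshold: float):
    """First time bundle unbinding is sustained for ``dwell_time``.

    Returns None if the polymer never detaches, and 0.0 if it never attaches
    to the bundle in the first place.  Scanning starts at the first attached
    sample, so the initial approach is not scored as a detachment.
    """
    t = series.times
    unbound = (~series.attached_bundle) & (series.min_dist_bundle
                                           > min_dist_threshold)
    att = np.flatnonzero(series.attached_bundle)
    if not len(att):
        return 0.0
    i = int(att[0])
    while i < len(t):
        if unbound[i]:
            j = i
            while j < len(t) and unbound[j]:
                j += 1
            if (j - 1 > i and t[j - 1] - t[i] >= dwell_time) or \
                    (j == len(t) and t[-1] - t[i] >= dwell_time):
                return float(t[i])
            i = j
        else:
            i += 1
    return None


def detachment_statistics(series_list, dwell_time: float = 1.0,
                          min_dist_threshold: float = 2.5):
    """Mean time to first detachment over replicate runs.

    Censored replicates (no detachment before the run ends) enter at their
    run length; the result reports how many were censored.
    """
    if len(series_list) < 2:
        raise ValueError("detachment statistics require replicate runs")
    times, censored = [], []
    for s in series_list:
        td = first_detachment_time(s, dwell_time, min_dist_threshold)
        if td is None:
            times.append(float(s.times[-1]))
            censored.append(True)
        else:
            times.append(td)
            censored.append(False)
    times = np.asarray(times)
    return {
        "mean": float(times.mean()),
        "se": float(times.std(ddof=1) / np.sqrt(len(times))),
        "times": times,
        "censored": np.asarray(censored),
        "all_censored": all(censored),
    }


def crossing_time(series: ObservableSeries, distance: float):
    """First time the ParB COM has advanced by ``distance`` along +x."""
    dx = series.parb_com[:, 0] - series.parb_com[0, 0]
    idx = np.flatnonzero(dx >= distance)
    return float(series.times[idx[0]]) if len(idx) else None


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def force_velocity(config, force_grid, seed: int = 0,
                   n_steps: int | None = None,
                   dwell_time: float = 1.0) -> pd.DataFrame:
    """Translocation velocity vs opposing external force."""
    from .simulate import run_scenario

    rows = []
    for k, f in enumerate(force_grid):
        cfg = config.model_copy(deep=True)
        cfg.geometry.external_force = float(f)
        res = run_scenario(cfg, n_steps=n_steps, seed=seed + 1000 * k)
        ff = cfg.forcefield_params()
        td = first_detachment_time(res.series, dwell_time,
                                   ff.range_b + ff.subunit_diameter_a)
        att = res.series.attached
        v, se = translocation_velocity(res.series) if att.mean() > 0.5 else (np.nan, np.nan)
        rows.append({"force": float(f), "velocity": v, "velocity_se": se,
                     "detached": td is not None, "t_detach": td})
    return pd.DataFrame(rows)


def unanchored_speeds(frames, frame_times, state0, events,
                      gamma0: float = 1.0, window: tuple | None = None):
    """COM x velocities of ParB and of the surviving polymerized ParA.

    The ParA velocity is measured from per-subunit displacements of subunits
    polymerized in both frames of each consecutive pair, which removes the
    spurious COM drift caused by erosion of the bundle.
    """
    parb = state0.species != 0
    parA = state0.species == 0
    t0, t1 = window if window else (frame_times[0], frame_times[-1])
    sel = [k for k, t in enumerate(frame_times) if t0 <= t <= t1]
    if len(sel) < 3:
        raise ValueError("need at least 3 frames")
    dxa, dxb, dts, drags_a = [], [], [], []
    for k0, k1 in zip(sel[:-1], sel[1:]):
        m0 = polymerized_mask_at(state0, events, frame_times[k0]) & parA
        m1 = polymerized_mask_at(state0, events, frame_times[k1]) & parA
        both = m0 & m1
        if both.sum() == 0:
            continue
        dt = frame_times[k1] - frame_times[k0]
        dxa.append((frames[k1][both, 0] - frames[k0][both, 0]).mean())
        dxb.append(frames[k1][parb, 0].mean() - frames[k0][parb, 0].mean())
        dts.append(dt)
        drags_a.append(gamma0 * state0.alpha[both].sum())
    dxa, dxb, dts = map(np.asarray, (dxa, dxb, dts))
    drags_a = np.asarray(drags_a)
    v_a = float(dxa.sum() / dts.sum())
    v_b = float(dxb.sum() / dts.sum())
    n = len(dts)
    mean_dt = dts.mean()
    se_a = float(np.std(dxa / dts, ddof=1) / np.sqrt(n) * (dts.std() and 1.0 or 1.0))
    se_b = float(np.std(dxb / dts, ddof=1) / np.sqrt(n))
    gamma_b = float(gamma0 * state0.alpha[parb].sum())
    # force-balance residual per increment: gamma_A dx_A + gamma_B dx_B
    resid = (drags_a * dxa + gamma_b * dxb) / dts
    return {
        "v_parb": v_b, "v_parb_se": se_b,
        "v_parA": v_a, "v_parA_se": se_a,
        "gamma_A": float(drags_a.mean()),
        "gamma_B": gamma_b,
        "balance_mean": float(resid.mean()),
        "balance_se": float(resid.std(ddof=1) / np.sqrt(n)),
        "n_increments": n,
    }
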
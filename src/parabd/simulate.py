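"""Simulation driver: chunked kernel execution plus chain bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine
from .chemistry import (BindingMode, ChemistryParams, DisassemblyMode,
                        TopologyEvent, apply_depolymerization, apply_sever,
                        cull_monomers)
from .dynamics import IntegratorParams
from .forcefield import BindingForm, ForceFieldParams
from .observables import ObservableSeries
from .state import SystemState

__all__ = ["Simulation", "RunResult", "run_scenario"]


@dataclass
class RunResult:
    series: ObservableSeries
    events: list
    frames: np.ndarray | None
    frame_times: np.ndarray | None
    final_state: SystemState
    meta: dict = field(default_factory=dict)


class Simulation:
    """Brownian-dynamics run of one system under one parameter set.

    The integrator seed fully determines the trajectory; consecutive
    :meth:`run` calls continue the same run (time, RNG stream and chemistry
    state carry over).
    """

    def __init__(self, system: SystemState, ff: ForceFieldParams,
                 chem: ChemistryParams, integ: IntegratorParams,
                 bound_energy_cut: float = 1.0, config=None):
        chem.validate_dt(integ.dt)
        self.system = system
        self.ff = ff
        self.chem = chem
        self.integ = integ
        self.bound_cut = bound_energy_cut
        self.config = config
        self.step = 0
        self.rot_stride = 4   # polarization update cadence, in steps
        self._seeded = False
        self._pair_cap = max(256, 96 * system.n)
        system.rebuild_topology(ff, tip_only_binding=chem.binding_mode
                                is BindingMode.TIP_ONLY)
        self.n_culled = 0

    # ------------------------------------------------------------------
    def _pf(self) -> np.ndarray:
        ff, chem, integ = self.ff, self.chem, self.integ
        cfg = self.config
        pf = np.zeros(engine.PF_N)
        pf[engine.PF_A] = ff.subunit_diameter_a
        pf[engine.PF_K_EV] = ff.k_ev
        pf[engine.PF_K_BOND] = ff.k_bond
        pf[engine.PF_K_XL] = ff.k_crosslink
        pf[engine.PF_D0] = ff.d0
        pf[engine.PF_K_ALIGN] = ff.k_align
        pf[engine.PF_EPS_B] = ff.eps_b
        pf[engine.PF_R_B] = ff.r_b
        pf[engine.PF_RANGE_B] = ff.range_b
        pf[engine.PF_KAP1], pf[engine.PF_KAP2], pf[engine.PF_KAP3] = ff.ang_widths
        pf[engine.PF_DT] = integ.dt
        pf[engine.PF_KT] = integ.kT
        pf[engine.PF_G0] = integ.gamma0
        pf[engine.PF_GROT] = integ.gamma_rot
        pf[engine.PF_KH] = chem.k_h
        pf[engine.PF_KD] = chem.k_d
        pf[engine.PF_EPSTH] = chem.eps_threshold
        pf[engine.PF_BOUNDCUT] = self.bound_cut
        pf[engine.PF_SKIN] = 1.0 * ff.subunit_diameter_a
        pf[engine.PF_MAXDISP] = integ.max_step_displacement
        ext = 0.0
        if cfg is not None and cfg.geometry.external_force:
            ext = -abs(cfg.geometry.external_force)   # opposes +x translocation
        pf[engine.PF_EXTFX] = ext
        if cfg is not None and cfg.geometry.confinement_radius:
            pf[engine.PF_CONF_R] = cfg.geometry.confinement_radius
            if cfg.geometry.confinement_length:
                half = 0.5 * cfg.geometry.confinement_length
                mid = 0.5 * (self.system.pos[:, 0].min() + self.system.pos[:, 0].max())
                pf[engine.PF_CONF_X0] = mid - half
                pf[engine.PF_CONF_X1] = mid + half
            pf[engine.PF_KWALL] = 50.0
        return pf

    # ------------------------------------------------------------------
    def run(self, n_steps: int, sample_stride: int = 500,
            traj_stride: int = 0) -> RunResult:
        sys_ = self.system
        n = sys_.n
        if not self._seeded:
            engine.seed_rng(int(self.integ.seed) & 0x7FFFFFFF)
            self._noise_rng = np.random.default_rng(
                (int(self.integ.seed) ^ 0x5DEECE66) & 0x7FFFFFFF)
            self._seeded = True
        pf = self._pf()
        sever = 1 if self.chem.disassembly_mode is DisassemblyMode.SEVERING else 0
        oriented = 1 if self.ff.binding_form is BindingForm.ORIENTED else 0
        tip_only = self.chem.binding_mode is BindingMode.TIP_ONLY

        n_samp = (n_steps // sample_stride + 2) if sample_stride > 0 else 1
        n_frames = (n_steps // traj_stride + 2) if traj_stride > 0 else 1
        t_times = np.full(n_samp, np.nan)
        t_comb = np.zeros((n_samp, 3))
        t_coma = np.zeros((n_samp, 3))
        t_gyr = np.zeros((n_samp, 6))
        t_nbound = np.zeros(n_samp, np.int64)
        t_nboundb = np.zeros(n_samp, np.int64)
        t_tipx = np.zeros(n_samp)
        t_q90 = np.zeros(n_samp)
        t_mind = np.zeros(n_samp)
        t_mindb = np.zeros(n_samp)
        t_npoly = np.zeros(n_samp, np.int64)
        hyd_steps = np.zeros(n + 64, np.int64)
        hyd_ids = np.zeros(n + 64, np.int32)
        frames = np.zeros((n_frames, n, 3)) if traj_stride > 0 else np.zeros((1, n, 3))
        frame_steps = np.full(n_frames if traj_stride > 0 else 1, -1, np.int64)
        counters = np.zeros(engine.CT_N, np.int64)
        forces = np.zeros((n, 3))
        pgrad = np.zeros((n, 3))
        maxb = np.zeros(n)
        maxb_bun = np.zeros(n)
        scratch = np.zeros(n)
        ref_pos = np.zeros((n, 3))
        chunk_cap = 4096
        rot_stride = self.rot_stride
        noise = np.empty((chunk_cap, n, 3))
        noise_rot = np.empty((chunk_cap // rot_stride + 2, n, 3))
        mob = self.integ.dt / (sys_.alpha * self.integ.gamma0)
        std_t = np.sqrt(2.0 * self.integ.kT * mob)

        events: list[TopologyEvent] = []
        dt = self.integ.dt
        remaining = n_steps
        while remaining > 0:
            pair_i = np.empty(self._pair_cap, np.int32)
            pair_j = np.empty(self._pair_cap, np.int32)
            bind_i = np.empty(self._pair_cap, np.int32)
            bind_j = np.empty(self._pair_cap, np.int32)
            counters[engine.CT_LIST_VALID] = 0
            csteps = min(remaining, chunk_cap)
            self._noise_rng.standard_normal(out=noise[:csteps].reshape(-1))
            nrot = csteps // rot_stride + 2
            self._noise_rng.standard_normal(out=noise_rot[:nrot].reshape(-1))
            code, done, ev_id, ev_kind = engine.run_chunk(
                sys_.pos, sys_.pol, sys_.species, sys_.nucleotide, sys_.alpha,
                sys_.anchored, sys_.polymerized, sys_.active, sys_.has_pol,
                sys_.bonds, sys_.crosslinks, sys_.angles, sys_.angle_k,
                sys_.align_pairs, sys_.align_c0, sys_.helix_pairs,
                sys_.helix_k, sys_.helix_c0, sys_.bind_eligible, sys_.is_tip,
                sys_.in_bundle, sys_.ext_force_ids, pf, oriented, sever,
                pair_i, pair_j, bind_i, bind_j, ref_pos,
                forces, pgrad, maxb, maxb_bun, scratch, noise, noise_rot,
                mob, std_t,
                rot_stride, csteps, self.step, sample_stride, traj_stride,
                t_times, t_comb, t_coma, t_gyr, t_nbound, t_nboundb, t_tipx,
                t_q90, t_mind, t_mindb, t_npoly, hyd_steps, hyd_ids, frames,
                frame_steps, counters)
            self.step += done
            remaining -= done
            if code == engine.CODE_NAN:
                raise FloatingPointError(
                    f"NaN coordinate on subunit {ev_id} at step {self.step}: "
                    "integration blow-up")
            if code == engine.CODE_OVERFLOW:
                self._pair_cap *= 2
                continue
            if code == engine.CODE_EVENT:
                t = self.step * dt
                if ev_kind == engine.EV_DEPOLYMERIZATION:
                    events.append(TopologyEvent(t, "DEPOLYMERIZATION", int(ev_id),
                                                int(sys_.chain_id[ev_id])))
                    apply_depolymerization(sys_, int(ev_id))
                else:
                    events.append(TopologyEvent(t, "SEVER", int(ev_id),
                                                int(sys_.chain_id[ev_id])))
                    apply_sever(sys_, int(ev_id))
                sys_.rebuild_topology(self.ff, tip_only_binding=tip_only)
                if self.chem.remove_monomer_distance:
                    self.n_culled += cull_monomers(
                        sys_, self.chem.remove_monomer_distance)

        # hydrolysis events from the kernel buffer
        for k in range(counters[engine.CT_NHYD]):
            events.append(TopologyEvent(hyd_steps[k] * dt, "HYDROLYSIS",
                                        int(hyd_ids[k]), -1))
        events.sort(key=lambda e: e.time)

        ns = int(counters[engine.CT_NSAMP])
        series = ObservableSeries(
            times=t_times[:ns], parb_com=t_comb[:ns], parA_com=t_coma[:ns],
            gyration=t_gyr[:ns], n_bound=t_nbound[:ns],
            n_bound_bundle=t_nboundb[:ns], tip_x=t_tipx[:ns],
            q90_x=t_q90[:ns], min_dist=t_mind[:ns],
            min_dist_bundle=t_mindb[:ns], n_polymerized=t_npoly[:ns])
        nf = int(counters[engine.CT_NFRAME])
        meta = {
            "n_rebuilds": int(counters[engine.CT_NREBUILD]),
            "n_displacement_warnings": int(counters[engine.CT_NWARN]),
            "n_culled": self.n_culled,
            "gamma_parb": float(self.integ.gamma0
                                * sys_.alpha[sys_.species != 0].sum()),
            "seed": self.integ.seed,
        }
        return RunResult(
            series=series, events=events,
            frames=frames[:nf].copy() if traj_stride > 0 else None,
            frame_times=frame_steps[:nf] * dt if traj_stride > 0 else None,
            final_state=sys_, meta=meta)


def run_scenario(config, n_steps: int | None = None, seed: int | None = None,
                 sample_stride: int | None = None,
                 traj_stride: int | None = None) -> RunResult:
    """Build the initial system for a config and run it."""
    from .builder import build_system

    if seed is not None:
        config = config.model_copy(deep=True)
        config.integrator.seed = int(seed)
    system = build_system(config)
    sim = Simulation(system, config.forcefield_params(),
                     config.chemistry_params(), config.integrator_params(),
                     config=config)
    res = sim.run(n_steps if n_steps is not None else config.integrator.n_steps,
                  sample_stride=(sample_stride if sample_stride is not None
                                 else config.output.sample_stride),
                  traj_stride=(traj_stride if traj_stride is not None
                               else config.output.traj_stride))
    res.meta["config_hash"] = config.config_hash()
    res.meta["scenario"] = config.scenario_name
    return res
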
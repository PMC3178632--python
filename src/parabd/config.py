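"""Run configuration: schema, validation, serialization, provenance hash.

A :class:`RunConfig` collects geometry, force field, chemistry, integrator and
output settings.  Unknown keys are rejected with their location, defaults are
filled in, and a canonical YAML serialization round-trips losslessly; the
sha256 of the canonical JSON form identifies the resolved configuration in
run manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .chemistry import ChemistryParams
from .dynamics import IntegratorParams
from .forcefield import ForceFieldParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryModel(_Strict):
    """Initial-system geometry (see :mod:`parabd.builder`)."""

    n_filaments: int = 7
    filament_length: int = 40
    arrangement: str = Field("packed_bundle", pattern="^(packed_bundle|tube)$")
    spacing: float = 2.0            # d0, in a
    crosslink_fraction: float = Field(0.4, ge=0.0, le=1.0)
    anchored: bool = True
    parb_total_length: int = 100
    parb_binding_length: int = 50
    parb_start_offset: float | None = None   # gap tip->ParB COM; None = one Rg_x
    external_force: float = 0.0     # magnitude, -x on each ParB end
    confinement_radius: float | None = None
    confinement_length: float | None = None
    alpha_parA: float = 1.0
    alpha_parb_bind: float = 1.0
    alpha_inert: float = 5.0        # drag factor of non-binding ParB subunits
    parb_relax_steps: int = 20_000  # free-polymer equilibration (chemistry off)
    prebind_steps: int = 10_000     # attachment relaxation (chemistry off)

    @model_validator(mode="after")
    def _check(self):
        if self.parb_binding_length > self.parb_total_length:
            raise ValueError("parb_binding_length must be <= parb_total_length")
        if self.spacing < 1.0:
            raise ValueError("spacing must be >= the subunit diameter")
        if self.n_filaments < 1 or self.filament_length < 1:
            raise ValueError("n_filaments and filament_length must be >= 1")
        return self


class ForceFieldModel(_Strict):
    subunit_diameter_a: float = 1.0
    k_ev: float = 100.0
    k_bond: float = 100.0
    k_crosslink: float = 50.0
    k_bend_parA: float = 50.0
    k_bend_parB: float = 0.0
    k_align: float = 10.0
    theta0_deg: float = 90.0
    k_helix_nn: float = 10.0
    k_helix_nnn: float = 10.0
    psi_nn_parA_deg: float = 60.0
    psi_nnn_parA_deg: float = 120.0
    psi_nn_parB_deg: float = 30.0
    psi_nnn_parB_deg: float = 60.0
    eps_b: float = 10.0
    r_b: float = 1.0
    range_b: float = 1.5
    ang_widths: tuple[float, float, float] = (0.6, 0.6, 0.6)
    binding_form: str = Field("oriented",
                              pattern="^(oriented|tip_no_parb_polar|side_no_parb_polar)$")

    def build(self, d0: float) -> ForceFieldParams:
        kw = self.model_dump()
        kw["binding_form"] = kw.pop("binding_form")
        return ForceFieldParams(d0=d0, **kw)


class ChemistryModel(_Strict):
    k_h: float = Field(20.0, ge=0.0)
    k_d: float = Field(2e-3, ge=0.0)
    eps_threshold: float | None = None   # None -> 0.5 * eps_b
    binding_mode: str = Field("side", pattern="^(side|tip_only)$")
    disassembly_mode: str = Field("tip_only", pattern="^(tip_only|severing)$")
    remove_monomer_distance: float | None = None

    def build(self, eps_b: float) -> ChemistryParams:
        thr = self.eps_threshold if self.eps_threshold is not None else 0.5 * eps_b
        return ChemistryParams(
            k_h=self.k_h, k_d=self.k_d, eps_threshold=thr,
            binding_mode=self.binding_mode, disassembly_mode=self.disassembly_mode,
            remove_monomer_distance=self.remove_monomer_distance)


class IntegratorModel(_Strict):
    dt: float = Field(1e-4, gt=0.0)
    kT: float = Field(1.0, gt=0.0)
    gamma0: float = Field(1.0, gt=0.0)
    gamma_rot: float = Field(1.0 / 3.0, gt=0.0)
    seed: int = 0
    n_steps: int = 1_000_000

    def build(self) -> IntegratorParams:
        return IntegratorParams(dt=self.dt, kT=self.kT, gamma0=self.gamma0,
                                gamma_rot=self.gamma_rot, seed=self.seed,
                                n_steps=self.n_steps)


class OutputModel(_Strict):
    sample_stride: int = 1000
    traj_stride: int = 0          # 0 disables frame capture
    directory: str | None = None


class RunConfig(_Strict):
    geometry: GeometryModel = GeometryModel()
    forcefield: ForceFieldModel = ForceFieldModel()
    chemistry: ChemistryModel = ChemistryModel()
    integrator: IntegratorModel = IntegratorModel()
    output: OutputModel = OutputModel()
    scenario_name: str | None = None

    # -- parameter-object factories ------------------------------------
    def forcefield_params(self) -> ForceFieldParams:
        return self.forcefield.build(d0=self.geometry.spacing)

    def chemistry_params(self) -> ChemistryParams:
        return self.chemistry.build(eps_b=self.forcefield.eps_b)

    def integrator_params(self) -> IntegratorParams:
        return self.integrator.build()

    # -- serialization --------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(self.model_dump_json()),
                              sort_keys=True, default_flow_style=False)

    def config_hash(self) -> str:
        payload = json.dumps(json.loads(self.model_dump_json()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def read_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def write_config(config: RunConfig, path) -> None:
    """Write the fully resolved configuration in canonical YAML form."""
    Path(path).write_text(config.to_yaml())
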
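"""JSON run configuration (pydantic models) and its mapping to domain types.

The JSON document has four blocks — ``cohort``, ``pressures``,
``driving_force`` and ``rig`` — each optional and fully defaulted, so an
empty ``{}`` reproduces the standard analysis.  Validation errors carry the
offending field path (pydantic); domain invariants (landmark ordering, area
positivity, ...) are enforced by the domain types themselves when the config
is materialized.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .driving_force import DrivingForceEstimate, estimate_driving_force
from .geometry_synth import ChamberLandmarks, CohortParams, CyclePhases, DEFAULT_T_ES
from .hydraulics import PressureModel
from .piston_sim import PistonRig

__all__ = [
    "PhasesConfig",
    "LandmarksConfig",
    "CohortConfig",
    "PressuresConfig",
    "DrivingForceConfig",
    "RigConfig",
    "RunConfig",
    "load_config",
]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhasesConfig(_Model):
    t_es: float = DEFAULT_T_ES
    t_cross_endo: float = 0.53
    t_dd: float = 0.70
    t_ak: float = 0.90

    def to_phases(self) -> CyclePhases:
        return CyclePhases(**self.model_dump())


class LandmarksConfig(_Model):
    a_ed: float
    a_es: float
    a_dd: float

    def to_landmarks(self) -> ChamberLandmarks:
        return ChamberLandmarks(**self.model_dump())


class CohortConfig(_Model):
    n_subjects: int = 10
    asa: LandmarksConfig = Field(default=LandmarksConfig(a_ed=14.0, a_es=20.0, a_dd=16.0))
    vsa_endo: LandmarksConfig = Field(default=LandmarksConfig(a_ed=26.0, a_es=12.0, a_dd=23.7))
    vsa_epi: LandmarksConfig = Field(default=LandmarksConfig(a_ed=45.0, a_es=38.0, a_dd=41.4))
    phases: PhasesConfig = Field(default_factory=PhasesConfig)
    subject_sd: dict[str, float] = Field(
        default={"asa": 0.0, "vsa_endo": 4.4, "vsa_epi": 7.3}
    )
    n_frames: int = 30
    seed: int = 0
    max_redraws: int = 100

    def to_params(self) -> CohortParams:
        return CohortParams(
            n_subjects=self.n_subjects,
            landmarks={
                "asa": self.asa.to_landmarks(),
                "vsa_endo": self.vsa_endo.to_landmarks(),
                "vsa_epi": self.vsa_epi.to_landmarks(),
            },
            phases=self.phases.to_phases(),
            subject_sd=dict(self.subject_sd),
            n_frames=self.n_frames,
            seed=self.seed,
            max_redraws=self.max_redraws,
        )


class PressuresConfig(_Model):
    p_la_mmhg: float = 10.0
    p_lv_mmhg: float = 10.0
    equal_pressure: bool = True

    def to_model(self) -> PressureModel:
        return PressureModel(p_la=self.p_la_mmhg, p_lv=self.p_lv_mmhg,
                             equal_pressure=self.equal_pressure)


class DrivingForceConfig(_Model):
    f_per_mass_mN_g: float = 25.0
    lv_mass_g: float = 125.0
    extra_min_g: float = 75.0
    extra_max_g: float = 275.0

    def to_estimate(self) -> DrivingForceEstimate:
        return estimate_driving_force(
            f_per_mass=self.f_per_mass_mN_g, lv_mass=self.lv_mass_g,
            extra_min=self.extra_min_g, extra_max=self.extra_max_g,
        )


class RigConfig(_Model):
    a_small: float = 1.00e-3
    a_large: float = 1.73e-3
    a_column: float = 5.0e-4
    h0: float = 1.4
    rho: float = 1000.0
    g: float = 9.81
    m_piston: float = 0.5
    damping: float = 50.0
    travel: float = 0.03

    def to_rig(self) -> PistonRig:
        return PistonRig(**self.model_dump())


class RunConfig(_Model):
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    pressures: PressuresConfig = Field(default_factory=PressuresConfig)
    driving_force: DrivingForceConfig = Field(default_factory=DrivingForceConfig)
    rig: RigConfig = Field(default_factory=RigConfig)
    output_dir: str = "out"
    report_precision: int = 6

    def sha256(self) -> str:
        """Stable hash of the fully-resolved configuration."""
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def load_config(path=None) -> RunConfig:
    """Load a RunConfig from a JSON file; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    return RunConfig.model_validate_json(text)
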
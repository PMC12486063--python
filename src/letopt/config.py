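"""Run configuration: one YAML file driving the whole pipeline.

Defaults encode the standard study conditions: c = 0.04 um/keV, 3 mm
isotropic grid, PTV dose window [0.95, 1.07] x prescription with the
98 %-of-PTV-at-95 % coverage rule checked post hoc, OAR cDL30 upper bounds
(30 % volume fraction), 200 solver iterations.  All parameter-domain checks
(lambda, alpha, eta, fractions) run at load time, and every run echoes the
config verbatim into its output directory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .influence import DEFAULT_C
from .phantom import BeamModelParams, StructureSpec
from .solvers import AMSParams, SuperiorizationParams

__all__ = ["PhantomConfig", "ConstraintConfig", "RunConfig"]


@dataclass(frozen=True)
class PhantomConfig:
    dims: tuple[int, int, int] = (20, 20, 20)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    ptv_radius_mm: float = 9.0
    seed: int = 42
    layout: list[StructureSpec] | None = None
    n_energy_layers: int = 5
    lateral_spacing_mm: float = 10.5

    def __post_init__(self) -> None:
        if self.ptv_radius_mm <= 0:
            raise ValueError("ptv_radius_mm must be > 0")


@dataclass(frozen=True)
class ConstraintConfig:
    prescription_Gy: float = 74.0
    ptv_lower_frac: float = 0.95
    ptv_upper_frac: float = 1.07
    ptv_v95_min_volume_pct: float = 98.0
    oar_fraction: float = 0.30
    ptv_weight: float = 10.0
    oar_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.prescription_Gy <= 0:
            raise ValueError("prescription must be > 0")
        if not 0 < self.ptv_lower_frac <= 1 <= self.ptv_upper_frac:
            raise ValueError("need 0 < ptv_lower_frac <= 1 <= ptv_upper_frac")
        if not 0 < self.oar_fraction < 1:
            raise ValueError("oar_fraction must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs; loadable from / echoable to YAML."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    beam: BeamModelParams = field(default_factory=BeamModelParams)
    constraints: ConstraintConfig = field(default_factory=ConstraintConfig)
    ams: AMSParams = field(default_factory=AMSParams)
    superiorization: SuperiorizationParams = field(default_factory=SuperiorizationParams)
    c: float = DEFAULT_C
    dose_floor_frac: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("constant c must be > 0")
        if self.dose_floor_frac < 0:
            raise ValueError("dose_floor_frac must be >= 0")

    @property
    def dose_floor_Gy(self) -> float:
        """Absolute LET_d reporting floor: a fraction of the prescription."""
        return self.dose_floor_frac * self.constraints.prescription_Gy

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        sections = {
            "phantom": PhantomConfig,
            "beam": BeamModelParams,
            "constraints": ConstraintConfig,
            "ams": AMSParams,
            "superiorization": SuperiorizationParams,
        }
        for key, klass in sections.items():
            if key in raw:
                section = dict(raw[key])
                if key == "phantom":
                    if "dims" in section:
                        section["dims"] = tuple(section["dims"])
                    if "spacing" in section:
                        section["spacing"] = tuple(section["spacing"])
                    if section.get("layout"):
                        section["layout"] = [
                            StructureSpec(
                                name=s["name"],
                                role=s["role"],
                                shape=s.get("shape", "sphere"),
                                center_mm=tuple(s.get("center_mm", (0, 0, 0))),
                                size_mm=(
                                    tuple(s["size_mm"])
                                    if isinstance(s["size_mm"], (list, tuple))
                                    else s["size_mm"]
                                ),
                                priority=s.get("priority"),
                            )
                            for s in section["layout"]
                        ]
                kwargs[key] = klass(**section)
        for key in ("c", "dose_floor_frac", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def echo(self, out_dir) -> Path:
        """Write the fully resolved configuration into the output directory."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "config.yaml"
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path
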
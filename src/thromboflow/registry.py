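"""Central registry of microspot designs, kinetic parameters and flow conditions.

The assay measures platelet-fibrin thrombus formation in flowing whole blood
over protein microspots (M1-M9).  Each microspot presents defined platelet
receptors and may be co-coated with tissue factor (TF, extrinsic coagulation
trigger) or with an anticoagulant (thrombomodulin or activated protein C).
Nine kinetic readouts (P1-P9) are recorded per microspot: platelet adhesion
and phosphatidylserine exposure (P1-P2), thrombus coverage, morphology,
aggregation and contraction (P3-P6), fibrin deposition and score (P7-P8),
and the shortened time-to-fibrin statistic (P9, reported as ``11 - t`` min
with a default of 11 min when no fibrin is seen).

The coding is shipped as a versioned JSON file so downstream analyses are
reproducible against a pinned registry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

__all__ = [
    "MicrospotDesign",
    "ParameterDef",
    "Condition",
    "ParameterRecord",
    "RegistryError",
    "load_registry",
    "registry_lookup",
    "condition_class",
    "CAPTURE_TIMES",
    "OBSERVATION_LIMIT_MIN",
    "P9_DEFAULT_MIN",
    "PARAMETER_IDS",
    "SURFACE_IDS",
]

#: Standard capture grid for P1-P8 (minutes).
CAPTURE_TIMES: tuple[int, ...] = (0, 2, 4, 6, 8)

#: Fibrin is watched up to this time (minutes) ...
OBSERVATION_LIMIT_MIN: float = 10.0
#: ... and P9 defaults to ``11 - 11 = 0`` when no fibrin appears by then.
P9_DEFAULT_MIN: float = 11.0

SURFACE_IDS: tuple[str, ...] = tuple(f"M{i}" for i in range(1, 10))
PARAMETER_IDS: tuple[str, ...] = tuple(f"P{i}" for i in range(1, 10))


class RegistryError(KeyError):
    """Raised when an unknown surface or parameter id is looked up."""


@dataclass(frozen=True)
class MicrospotDesign:
    """One microspot coating design (a row of the M-coding table)."""

    id: str
    description: str
    components: tuple[Mapping[str, object], ...]
    receptors: tuple[str, ...]
    co_coating: str | None  # "TF" | "TM" | "APC" | None
    co_coating_dose: float | None
    co_coating_dose_unit: str | None
    co_coating_optional: bool
    tf_in_medium: bool  # 10 pM TF added to recalcification medium (M8-M9 convention)

    def __post_init__(self) -> None:
        # TF vs TM/APC co-coating exclusivity is structural: one field.
        if self.co_coating == "TF" and self.tf_in_medium:
            raise ValueError("TF co-coating and TF-in-medium are mutually exclusive")
        if self.co_coating not in (None, "TF", "TM", "APC"):
            raise ValueError(f"unknown co-coating {self.co_coating!r}")
        for comp in self.components:
            if float(comp["concentration"]) < 0:  # type: ignore[arg-type]
                raise ValueError(f"negative concentration in {self.id}")
        if self.co_coating_dose is not None and self.co_coating_dose < 0:
            raise ValueError(f"negative co-coating dose in {self.id}")


@dataclass(frozen=True)
class ParameterDef:
    """Definition of one kinetic readout (a row of the P-coding table)."""

    id: str
    description: str
    channel: str  # platelet | ps | fibrin | brightfield
    unit: str  # %SAC | score | "11 - t min"
    range: tuple[float, float]
    integer: bool
    capture_times: tuple[int, ...]

    def validate(self, value: float) -> None:
        """Raise ``ValueError`` if *value* violates this parameter's contract."""
        lo, hi = self.range
        if not (lo <= value <= hi):
            raise ValueError(f"{self.id} value {value} outside [{lo}, {hi}]")
        if self.integer and float(value) != int(value):
            raise ValueError(f"{self.id} must be an integer score, got {value}")


@dataclass(frozen=True)
class Condition:
    """Flow-run condition: shear rate plus the coagulation interventions.

    The (TF, iFVIIa, CTI) boolean triple defines one of 8 condition classes
    used by the prediction layer.  ``tf`` triggers the extrinsic pathway,
    ``ifviia`` (active-site inactivated FVIIa) blocks it, and ``cti`` (corn
    trypsin inhibitor) blocks the intrinsic FXIIa pathway.
    """

    shear_rate: int = 1000  # wall shear rate, 1/s
    tf: bool = False
    tf_dose_pm: float = 0.0
    ifviia: bool = False
    cti: bool = False
    soluble: str = "none"  # none | C4BP | sAPC

    def __post_init__(self) -> None:
        if self.shear_rate not in (150, 1000):
            raise ValueError("shear rate must be 150 or 1000 1/s")
        if self.tf and self.tf_dose_pm <= 0:
            object.__setattr__(self, "tf_dose_pm", 500.0)
        if not self.tf:
            object.__setattr__(self, "tf_dose_pm", 0.0)
        if self.soluble not in ("none", "C4BP", "sAPC"):
            raise ValueError(f"unknown soluble addition {self.soluble!r}")

    def with_tf(self, dose_pm: float = 500.0) -> "Condition":
        return replace(self, tf=dose_pm > 0, tf_dose_pm=float(dose_pm))

    @property
    def label(self) -> str:
        bits = [
            f"{self.shear_rate}s",
            f"TF{self.tf_dose_pm:g}" if self.tf else "noTF",
        ]
        if self.ifviia:
            bits.append("iFVIIa")
        if self.cti:
            bits.append("CTI")
        if self.soluble != "none":
            bits.append(self.soluble)
        return "+".join(bits)


def condition_class(condition: Condition) -> int:
    """Map the (TF, iFVIIa, CTI) triple to its class index 0..7.

    Bit order is TF=4, iFVIIa=2, CTI=1, so the all-absent condition is class
    0 and the all-present condition is class 7.  The map is a bijection on
    the 8 triples.
    """
    return 4 * int(condition.tf) + 2 * int(condition.ifviia) + int(condition.cti)


@dataclass
class ParameterRecord:
    """P1-P9 values for one subject x surface x condition flow run.

    A complete record holds 8 parameters x 5 capture times plus the scalar
    P9, i.e. 41 values.
    """

    subject: str
    surface: str
    condition: Condition
    values: dict[tuple[str, int], float] = field(default_factory=dict)
    p9: float | None = None
    provenance: str = "measured"  # measured | synthetic
    seed: int | None = None

    TIMED_PARAMETERS = PARAMETER_IDS[:8]

    def n_values(self) -> int:
        return len(self.values) + (self.p9 is not None)

    @property
    def complete(self) -> bool:
        expected = {
            (p, t) for p in self.TIMED_PARAMETERS for t in CAPTURE_TIMES
        }
        return self.p9 is not None and set(self.values) == expected

    def validate(self, registry: "Registry | None" = None) -> None:
        reg = registry or load_registry()
        for (pid, t), value in self.values.items():
            pdef = reg.parameters[pid]
            if t not in pdef.capture_times:
                raise ValueError(f"{pid} has no capture time {t}")
            pdef.validate(value)
            if t == 0 and pid in ("P4", "P5", "P6", "P8") and value != 0:
                raise ValueError(f"{pid} must be 0 on the blank t=0 field")
        if self.p9 is not None:
            reg.parameters["P9"].validate(self.p9)
            if not (self.p9 == 0 or 1 <= self.p9 <= 11):
                raise ValueError("P9 must be 0 (no fibrin) or in [1, 11]")


@dataclass(frozen=True)
class Registry:
    """Immutable registry of surface designs and parameter definitions."""

    schema_version: int
    surfaces: Mapping[str, MicrospotDesign]
    parameters: Mapping[str, ParameterDef]

    def lookup(self, id: str) -> MicrospotDesign | ParameterDef:
        if id in self.surfaces:
            return self.surfaces[id]
        if id in self.parameters:
            return self.parameters[id]
        raise RegistryError(f"unknown registry id {id!r}")

    def to_dict(self) -> dict:
        def _surface(s: MicrospotDesign) -> dict:
            return {
                "id": s.id,
                "description": s.description,
                "components": [dict(c) for c in s.components],
                "receptors": list(s.receptors),
                "co_coating": s.co_coating,
                "co_coating_dose": s.co_coating_dose,
                "co_coating_dose_unit": s.co_coating_dose_unit,
                "co_coating_optional": s.co_coating_optional,
                "tf_in_medium": s.tf_in_medium,
            }

        def _param(p: ParameterDef) -> dict:
            return {
                "id": p.id,
                "description": p.description,
                "channel": p.channel,
                "unit": p.unit,
                "range": list(p.range),
                "integer": p.integer,
                "capture_times": list(p.capture_times),
            }

        return {
            "schema_version": self.schema_version,
            "surfaces": {k: _surface(v) for k, v in self.surfaces.items()},
            "parameters": {k: _param(v) for k, v in self.parameters.items()},
        }


def _registry_from_dict(raw: dict) -> Registry:
    surfaces = {
        sid: MicrospotDesign(
            id=s["id"],
            description=s["description"],
            components=tuple(s["components"]),
            receptors=tuple(s["receptors"]),
            co_coating=s["co_coating"],
            co_coating_dose=s["co_coating_dose"],
            co_coating_dose_unit=s["co_coating_dose_unit"],
            co_coating_optional=s["co_coating_optional"],
            tf_in_medium=s["tf_in_medium"],
        )
        for sid, s in raw["surfaces"].items()
    }
    parameters = {
        pid: ParameterDef(
            id=p["id"],
            description=p["description"],
            channel=p["channel"],
            unit=p["unit"],
            range=(float(p["range"][0]), float(p["range"][1])),
            integer=p["integer"],
            capture_times=tuple(p["capture_times"]),
        )
        for pid, p in raw["parameters"].items()
    }
    return Registry(
        schema_version=int(raw["schema_version"]),
        surfaces=surfaces,
        parameters=parameters,
    )


_REGISTRY_CACHE: Registry | None = None


def load_registry(path: str | None = None) -> Registry:
    """Load the pinned registry (or a registry JSON at *path*)."""
    global _REGISTRY_CACHE
    if path is None:
        if _REGISTRY_CACHE is None:
            text = resources.files("thromboflow.data").joinpath("registry.json").read_text()
            _REGISTRY_CACHE = _registry_from_dict(json.loads(text))
        return _REGISTRY_CACHE
    with open(path) as fh:
        return _registry_from_dict(json.load(fh))


def registry_lookup(id: str) -> MicrospotDesign | ParameterDef:
    """Return the immutable registry entry for a surface or parameter id."""
    return load_registry().lookup(id)
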
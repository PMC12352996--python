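"""Drug-specific parameters and dosing scenario definitions.

The default parameter set is the final henagliflozin parameterization:
physicochemistry (logP, MW, solubility), a Weibull dissolution profile,
specific intestinal permeability, plasma binding, blood/plasma ratio, a
glomerular-filtration scaling fraction, and per-enzyme intrinsic clearances
for the UGT1A9 / UGT2B7 / UGT1A3 glucuronidation pathways plus a lumped
CYP3A4-family oxidative pathway.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

SCHEMA_VERSION = 1

UGT_ENZYMES = ("UGT1A9", "UGT2B7", "UGT1A3")
CYP_FAMILY = "CYP3A4"
ENZYME_NAMES = UGT_ENZYMES + (CYP_FAMILY,)


class ScenarioError(ValueError):
    """Raised when a scenario configuration is invalid."""


@dataclass
class EnzymeProcess:
    """One first-order metabolic pathway.

    ``clint`` is in uL/min/mg microsomal protein for UGTs and uL/min/pmol
    recombinant enzyme for the CYP family. ``microsomal_content`` (pmol/mg,
    UGTs only) is carried as reference metadata. ``tissue_split`` gives the
    (liver, kidney) allocation of the pathway's clearance capacity.
    """

    enzyme_name: str
    clint: float
    microsomal_content: float | None = None
    tissue_split: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.enzyme_name not in ENZYME_NAMES:
            raise ValueError(f"unknown enzyme {self.enzyme_name!r}")
        if self.clint < 0:
            raise ValueError("clint must be >= 0")
        if self.tissue_split is None:
            # 90% liver / 10% kidney for glucuronidation; CYP is hepatic only
            self.tissue_split = (0.9, 0.1) if self.enzyme_name != CYP_FAMILY else (1.0, 0.0)
        self.tissue_split = (float(self.tissue_split[0]), float(self.tissue_split[1]))
        if abs(sum(self.tissue_split) - 1.0) > 1e-9:
            raise ValueError("tissue_split must sum to 1")


@dataclass
class CompoundParameters:
    """Physicochemistry, absorption, binding and clearance inputs.

    Units: MW g/mol; solubility mg/mL; dissolution_time50 minutes (time to
    50% dissolved, the Weibull median); intestinal_permeability cm/s; fu and
    gfr_fraction dimensionless fractions.
    """

    name: str = "henagliflozin"
    logP: float = 2.1
    MW: float = 454.9
    solubility: float = 0.182
    dissolution_time50: float = 87.0
    dissolution_shape: float = 1.70
    intestinal_permeability: float = 6.7e-4
    fu: float = 0.05
    bp_ratio: float = 0.55
    gfr_fraction: float = 0.70
    cyp_reference_conc: float = 4.32  # umol/L liver, lumped CYP3A4-family
    enzyme_processes: list[EnzymeProcess] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.fu <= 1.0):
            raise ValueError("fu must be in (0, 1]")
        if self.bp_ratio <= 0:
            raise ValueError("bp_ratio must be > 0")
        if self.MW <= 0:
            raise ValueError("MW must be > 0")
        for attr in ("solubility", "dissolution_time50", "dissolution_shape",
                     "intestinal_permeability", "gfr_fraction"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")

    def process(self, enzyme_name: str) -> EnzymeProcess:
        for p in self.enzyme_processes:
            if p.enzyme_name == enzyme_name:
                return p
        raise KeyError(enzyme_name)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for p in d["enzyme_processes"]:
            p["tissue_split"] = list(p["tissue_split"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CompoundParameters":
        d = dict(d)
        procs = [EnzymeProcess(**{**p, "tissue_split": tuple(p["tissue_split"])
                                  if p.get("tissue_split") else None})
                 for p in d.pop("enzyme_processes", [])]
        return cls(enzyme_processes=procs, **d)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CompoundParameters":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls.from_dict(json.loads(text))


def default_henagliflozin() -> CompoundParameters:
    """The final henagliflozin parameter set (optimized values)."""
    return CompoundParameters(
        enzyme_processes=[
            EnzymeProcess("UGT1A9", clint=32.4, microsomal_content=61.2),
            EnzymeProcess("UGT2B7", clint=20.7, microsomal_content=200.0),
            EnzymeProcess("UGT1A3", clint=6.3, microsomal_content=20.6),
            EnzymeProcess(CYP_FAMILY, clint=0.08),
        ]
    )


@dataclass
class DosingRegimen:
    dose: float  # mg
    interval: float = 24.0  # h
    n_doses: int = 1
    prandial_state: str = "fasted"
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.prandial_state not in ("fasted", "fed"):
            raise ValueError("prandial_state must be 'fasted' or 'fed'")
        if self.route != "oral":
            raise ValueError("only the oral route is supported")


@dataclass
class FeedingEvent:
    meal_energy: float = 1000.0  # kcal
    time_offset: float = 0.0  # h relative to dose

    def __post_init__(self) -> None:
        if self.meal_energy < 0:
            raise ValueError("meal_energy must be >= 0")


# ---------------------------------------------------------------------------
# Scenario configuration (YAML)
# ---------------------------------------------------------------------------

_REGIMEN_DEFAULTS = {"interval_h": 24.0, "n_doses": 1, "prandial_state": "fasted"}
_POPULATION_DEFAULTS = {
    "subgroup": "adult", "n": 1, "sex_ratio": 0.5, "impairment": "healthy",
    "age_range": None, "seed": 0, "variability": None,
}


def _compound_from_config(block: dict[str, Any] | None) -> CompoundParameters:
    base = default_henagliflozin()
    if not block:
        return base
    d = base.to_dict()
    for key, value in block.items():
        if key == "enzyme_processes":
            d["enzyme_processes"] = value
        elif key in d:
            d[key] = value
        else:
            raise ScenarioError(f"unknown compound field {key!r}")
    return CompoundParameters.from_dict(d)


def _regimen_from_config(block: dict[str, Any]) -> DosingRegimen:
    if "dose_mg" not in block:
        raise ScenarioError("regimen block must declare 'dose_mg'")
    merged = {**_REGIMEN_DEFAULTS, **block}
    try:
        return DosingRegimen(
            dose=float(merged["dose_mg"]),
            interval=float(merged["interval_h"]),
            n_doses=int(merged["n_doses"]),
            prandial_state=str(merged["prandial_state"]),
        )
    except ValueError as exc:
        # name the offending field for schema diagnostics
        raise ScenarioError(f"invalid regimen: {exc} (fields: {sorted(block)})") from exc


@dataclass
class Scenario:
    """Validated scenario: compound, regimen, population descriptor, run opts."""

    compound: CompoundParameters
    regimen: DosingRegimen
    population: dict[str, Any]
    pd_model: dict[str, float]
    run: dict[str, Any]
    clearance_budget: dict[str, Any] | None = None
    sensitivity: dict[str, Any] | None = None
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict[str, Any]:
        reg = self.regimen
        return {
            "schema_version": self.schema_version,
            "compound": self.compound.to_dict(),
            "regimen": {"dose_mg": reg.dose, "interval_h": reg.interval,
                        "n_doses": reg.n_doses, "prandial_state": reg.prandial_state},
            "population": self.population,
            "pd_model": self.pd_model,
            "run": self.run,
            "clearance_budget": self.clearance_budget,
            "sensitivity": self.sensitivity,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


_DEFAULT_PD = {"emax_cmax": 48.8, "ec50_cmax": 62.0, "emax_auc": 48.2, "ec50_auc": 356.0}
_DEFAULT_RUN = {"duration_h": None, "rtol": 1e-8, "atol": 1e-10, "output_step_h": 0.1}


def load_scenario(config_path: str | Path) -> Scenario:
    """Parse and validate a YAML scenario file.

    Unspecified blocks take documented defaults; the compound block defaults
    to the full henagliflozin parameter set.
    """
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(f"scenario file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ScenarioError("scenario file must contain a mapping")
    known = {"schema_version", "compound", "regimen", "population", "pd_model",
             "run", "clearance_budget", "sensitivity"}
    unknown = set(raw) - known
    if unknown:
        raise ScenarioError(f"unknown top-level keys: {sorted(unknown)}")
    if "regimen" not in raw:
        raise ScenarioError("scenario must declare a 'regimen' block")
    version = int(raw.get("schema_version", SCHEMA_VERSION))
    if version != SCHEMA_VERSION:
        raise ScenarioError(f"unsupported schema_version {version}")
    compound = _compound_from_config(raw.get("compound"))
    regimen = _regimen_from_config(dict(raw["regimen"]))
    population = {**_POPULATION_DEFAULTS, **(raw.get("population") or {})}
    pd_model = {**_DEFAULT_PD, **(raw.get("pd_model") or {})}
    run = {**_DEFAULT_RUN, **(raw.get("run") or {})}
    return Scenario(compound=compound, regimen=regimen, population=population,
                    pd_model=pd_model, run=run,
                    clearance_budget=raw.get("clearance_budget"),
                    sensitivity=raw.get("sensitivity"), schema_version=version)
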
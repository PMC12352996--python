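"""Virtual individuals and populations.

Builds a reference East Asian adult from packaged ICRP-style anatomy
tables, scales anthropometry / organ volumes / blood flows / GFR to any
age, applies enzyme-ontogeny maturation functions and Child-Pugh hepatic
impairment scalings, and samples variable populations reproducibly.

Conventions
-----------
* Organ ``blood_flow`` entries are systemic arterial inflows (L/h); the
  liver entry is the hepatic artery only, with portal inflow given by the
  pooled splanchnic outflows. The lung entry equals cardiac output.
* ``enzyme_expression`` multipliers are relative to the reference adult
  (1.0); ontogeny, impairment and inter-individual variability all act
  multiplicatively on them.
* GFR is in mL/min.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .compound import CYP_FAMILY, ENZYME_NAMES

REFERENCE_AGE = 30.0
REFERENCE_WEIGHT = 63.0  # kg, adult male
REFERENCE_CO = 340.0  # L/h
ADULT_GFR = 110.0  # mL/min per 1.73 m2
GFR_TM50_PMA = 47.7  # weeks postmenstrual age
GFR_HILL = 3.4

SPLANCHNIC_ORGANS = ("stomach", "small_intestine", "large_intestine", "spleen", "pancreas")
BLOOD_POOLS = ("arterial_blood", "venous_blood", "portal_vein")

SUBGROUP_AGE_BOUNDS = {
    "neonate": (0.0, 27.0 / 365.25),
    "infant_toddler": (28.0 / 365.25, 23.0 / 12.0),
    "child": (2.0, 12.0),
    "adolescent": (12.0, 18.0),
    "adult": (18.0, 45.0),
    "custom": (0.0, 100.0),
}

DEFAULT_VARIABILITY = {
    "weight": 0.12,
    "organ_volume": 0.20,
    "blood_flow": 0.20,
    "enzyme": 0.30,
    "gfr": 0.20,
}


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("henapbpk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


_ANATOMY = _load_table("reference_anatomy.csv").set_index("organ")
_GROWTH = _load_table("growth_reference.csv")
_AGE_FACTORS = _load_table("organ_age_factors.csv").set_index("organ")
_AGE_FACTOR_GRID = np.array([0.0, 1.0, 5.0, 10.0, 15.0, REFERENCE_AGE])
_ONTOGENY = _load_table("ontogeny_parameters.csv").set_index("enzyme")
_IMPAIRMENT = _load_table("hepatic_impairment.csv").set_index("parameter")

PERFUSED_ORGANS = tuple(o for o in _ANATOMY.index if o not in BLOOD_POOLS)


@dataclass
class Individual:
    age: float
    sex: str
    weight: float
    height: float
    organs: dict[str, dict[str, float]]
    hematocrit: float = 0.47
    enzyme_expression: dict[str, float] = field(
        default_factory=lambda: {e: 1.0 for e in ENZYME_NAMES})
    plasma_protein_factors: dict[str, float] = field(
        default_factory=lambda: {"albumin_ontogeny": 1.0, "agp_ontogeny": 1.0})
    gfr: float = ADULT_GFR
    impairment_grade: str = "healthy"
    id: str = "ref"

    def __post_init__(self) -> None:
        if not (0.0 < self.hematocrit < 1.0):
            raise ValueError("hematocrit must be in (0, 1)")
        for organ, entry in self.organs.items():
            if entry["volume"] < 0 or entry.get("blood_flow", 0.0) < 0:
                raise ValueError(f"negative volume/flow for {organ}")
        if self.gfr < 0:
            raise ValueError("gfr must be >= 0")

    @property
    def cardiac_output(self) -> float:
        return self.organs["lung"]["blood_flow"]

    def systemic_flow_sum(self) -> float:
        return sum(e["blood_flow"] for name, e in self.organs.items()
                   if name not in BLOOD_POOLS + ("lung",))

    def copy(self) -> "Individual":
        return copy.deepcopy(self)


def body_surface_area(weight: float, height: float) -> float:
    """Du Bois BSA in m^2 (weight kg, height cm)."""
    return 0.007184 * weight ** 0.425 * height ** 0.725


def gfr_maturation(age: float) -> float:
    """Fraction of BSA-normalized adult GFR, Hill function of postmenstrual age."""
    pma = age * 52.14 + 40.0
    return pma ** GFR_HILL / (pma ** GFR_HILL + GFR_TM50_PMA ** GFR_HILL)


def ontogeny_factor(enzyme: str, age: float,
                    parameters: pd.DataFrame | None = None) -> float:
    """Fraction of adult enzyme expression at a given age (1.0 from age 18)."""
    if age >= 18.0:
        return 1.0
    table = _ONTOGENY if parameters is None else parameters
    tm50 = float(table.loc[enzyme, "tm50_pma_weeks"])
    hill = float(table.loc[enzyme, "hill"])
    pma = age * 52.14 + 40.0
    return pma ** hill / (pma ** hill + tm50 ** hill)


def _growth_lookup(age: float, sex: str) -> tuple[float, float]:
    wcol = "weight_m_kg" if sex == "male" else "weight_f_kg"
    hcol = "height_m_cm" if sex == "male" else "height_f_cm"
    ages = _GROWTH["age_years"].to_numpy()
    w = float(np.interp(age, ages, _GROWTH[wcol].to_numpy()))
    h = float(np.interp(age, ages, _GROWTH[hcol].to_numpy()))
    return w, h


def _organ_age_factor(organ: str, age: float) -> float:
    if organ not in _AGE_FACTORS.index:
        return 1.0
    row = _AGE_FACTORS.loc[organ].to_numpy(dtype=float)
    return float(np.interp(age, _AGE_FACTOR_GRID, row))


def create_reference_adult() -> Individual:
    """The typical 30-year-old East Asian male used as the scaling anchor."""
    organs = {o: {"volume": float(_ANATOMY.loc[o, "volume_l"]),
                  "blood_flow": float(_ANATOMY.loc[o, "flow_fraction_co"]) * REFERENCE_CO}
              for o in _ANATOMY.index}
    w, h = _growth_lookup(REFERENCE_AGE, "male")
    return Individual(age=REFERENCE_AGE, sex="male", weight=w, height=h,
                      organs=organs, gfr=ADULT_GFR *
                      body_surface_area(w, h) / 1.73 * gfr_maturation(REFERENCE_AGE))


def scale_to_age(reference: Individual, age: float, sex: str = "male",
                 seed: int | None = None) -> Individual:
    """Deterministic age/sex scaling of anthropometry, organs, flows and GFR.

    Organ volumes scale with body weight modulated by organ-specific
    age factors (brain, liver, kidney, muscle, adipose deviate from
    weight-proportionality in childhood). Flows preserve the reference
    specific perfusion of each organ and are renormalized so the systemic
    sum equals cardiac output, which scales allometrically (W^0.75).
    ``seed`` is accepted for interface symmetry; the operation is
    deterministic (variability is added at the population level).
    """
    del seed
    if not (0.0 <= age <= 100.0):
        raise ValueError("age out of supported range [0, 100]")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    weight, height = _growth_lookup(age, sex)
    w_ratio = weight / REFERENCE_WEIGHT
    co = REFERENCE_CO * w_ratio ** 0.75

    organs: dict[str, dict[str, float]] = {}
    raw_flows: dict[str, float] = {}
    for organ in reference.organs:
        ref = reference.organs[organ]
        if organ in BLOOD_POOLS:
            organs[organ] = {"volume": ref["volume"] * w_ratio, "blood_flow": 0.0}
            continue
        vol = ref["volume"] * w_ratio * _organ_age_factor(organ, age)
        organs[organ] = {"volume": vol, "blood_flow": 0.0}
        if organ != "lung" and ref["volume"] > 0:
            raw_flows[organ] = (ref["blood_flow"] / ref["volume"]) * vol
    norm = co / sum(raw_flows.values())
    for organ, q in raw_flows.items():
        organs[organ]["blood_flow"] = q * norm
    organs["lung"]["blood_flow"] = co

    gfr = ADULT_GFR * body_surface_area(weight, height) / 1.73 * gfr_maturation(age)
    return Individual(age=age, sex=sex, weight=weight, height=height,
                      organs=organs, hematocrit=reference.hematocrit, gfr=gfr)


def apply_ontogeny(individual: Individual,
                   parameters: pd.DataFrame | None = None) -> Individual:
    """Set enzyme expression multipliers to their age maturation fractions."""
    out = individual.copy()
    for enzyme in ENZYME_NAMES:
        out.enzyme_expression[enzyme] = ontogeny_factor(enzyme, individual.age, parameters)
    alb = 1.0 - 0.25 * np.exp(-3.5 * individual.age)
    agp = 1.0 - 0.55 * np.exp(-2.0 * individual.age)
    out.plasma_protein_factors = {"albumin_ontogeny": float(alb),
                                  "agp_ontogeny": float(agp)}
    return out


# ---------------------------------------------------------------------------
# Hepatic impairment
# ---------------------------------------------------------------------------

@dataclass
class ImpairmentScaling:
    grade: str
    portal_flow_fraction: float
    hepatic_arterial_flow_fraction: float
    renal_flow_fraction: float
    brain_flow_fraction: float
    other_organ_flow_fraction: float
    liver_volume_fraction: float
    hematocrit: float
    albumin_factor: float
    agp_factor: float
    enzyme_conc_factors: dict[str, float]
    gfr_fraction: float

    @classmethod
    def for_grade(cls, grade: str) -> "ImpairmentScaling":
        key = {"healthy": "healthy", "CP-A": "cp_a", "CP-B": "cp_b", "CP-C": "cp_c"}
        if grade not in key:
            raise ValueError(f"unknown impairment grade {grade!r}")
        col = key[grade]
        t = _IMPAIRMENT[col]
        cyp_ref = float(_IMPAIRMENT.loc["cyp3a4_conc", "healthy"])
        return cls(
            grade=grade,
            portal_flow_fraction=float(t["portal_flow"]),
            hepatic_arterial_flow_fraction=float(t["hepatic_arterial_flow"]),
            renal_flow_fraction=float(t["renal_flow"]),
            brain_flow_fraction=float(t["brain_flow"]),
            other_organ_flow_fraction=float(t["other_organ_flow"]),
            liver_volume_fraction=float(t["liver_volume"]),
            hematocrit=float(t["hematocrit"]),
            albumin_factor=float(t["albumin"]),
            agp_factor=float(t["agp"]),
            enzyme_conc_factors={
                "UGT1A9": float(t["ugt1a9_conc"]),
                "UGT2B7": float(t["ugt2b7_conc"]),
                CYP_FAMILY: float(t["cyp3a4_conc"]) / cyp_ref,
                "UGT1A3": 1.0,
            },
            gfr_fraction=float(t["gfr"]),
        )


def apply_hepatic_impairment(individual: Individual,
                             scaling: ImpairmentScaling) -> Individual:
    """Apply Child-Pugh physiological scalers to an adult individual."""
    if individual.age < 18.0:
        raise ValueError("hepatic impairment scaling is defined for adults only")
    out = individual.copy()
    for organ in SPLANCHNIC_ORGANS:
        out.organs[organ]["blood_flow"] *= scaling.portal_flow_fraction
    out.organs["liver"]["blood_flow"] *= scaling.hepatic_arterial_flow_fraction
    out.organs["kidney"]["blood_flow"] *= scaling.renal_flow_fraction
    out.organs["brain"]["blood_flow"] *= scaling.brain_flow_fraction
    other = [o for o in PERFUSED_ORGANS
             if o not in SPLANCHNIC_ORGANS + ("liver", "kidney", "brain", "lung")]
    for organ in other:
        out.organs[organ]["blood_flow"] *= scaling.other_organ_flow_fraction
    out.organs["liver"]["volume"] *= scaling.liver_volume_fraction
    out.organs["lung"]["blood_flow"] = out.systemic_flow_sum()
    out.hematocrit = scaling.hematocrit
    out.plasma_protein_factors["albumin_ontogeny"] *= scaling.albumin_factor
    out.plasma_protein_factors["agp_ontogeny"] *= scaling.agp_factor
    for enzyme, factor in scaling.enzyme_conc_factors.items():
        out.enzyme_expression[enzyme] *= factor
    out.gfr *= scaling.gfr_fraction
    out.impairment_grade = scaling.grade
    return out


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    n: int = 100
    subgroup: str = "adult"
    age_range: tuple[float, float] | None = None
    sex_ratio: float = 0.5  # fraction female
    impairment_grade: str = "healthy"
    variability: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")
        lo, hi = SUBGROUP_AGE_BOUNDS[self.subgroup]
        if self.age_range is None:
            self.age_range = (lo, hi)
        else:
            a, b = self.age_range
            if a > b:
                raise ValueError("empty age range")
            if self.subgroup != "custom" and (a < lo - 1e-9 or b > hi + 1e-9):
                raise ValueError(f"age_range {self.age_range} outside "
                                 f"{self.subgroup} bounds {lo, hi}")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 multiplicative lognormal perturbation with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def sample_population(spec: PopulationSpec,
                      reference: Individual | None = None) -> list[Individual]:
    """Sample ``spec.n`` individuals, reproducibly under ``spec.seed``.

    Sexes are split deterministically (floor(n * sex_ratio) females, the
    remainder male); ages are uniform over the age range; anthropometry,
    organ volumes/flows, GFR and enzyme expression carry mean-1 lognormal
    variability with configurable CVs.
    """
    reference = reference or create_reference_adult()
    cvs = {**DEFAULT_VARIABILITY, **(spec.variability or {})}
    rng = np.random.default_rng(spec.seed)
    n_female = int(spec.n * spec.sex_ratio)
    lo, hi = spec.age_range
    scaling = (ImpairmentScaling.for_grade(spec.impairment_grade)
               if spec.impairment_grade != "healthy" else None)

    individuals = []
    for i in range(spec.n):
        sex = "female" if i < n_female else "male"
        age = float(rng.uniform(lo, hi))
        ind = scale_to_age(reference, age, sex)
        ind = apply_ontogeny(ind)
        f_w = float(_lognormal_factor(rng, cvs["weight"]))
        ind.weight *= f_w
        co_f = float(_lognormal_factor(rng, cvs["blood_flow"]))
        raw = {}
        for organ in ind.organs:
            if organ in BLOOD_POOLS:
                continue
            ind.organs[organ]["volume"] *= f_w * float(
                _lognormal_factor(rng, cvs["organ_volume"]))
            if organ != "lung":
                raw[organ] = ind.organs[organ]["blood_flow"] * float(
                    _lognormal_factor(rng, cvs["blood_flow"]))
        co = ind.cardiac_output * f_w ** 0.75 * co_f
        norm = co / sum(raw.values())
        for organ, q in raw.items():
            ind.organs[organ]["blood_flow"] = q * norm
        ind.organs["lung"]["blood_flow"] = co
        ind.gfr *= float(_lognormal_factor(rng, cvs["gfr"]))
        for enzyme in ind.enzyme_expression:
            ind.enzyme_expression[enzyme] *= float(_lognormal_factor(rng, cvs["enzyme"]))
        if scaling is not None:
            ind = apply_hepatic_impairment(ind, scaling)
        ind.id = f"{spec.subgroup}-{i:03d}"
        individuals.append(ind)
    return individuals


def population_to_frame(individuals: Iterable[Individual]) -> pd.DataFrame:
    """One row per individual: demographics, GFR and enzyme multipliers."""
    rows = []
    for ind in individuals:
        row = {"id": ind.id, "age": ind.age, "sex": ind.sex, "weight": ind.weight,
               "height": ind.height, "gfr": ind.gfr,
               "impairment": ind.impairment_grade}
        row.update({f"expr_{e}": ind.enzyme_expression[e] for e in ENZYME_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
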
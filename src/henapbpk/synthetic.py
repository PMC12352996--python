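"""Synthetic "observed" clinical datasets.

Clinical concentration-time profiles for this compound exist only as
digitized literature figures; this module generates stand-ins with the same
statistical structure (per-subject multiplicative lognormal residual error
around a true model profile, censoring below a quantification limit) so the
qualification-metric and fitting pipelines are testable end to end. All
study labels carry a ``synthetic:`` namespace to prevent confusion with
literature data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compound import CompoundParameters, DosingRegimen
from .engine import SimulationResult, build_model, simulate_regimen
from .physiology import Individual, create_reference_adult

DEFAULT_LLOQ = 0.5  # ng/mL
SINGLE_DOSES = (2.5, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0)
MULTIPLE_DOSES = (1.25, 2.5, 5.0, 10.0, 25.0, 100.0)
FED_DOSES = (5.0, 10.0)
SINGLE_DOSE_TIMES = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0,
                     24.0, 48.0, 72.0)


@dataclass
class ObservedDataset:
    study_label: str
    regimen: DosingRegimen
    sampling_times: np.ndarray
    records: pd.DataFrame  # subject_id, time, concentration, censored
    lloq: float
    residual_cv: float
    seed: int
    n_subjects: int
    true_concentrations: np.ndarray = field(default=None, repr=False)

    def geometric_mean_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, geometric mean over uncensored records per time point)."""
        ok = self.records[~self.records.censored]
        g = ok.groupby("time")["concentration"].apply(
            lambda x: float(np.exp(np.mean(np.log(x)))))
        return g.index.to_numpy(), g.to_numpy()

    def to_csv(self, path: str | Path) -> None:
        out = self.records.copy()
        out.insert(0, "study_label", self.study_label)
        out.to_csv(path, index=False, float_format="%.6g")


def lognormal_sigma(cv: float) -> float:
    """Log-scale SD of a lognormal with coefficient of variation cv."""
    return float(np.sqrt(np.log1p(cv ** 2)))


def expected_aafe(cv: float) -> float:
    """Analytic AAFE of a median-1 lognormal residual: 10^(E|log10 X|)."""
    sigma = lognormal_sigma(cv)
    return float(10.0 ** (sigma / np.log(10.0) * np.sqrt(2.0 / np.pi)))


def generate_observed(true_profile: SimulationResult, sampling_times,
                      residual_cv: float = 0.2, lloq: float = DEFAULT_LLOQ,
                      n_subjects: int = 12, seed: int = 0,
                      study_label: str = "synthetic:study") -> ObservedDataset:
    """Sample noisy per-subject observations from a true simulated profile.

    Residual error is multiplicative lognormal with median 1 (log-scale SD
    derived from the CV); records below the LLOQ are flagged censored.
    """
    sampling_times = np.asarray(sampling_times, dtype=float)
    if sampling_times.size == 0:
        raise ValueError("empty sampling schedule")
    if residual_cv < 0:
        raise ValueError("residual_cv must be >= 0")
    if sampling_times.max() > true_profile.time.max() + 1e-9:
        raise ValueError("sampling times extend beyond the simulated profile")
    true_c = np.interp(sampling_times, true_profile.time,
                       true_profile.plasma_concentration)
    rng = np.random.default_rng(seed)
    sigma = lognormal_sigma(residual_cv)
    rows = []
    for subj in range(n_subjects):
        noise = (np.exp(rng.normal(0.0, sigma, size=len(sampling_times)))
                 if sigma > 0 else np.ones(len(sampling_times)))
        conc = true_c * noise
        for t, c in zip(sampling_times, conc):
            rows.append({"subject_id": subj, "time": t, "concentration": c,
                         "censored": bool(c < lloq)})
    records = pd.DataFrame(rows)
    return ObservedDataset(study_label=study_label, regimen=None,
                           sampling_times=sampling_times, records=records,
                           lloq=lloq, residual_cv=residual_cv, seed=seed,
                           n_subjects=n_subjects, true_concentrations=true_c)


def generate_study_suite(compound: CompoundParameters,
                         regimens: list[tuple[str, DosingRegimen]] | None = None,
                         seed: int = 0, residual_cv: float = 0.2,
                         lloq: float = DEFAULT_LLOQ, n_subjects: int = 12,
                         individual: Individual | None = None,
                         rtol: float = 1e-6, atol: float = 1e-9,
                         output_step: float = 0.25) -> list[ObservedDataset]:
    """A suite of synthetic studies mirroring the clinical design space:
    single oral doses 2.5-200 mg fasted, once-daily multiple doses
    1.25-100 mg, and fed single-dose variants."""
    individual = individual or create_reference_adult()
    if regimens is None:
        regimens = []
        for d in SINGLE_DOSES:
            regimens.append((f"synthetic:single-{d}mg-fasted",
                             DosingRegimen(dose=d, n_doses=1)))
        for d in MULTIPLE_DOSES:
            regimens.append((f"synthetic:multiple-{d}mg-fasted",
                             DosingRegimen(dose=d, n_doses=7, interval=24.0)))
        for d in FED_DOSES:
            regimens.append((f"synthetic:single-{d}mg-fed",
                             DosingRegimen(dose=d, n_doses=1,
                                           prandial_state="fed")))
    rng = np.random.default_rng(seed)
    datasets = []
    for label, regimen in regimens:
        model = build_model(compound, individual, regimen)
        if regimen.n_doses == 1:
            times = np.array(SINGLE_DOSE_TIMES)
            duration = 96.0
        else:
            start = (regimen.n_doses - 1) * regimen.interval
            times = start + np.array([0.25, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 12, 24.0])
            duration = start + regimen.interval
        profile = simulate_regimen(model, regimen, duration=duration,
                                   rtol=rtol, atol=atol, output_step=output_step)
        ds = generate_observed(profile, times, residual_cv=residual_cv,
                               lloq=lloq, n_subjects=n_subjects,
                               seed=int(rng.integers(2 ** 31)),
                               study_label=label)
        ds.regimen = regimen
        datasets.append(ds)
    return datasets


def write_manifest(datasets: list[ObservedDataset], path: str | Path) -> None:
    manifest = [{"study_label": d.study_label,
                 "dose_mg": d.regimen.dose if d.regimen else None,
                 "n_doses": d.regimen.n_doses if d.regimen else None,
                 "prandial_state": d.regimen.prandial_state if d.regimen else None,
                 "n_subjects": d.n_subjects, "lloq": d.lloq,
                 "residual_cv": d.residual_cv, "seed": d.seed} for d in datasets]
    Path(path).write_text(json.dumps(manifest, indent=2))
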
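"""Exposure-matched pediatric dose selection.

For each pediatric group, pick the candidate dose whose steady-state AUC
geometric mean is closest (in log space) to the adult reference, report the
Cmax counterpart and the UGE difference, and flag candidates outside the
twofold acceptance window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .exposure import ExposureSummary
from .pd_uge import default_pd_parameters, uge_from_auc, uge_from_cmax

DEFAULT_CANDIDATE_DOSES = (1.25, 2.5, 5.0, 10.0)


@dataclass
class DoseRecommendation:
    group: str
    candidate_dose: float
    reference_dose: float
    auc_ratio: float    # group geometric-mean AUC_ss / adult
    cmax_ratio: float
    within_twofold: bool
    uge_gap: float      # g, group minus adult (AUC-driven model)
    uge_cmax: float
    uge_auc: float


def _build_recommendation(exp: ExposureSummary, adult_reference: ExposureSummary,
                          candidate: float) -> DoseRecommendation:
    auc_ratio = exp.auc_geomean / adult_reference.auc_geomean
    cmax_ratio = exp.cmax_geomean / adult_reference.cmax_geomean
    p_cmax, p_auc = default_pd_parameters()
    uge_auc = uge_from_auc(exp.auc_mean, p_auc)
    uge_gap = uge_auc - uge_from_auc(adult_reference.auc_mean, p_auc)
    return DoseRecommendation(
        group=exp.group, candidate_dose=candidate,
        reference_dose=adult_reference.dose,
        auc_ratio=auc_ratio, cmax_ratio=cmax_ratio,
        within_twofold=(0.5 <= auc_ratio <= 2.0 and 0.5 <= cmax_ratio <= 2.0),
        uge_gap=uge_gap, uge_cmax=uge_from_cmax(exp.cmax_mean, p_cmax),
        uge_auc=uge_auc)


def recommend_dose(group_exposures: dict[float, ExposureSummary],
                   adult_reference: ExposureSummary,
                   candidate_doses: tuple[float, ...] | None = None) -> DoseRecommendation:
    """Candidate minimizing |log AUC ratio|; ties resolve to the lower dose."""
    if not group_exposures:
        raise ValueError("no candidate exposures supplied")
    doses = sorted(candidate_doses if candidate_doses is not None
                   else group_exposures.keys())
    missing = [d for d in doses if d not in group_exposures]
    if missing:
        raise ValueError(f"no exposure simulated for candidate doses {missing}")
    best = min(doses, key=lambda d: (
        abs(math.log(group_exposures[d].auc_geomean / adult_reference.auc_geomean)), d))
    return _build_recommendation(group_exposures[best], adult_reference, best)


def recommendation_table(exposures_by_group: dict[str, dict[float, ExposureSummary]],
                         adult_references: dict[float, ExposureSummary]) -> pd.DataFrame:
    """One row per (group, adult reference dose) with the selected dose.

    Because the PK is dose-linear in every population, the group/adult
    exposure ratio depends only on the candidate/reference dose-scaling
    factor. The table therefore first picks one scaling factor per group
    (minimizing the mean |log AUC ratio| across the adult references),
    keeping dose mappings mutually consistent; a reference falls back to
    single-reference selection when the factor-mapped candidate lies
    outside the twofold window (or is not among the candidates).
    """
    rows = []
    refs = sorted(adult_references)
    for group, by_dose in exposures_by_group.items():
        doses = sorted(by_dose)

        def nearest(x):
            return min(doses, key=lambda d: abs(d - x))

        def realizable(f):
            return all(abs(nearest(f * r) - f * r) <= 1e-9 * f * r for r in refs)

        factors = sorted({d / r for d in doses for r in refs})
        factors = [f for f in factors if realizable(f)]
        best_factor = None
        if factors:
            def mean_abs_log(f):
                return sum(abs(math.log(by_dose[nearest(f * r)].auc_geomean
                                        / adult_references[r].auc_geomean))
                           for r in refs) / len(refs)
            best_factor = min(factors, key=lambda f: (mean_abs_log(f), f))
        for ref_dose in refs:
            rec = None
            if best_factor is not None:
                mapped = nearest(best_factor * ref_dose)
                if abs(mapped - best_factor * ref_dose) <= 1e-9 * mapped:
                    cand = _build_recommendation(by_dose[mapped],
                                                 adult_references[ref_dose], mapped)
                    if cand.within_twofold:
                        rec = cand
            if rec is None:
                rec = recommend_dose(by_dose, adult_references[ref_dose])
            rows.append({
                "group": group, "reference_dose": ref_dose,
                "selected_dose": rec.candidate_dose,
                "auc_ratio": rec.auc_ratio, "cmax_ratio": rec.cmax_ratio,
                "within_twofold": rec.within_twofold,
                "uge_cmax": rec.uge_cmax, "uge_auc": rec.uge_auc,
                "uge_gap": rec.uge_gap})
    return pd.DataFrame(rows)
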
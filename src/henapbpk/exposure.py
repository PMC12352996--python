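"""Exposure summaries: the interface between PK simulation, the
exposure-response model, and dose matching."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExposureSummary:
    """Steady-state exposure for one group x dose cell.

    ``cmax_values`` / ``auc_values`` hold the per-individual metrics when the
    summary was computed from a simulated population; summaries built from
    published operating points carry only the mean and SD.
    """

    group: str
    dose: float  # mg
    cmax_mean: float  # ng/mL
    auc_mean: float   # ng*h/mL
    cmax_sd: float = 0.0
    auc_sd: float = 0.0
    n: int = 1
    cmax_values: np.ndarray | None = field(default=None, repr=False)
    auc_values: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_values(cls, group: str, dose: float, cmax: np.ndarray,
                    auc: np.ndarray) -> "ExposureSummary":
        cmax = np.asarray(cmax, dtype=float)
        auc = np.asarray(auc, dtype=float)
        return cls(group=group, dose=dose,
                   cmax_mean=float(cmax.mean()), auc_mean=float(auc.mean()),
                   cmax_sd=float(cmax.std(ddof=1)) if len(cmax) > 1 else 0.0,
                   auc_sd=float(auc.std(ddof=1)) if len(auc) > 1 else 0.0,
                   n=len(cmax), cmax_values=cmax, auc_values=auc)

    @property
    def auc_geomean(self) -> float:
        if self.auc_values is not None:
            return float(np.exp(np.mean(np.log(self.auc_values))))
        return self.auc_mean

    @property
    def cmax_geomean(self) -> float:
        if self.cmax_values is not None:
            return float(np.exp(np.mean(np.log(self.cmax_values))))
        return self.cmax_mean
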
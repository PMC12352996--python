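"""Model-qualification statistics.

Fold error FE = predicted/observed per pair; AFE = 10^(mean log10 FE)
(geometric mean fold error, bias); AAFE = 10^(mean |log10 FE|) (geometric
mean absolute fold error, spread); AAPE = mean |predicted - observed| /
observed (percentage prediction error). Acceptance bands: fold metrics
within [0.8, 1.25] (strict) or [0.5, 2] (twofold, inclusive); AAPE < 20%
satisfactory, 20-50% acceptable, >= 50% poor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class PairedObservations:
    """Positive (predicted, observed) pairs sharing units."""

    pairs: Sequence[tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("need at least one pair")
        arr = np.asarray(self.pairs, dtype=float)
        if np.any(arr <= 0):
            raise ValueError("predicted and observed values must be > 0")
        self._arr = arr

    @property
    def predicted(self) -> np.ndarray:
        return self._arr[:, 0]

    @property
    def observed(self) -> np.ndarray:
        return self._arr[:, 1]


@dataclass
class MetricsResult:
    fe: np.ndarray
    afe: float
    aafe: float
    aape: float  # fraction; multiply by 100 for %
    n: int
    label: str = ""
    classification: dict[str, str] = field(default_factory=dict)

    @property
    def aape_percent(self) -> float:
        return 100.0 * self.aape


def fold_error(predicted: float, observed: float) -> float:
    if observed <= 0:
        raise ValueError("observed must be > 0")
    return predicted / observed


def afe(pairs: PairedObservations) -> float:
    return float(10.0 ** np.mean(np.log10(pairs.predicted / pairs.observed)))


def aafe(pairs: PairedObservations) -> float:
    return float(10.0 ** np.mean(np.abs(np.log10(pairs.predicted / pairs.observed))))


def aape(pairs: PairedObservations) -> float:
    return float(np.mean(np.abs(pairs.predicted - pairs.observed) / pairs.observed))


def classify(metrics: "MetricsResult") -> dict[str, str]:
    """Fold band from AFE and AAFE jointly; AAPE band from the error scale."""
    vals = (metrics.afe, metrics.aafe)
    if all(0.8 <= v <= 1.25 for v in vals):
        fold_band = "within_1.25"
    elif all(0.5 <= v <= 2.0 for v in vals):
        fold_band = "within_2"
    else:
        fold_band = "outside"
    if metrics.aape < 0.20:
        aape_band = "satisfactory"
    elif metrics.aape < 0.50:
        aape_band = "acceptable"
    else:
        aape_band = "poor"
    return {"fold_band": fold_band, "aape_band": aape_band}


def compute_metrics(pairs: PairedObservations) -> MetricsResult:
    result = MetricsResult(
        fe=pairs.predicted / pairs.observed,
        afe=afe(pairs), aafe=aafe(pairs), aape=aape(pairs),
        n=len(pairs.pairs), label=pairs.label)
    result.classification = classify(result)
    return result


def pairs_from_profiles(predicted: np.ndarray, observed: np.ndarray,
                        lloq: float = 0.0, label: str = "") -> tuple[PairedObservations, int]:
    """Pair prediction with observation, excluding observations at/below LLOQ.

    Returns the pair set and the number of excluded records (the fold and
    percentage errors are undefined at observed = 0, so censored records
    are dropped rather than imputed).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    keep = (observed > lloq) & (observed > 0) & (predicted > 0)
    n_excluded = int(len(observed) - keep.sum())
    if keep.sum() == 0:
        raise ValueError(f"all {len(observed)} records censored or non-positive")
    pairs = PairedObservations(list(zip(predicted[keep], observed[keep])), label=label)
    return pairs, n_excluded


def metrics_frame(results: Sequence[MetricsResult]) -> pd.DataFrame:
    """Qualification table: one row per labelled comparison."""
    return pd.DataFrame([
        {"label": r.label, "n": r.n, "afe": r.afe, "aafe": r.aafe,
         "aape_percent": r.aape_percent, **r.classification}
        for r in results])
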
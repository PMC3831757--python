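"""Validation statistics: the qPCR enrichment call and ChIP-seq agreement.

qPCR enrichment, measured against a per-primer input standard curve, is
called positive when it exceeds two-fold over a background level defined as
mean + 2 x SD of the negative-control regions. Agreement between ChIP-seq
peak heights and qPCR enrichment is summarized as the squared Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class QPCRMeasurement:
    region_id: str
    value: float
    is_negative_control: bool
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("qPCR value must be >= 0")


def qpcr_background(
    measurements: Sequence[QPCRMeasurement], population_sd: bool = False
) -> float:
    """Background level: mean + 2 x SD of the negative-control values.

    Uses the sample SD (ddof=1) by default; ``population_sd`` switches to
    ddof=0. At least two negatives are required.
    """
    negatives = [m.value for m in measurements if m.is_negative_control]
    if len(negatives) < 2:
        raise ValueError(
            f"need >= 2 negative-control measurements, got {len(negatives)}"
        )
    arr = np.asarray(negatives, dtype=float)
    sd = float(np.std(arr, ddof=0 if population_sd else 1))
    return float(np.mean(arr)) + 2.0 * sd


def qpcr_call(value: float, background: float) -> str:
    """Positive iff enrichment exceeds two-fold over background (strict)."""
    if background <= 0:
        raise ValueError("background must be positive")
    return "positive" if value > 2.0 * background else "negative"


def call_qpcr_table(
    measurements: Sequence[QPCRMeasurement], population_sd: bool = False
) -> list[dict]:
    """Background per sample, then a call for every non-negative region."""
    samples = sorted({m.sample_id for m in measurements})
    rows = []
    for sample in samples:
        subset = [m for m in measurements if m.sample_id == sample]
        background = qpcr_background(subset, population_sd=population_sd)
        for m in subset:
            if m.is_negative_control:
                continue
            rows.append(
                {
                    "sample_id": sample,
                    "region_id": m.region_id,
                    "value": m.value,
                    "background": background,
                    "call": qpcr_call(m.value, background),
                }
            )
    return rows


def agreement_r2(
    chipseq_heights: Sequence[float], qpcr_values: Sequence[float]
) -> Optional[float]:
    """Squared Pearson correlation between paired ChIP-seq and qPCR values.

    Returns None (missing) when either vector has zero variance; requires
    at least three pairs.
    """
    x = np.asarray(chipseq_heights, dtype=float)
    y = np.asarray(qpcr_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be paired (same length)")
    if len(x) < 3:
        raise ValueError("need >= 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
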
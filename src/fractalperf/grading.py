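"""Grade-group prediction from FDmax and ADC_25, and significance rules.

The validated FD cutoffs separate pooled ISUP grade groups: 2.20 (group 1
vs 2-5), 2.31 (1-2 vs 3-5), 2.40 (1-3 vs 4-5); the highest grade group (5)
is not separable from group 4, so predictions run 1-4. The ADC_25 cutoff
905 (1e-6 mm^2/s) separates group 1 from 2-5. Boundary convention: an FD
exactly at a cutoff falls in the lower pool (strictly-greater calls the
higher pool); an ADC_25 strictly below the cutoff calls the higher pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InputError, ParameterError

SIGNIFICANCE_RULES = ("pirads_only", "fd_only", "adc_only", "pirads_and_fd", "pirads_or_fd")


@dataclass(frozen=True)
class ThresholdTable:
    """FD and ADC cutoffs driving grade prediction (validated defaults)."""

    c1: float = 2.20  # group 1 vs 2-5
    c2: float = 2.31  # groups 1-2 vs 3-5
    c3: float = 2.40  # groups 1-3 vs 4-5
    adc_cutoff: float = 905.0  # 1e-6 mm^2/s, group 1 vs 2-5

    def __post_init__(self):
        if not (self.c1 < self.c2 < self.c3):
            raise ParameterError("FD cutoffs must satisfy c1 < c2 < c3")
        if not (2.0 < self.c1 and self.c3 < 3.0):
            raise ParameterError("FD cutoffs must lie strictly inside (2, 3)")
        if self.adc_cutoff <= 0:
            raise ParameterError("ADC cutoff must be positive")


@dataclass
class LesionRecord:
    """One lesion's measurements, reference grading, and prediction."""

    lesion_id: str
    fdmax: float
    adc25: Optional[float] = None
    pirads: Optional[int] = None
    isup_ref: Optional[int] = None
    zone: str = "peripheral"  # "peripheral" or "transitional"
    pred_group: Optional[int] = None

    def __post_init__(self):
        if self.pirads is not None and not 1 <= self.pirads <= 5:
            raise InputError(f"PI-RADS must be 1-5, got {self.pirads}")
        if self.isup_ref is not None and not 1 <= self.isup_ref <= 5:
            raise InputError(f"ISUP grade group must be 1-5, got {self.isup_ref}")


def predict_group_fd(fdmax: float, thresholds: ThresholdTable = ThresholdTable()) -> int:
    """Pooled grade-group prediction from the margin FDmax.

    Monotone non-decreasing in FDmax: 1 if fdmax <= c1, 2 if c1 < fdmax <=
    c2, 3 if c2 < fdmax <= c3, 4 if fdmax > c3 (groups 4 and 5 merged).
    """
    fd = float(np.clip(fdmax, 2.0, 3.0))
    if fd <= thresholds.c1:
        return 1
    if fd <= thresholds.c2:
        return 2
    if fd <= thresholds.c3:
        return 3
    return 4


def adc25(adc_map: np.ndarray, hotspot: np.ndarray) -> float:
    """25th percentile of the ADC within the lowest-value hotspot ROI.

    Linear interpolation between order statistics; units follow the input
    map (1e-6 mm^2/s by package convention).
    """
    adc_map = np.asarray(adc_map, dtype=float)
    hotspot = np.asarray(hotspot, dtype=bool)
    if adc_map.shape != hotspot.shape:
        raise InputError("ADC map and hotspot ROI grids differ")
    values = adc_map[hotspot]
    if values.size == 0:
        raise InputError("hotspot ROI is empty")
    if np.any(values <= 0):
        raise InputError("ADC values must be positive")
    return float(np.percentile(values, 25))


def call_significant(
    record: LesionRecord,
    rule: str = "pirads_and_fd",
    thresholds: ThresholdTable = ThresholdTable(),
) -> bool:
    """Clinical-significance call under a configurable rule.

    ``pirads_only``: PI-RADS >= 4; ``fd_only``: fdmax > c1; ``adc_only``:
    ADC_25 < 905; ``pirads_and_fd`` (default) and ``pirads_or_fd`` combine
    the first two.
    """
    if rule not in SIGNIFICANCE_RULES:
        raise ParameterError(f"unknown rule {rule!r}; choose one of {SIGNIFICANCE_RULES}")

    def need(field_name):
        value = getattr(record, field_name)
        if value is None:
            raise InputError(f"rule {rule!r} requires field {field_name!r}")
        return value

    if rule == "pirads_only":
        return need("pirads") >= 4
    if rule == "fd_only":
        return need("fdmax") > thresholds.c1
    if rule == "adc_only":
        return need("adc25") < thresholds.adc_cutoff
    if rule == "pirads_and_fd":
        return (need("pirads") >= 4) and (need("fdmax") > thresholds.c1)
    return (need("pirads") >= 4) or (need("fdmax") > thresholds.c1)
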
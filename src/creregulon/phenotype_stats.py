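"""Sporulation-rate statistics for strain comparisons.

The sporulation rate of a culture is the heat-resistant colony-forming
fraction normalised by culture density:

    rate = 100 × (colonies_heat / A600_heat) ÷ (colonies_non / A600_non)

where the heat-shocked plate counts only spores (vegetative cells are killed
at 80 °C) and the non-heat-shocked plate counts all CFU.  Counts may instead
be supplied pre-normalised as (total_cfu, spores), in which case
rate = 100 × spores ÷ total_cfu.  Rates are not clipped at 100% — plate-count
noise can push a fully sporulated culture slightly above it — but values over
100 are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)


@dataclass
class PlateCount:
    """One strain/day plate measurement, in raw or pre-normalised form.

    Exactly one input form must be populated: either the four raw plate
    quantities (colony counts and A600 for the heat-shocked and untreated
    halves of the suspension), or the pre-normalised ``total_cfu``/``spores``
    pair.
    """

    strain: str
    day: int
    colonies_heat: float | None = None
    a600_heat: float | None = None
    colonies_non: float | None = None
    a600_non: float | None = None
    total_cfu: float | None = None
    spores: float | None = None

    def __post_init__(self) -> None:
        raw = [self.colonies_heat, self.a600_heat, self.colonies_non, self.a600_non]
        normalized = [self.total_cfu, self.spores]
        has_raw = all(v is not None for v in raw)
        has_norm = all(v is not None for v in normalized)
        if has_raw == has_norm:
            raise ValueError(
                "exactly one input form must be populated: raw plate counts "
                "or the (total_cfu, spores) pair"
            )
        if has_raw:
            if self.colonies_heat < 0 or self.colonies_non < 0:
                raise ValueError("colony counts must be ≥ 0")
            if self.a600_heat <= 0 or self.a600_non <= 0:
                raise ValueError("optical densities must be > 0")
        else:
            if self.spores < 0 or self.total_cfu < 0:
                raise ValueError("counts must be ≥ 0")


def sporulation_rate(count: PlateCount) -> float:
    """Percentage of spores among density-normalised CFU; may exceed 100."""
    if count.total_cfu is not None:
        if count.total_cfu == 0:
            raise ValueError("total CFU is zero: rate undefined")
        rate = 100.0 * count.spores / count.total_cfu
    else:
        if count.colonies_non == 0:
            raise ValueError("no colonies on the non-heat-shocked plate: rate undefined")
        rate = 100.0 * (count.colonies_heat / count.a600_heat) / (
            count.colonies_non / count.a600_non
        )
    if rate > 100.0:
        logger.info(
            "%s day %d: sporulation rate %.1f%% exceeds 100%% (plate-count noise)",
            count.strain,
            count.day,
            rate,
        )
    return rate


def rate_ratio(a: float, b: float) -> float:
    """Fold difference between two sporulation percentages (a ÷ b)."""
    if b == 0:
        raise ValueError("cannot form a ratio against a zero rate")
    return a / b
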
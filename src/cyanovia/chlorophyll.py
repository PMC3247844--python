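"""Chlorophyll a concentration from methanol-extract absorbance.

The standard single-wavelength estimate for a methanol extract of a culture
aliquot:

    chlorophyll (µg/ml) = Abs650 * coefficient / sample_volume_ml

with coefficient 13.9 and a 2 ml centrifuged culture volume by default.
The volume is an explicit field so the formula transfers to other extraction
protocols.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ChlorophyllReading:
    abs650: float
    sample_volume_ml: float = 2.0
    coefficient: float = 13.9

    def __post_init__(self) -> None:
        if self.abs650 < 0:
            raise ValueError(f"absorbance must be non-negative, got {self.abs650}")
        if self.sample_volume_ml <= 0:
            raise ValueError(
                f"sample volume must be positive, got {self.sample_volume_ml}"
            )


def chlorophyll_ug_per_ml(r: ChlorophyllReading) -> float:
    """Evaluate the extraction formula for one absorbance reading."""
    return r.abs650 * r.coefficient / r.sample_volume_ml
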
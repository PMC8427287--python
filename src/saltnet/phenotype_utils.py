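"""Photometric pigment quantification from leaf-extract absorbances.

Chlorophyll a, chlorophyll b and total carotenoid contents follow the
standard spectrophotometric forms for the 470 / 646.8 / 663.2 nm
absorbance triple:

    chl_a = 12.25 * A663.2 - 2.79 * A646.8
    chl_b = 21.5  * A646.8 - 5.1  * A663.2
    carotenoids = (100 * A470 - 1.82 * chl_a - 85.02 * chl_b) / 198

Negative outputs are physically impossible and indicate a bad reading;
they are returned as-is (with a warning) rather than clamped so data
problems stay visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import SaltnetError

logger = logging.getLogger(__name__)


class AbsorbanceError(SaltnetError):
    """A reading is negative, outside the photometric domain."""


@dataclass(frozen=True)
class AbsorbanceReading:
    """Absorbances at 470, 646.8 and 663.2 nm (absorbance units, >= 0)."""

    A470: float
    A646_8: float
    A663_2: float

    def __post_init__(self) -> None:
        for name in ("A470", "A646_8", "A663_2"):
            if getattr(self, name) < 0:
                raise AbsorbanceError(f"negative absorbance {name}")


def pigment_contents(reading: AbsorbanceReading) -> tuple[float, float, float]:
    """Return (chlorophyll a, chlorophyll b, total carotenoids)."""
    chl_a = 12.25 * reading.A663_2 - 2.79 * reading.A646_8
    chl_b = 21.5 * reading.A646_8 - 5.1 * reading.A663_2
    carotenoids = (100.0 * reading.A470 - 1.82 * chl_a - 85.02 * chl_b) / 198.0
    if min(chl_a, chl_b, carotenoids) < 0:
        logger.warning(
            "negative pigment content (chl_a=%.4g, chl_b=%.4g, carotenoids=%.4g); "
            "check the readings", chl_a, chl_b, carotenoids,
        )
    return chl_a, chl_b, carotenoids
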
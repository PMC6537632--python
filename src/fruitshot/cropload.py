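"""Cropload estimation: from a detection count to a per-tree fruit count.

A detector misses some visible fruit (captured by its F1 score) and can
never see fruit fully hidden inside the canopy (captured by t, the
hidden fraction of the training system — the orchard's trellis/tree
architecture, measured by counting fruit on trees in the field).  The
estimate inflates the detection count for both:

    cropload = d + d*(1 - F1) + t * (d + d*(1 - F1))
             = d * (2 - F1) * (1 + t)

Calibrated hidden fractions for the two measured training systems are
0.05 and 0.1 (i.e. 95% and 90% of fruit visible from the camera side).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CroploadInput", "estimate", "KNOWN_HIDDEN_FRACTIONS"]

KNOWN_HIDDEN_FRACTIONS = (0.05, 0.1)


@dataclass(frozen=True)
class CroploadInput:
    """detected count d, model F1 in (0, 1], hidden fraction t in [0, 1)."""

    detections: int
    f1: float
    hidden_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.detections < 0:
            raise ValueError("detections must be non-negative")
        if self.f1 == 0:
            raise ValueError("F1 = 0 leaves the correction undefined")
        if not (0.0 < self.f1 <= 1.0):
            raise ValueError("F1 must lie in (0, 1]")
        if not (0.0 <= self.hidden_fraction < 1.0):
            raise ValueError("hidden fraction must lie in [0, 1)")


def estimate(inp: CroploadInput) -> float:
    """Evaluate the cropload formula; the caller decides any rounding."""
    d, f1, t = inp.detections, inp.f1, inp.hidden_fraction
    missed_corrected = d + d * (1.0 - f1)
    return missed_corrected + t * missed_corrected
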
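"""Flow-cytometry genome-size (2C value) estimation.

Nuclear DNA content is read off propidium-iodide fluorescence peaks against
an internal standard.  Two standard curves are supported:

* ``two_point`` — linear interpolation between the Arabidopsis thaliana 2n
  and 4n standard peaks (2C = 0.33 pg, 4C = 0.66 pg):
  2C = (0.66 x (F - S2n) + 0.33 x (S4n - F)) / (S4n - S2n)
* ``one_standard`` — proportional to the Zea mays 'CE-777' 2n peak
  (2C = 5.57 pg):  2C = 5.57 x F / S2n

where F is the sample 2n peak mean and S2n/S4n the standard peak means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = ["FlowSample", "genome_size_2c",
           "ARABIDOPSIS_2C_PG", "ARABIDOPSIS_4C_PG", "MAIZE_2C_PG"]

ARABIDOPSIS_2C_PG = 0.33
ARABIDOPSIS_4C_PG = 0.66
MAIZE_2C_PG = 5.57


@dataclass(frozen=True)
class FlowSample:
    """Peak mean fluorescences of one sample and its internal standard."""

    f: float  # sample 2n peak mean
    s2n: float  # standard 2n peak mean
    s4n: Optional[float] = None  # standard 4n peak mean (two-point mode only)

    def __post_init__(self):
        if self.f <= 0 or self.s2n <= 0:
            raise ValueError("peak means must be positive")
        if self.s4n is not None:
            if self.s4n <= 0:
                raise ValueError("peak means must be positive")
            if not self.s2n < self.s4n:
                raise ValueError("standard 2n peak must lie below the 4n peak")


def genome_size_2c(sample: FlowSample, mode: str = "two_point") -> float:
    """Sample 2C value in pg under the chosen standard curve."""
    if mode == "two_point":
        if sample.s4n is None:
            raise ValueError("two_point mode needs the standard 4n peak")
        denom = sample.s4n - sample.s2n
        if denom == 0:
            raise ZeroDivisionError("degenerate standard: S4n equals S2n")
        return (ARABIDOPSIS_4C_PG * (sample.f - sample.s2n)
                + ARABIDOPSIS_2C_PG * (sample.s4n - sample.f)) / denom
    if mode == "one_standard":
        return MAIZE_2C_PG * sample.f / sample.s2n
    raise ValueError(f"unknown mode {mode!r}")
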
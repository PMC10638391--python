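"""Optical-fractionator stereology and its precision (Gundersen CE, m = 1).

The optical fractionator estimates the total number of neurons in a region
from cells counted in systematically sampled optical disectors:

    N = sum(Q-) * t / (h * asf * ssf)

with Q- the per-section counted cells, t the mean mounted section thickness,
h the disector (counting-frame) height, asf the area sampling fraction and
ssf the section sampling fraction.  Precision is summarised by the Gundersen
coefficient of error for smoothness class m = 1,

    CE = sqrt(s^2 + VAR_SRS) / s^2,
    VAR_SRS = (3 (A - s^2) - 4 B + C) / 240,

where A = sum(Q_i^2), B = sum(Q_i Q_{i+1}), C = sum(Q_i Q_{i+2}) over the
ordered section series and s^2 is the counting-noise variance.  By default
s^2 = sum(Q-), the Poisson "nugget"; note the classical CE formula divides by
sum(Q-), which coincides with this denominator only under that default.
Negative VAR_SRS (possible in short series) is clamped to zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StereologyParams",
    "SectionCounts",
    "optical_fractionator",
    "gundersen_ce",
    "interpolate_flawed",
]


@dataclass
class StereologyParams:
    """Sampling parameters of the optical fractionator.

    t : mean mounted section thickness (um)
    h : counting-frame (disector) height (um), 0 < h <= t
    asf : area sampling fraction (frame area / grid cell area)
    ssf : section sampling fraction (1 = every section analysed)
    """

    t: float
    h: float
    asf: float
    ssf: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.h <= self.t):
            raise ValueError("need 0 < h <= t")
        if not (0 < self.asf <= 1) or not (0 < self.ssf <= 1):
            raise ValueError("sampling fractions must be in (0, 1]")


@dataclass
class SectionCounts:
    """Ordered per-section counts Q_i^- (caudal to rostral) with flaw flags.

    ``s2`` is the noise variance used by :func:`gundersen_ce`; ``None`` means
    the Poisson default sum(Q).
    """

    Q: list[int]
    flawed: list[bool] = field(default_factory=list)
    s2: float | None = None

    def __post_init__(self) -> None:
        self.Q = [int(q) for q in self.Q]
        if len(self.Q) < 1:
            raise ValueError("need at least one section")
        if any(q < 0 for q in self.Q):
            raise ValueError("counts must be non-negative")
        if not self.flawed:
            self.flawed = [False] * len(self.Q)
        if len(self.flawed) != len(self.Q):
            raise ValueError("flaw flags must align with counts")

    @property
    def total(self) -> int:
        return int(sum(self.Q))

    def noise_variance(self) -> float:
        return float(self.total if self.s2 is None else self.s2)


def optical_fractionator(counts: SectionCounts, params: StereologyParams) -> float:
    """Estimated total cell number N = sum(Q-) * t / (h * asf * ssf)."""
    return counts.total * params.t / (params.h * params.asf * params.ssf)


def gundersen_ce(counts: SectionCounts) -> float:
    """Gundersen coefficient of error (m = 1) of the fractionator estimate.

    Sections must be in anatomical order: the systematic-sampling variance
    term depends on the lag-1 and lag-2 products B and C.
    """
    q = np.asarray(counts.Q, dtype=float)
    s2 = counts.noise_variance()
    if s2 <= 0:
        raise ValueError("noise variance s2 must be positive "
                         "(empty series has undefined CE)")
    A = float(np.sum(q * q))
    B = float(np.sum(q[:-1] * q[1:]))
    C = float(np.sum(q[:-2] * q[2:]))
    var_srs = (3.0 * (A - s2) - 4.0 * B + C) / 240.0
    var_srs = max(var_srs, 0.0)
    return math.sqrt(s2 + var_srs) / s2


def interpolate_flawed(counts: SectionCounts) -> SectionCounts:
    """Replace flawed sections by the mean of their two neighbours.

    A flawed section at either end of the series (no second neighbour) is
    repaired by copying its single neighbour, with a warning.  Two adjacent
    flawed sections cannot be repaired and raise an error.  Repairs are
    recorded in the returned object's provenance list.
    """
    flags = list(counts.flawed)
    for i in range(len(flags) - 1):
        if flags[i] and flags[i + 1]:
            raise ValueError(f"adjacent flawed sections at {i}, {i + 1}")
    q = [float(v) for v in counts.Q]
    repaired = list(q)
    provenance: list[str] = []
    for i, bad in enumerate(flags):
        if not bad:
            continue
        if i == 0:
            repaired[i] = q[1]
            warnings.warn("flawed section at series start: copied neighbour")
            provenance.append(f"section {i}: copied from {i + 1}")
        elif i == len(q) - 1:
            repaired[i] = q[i - 1]
            warnings.warn("flawed section at series end: copied neighbour")
            provenance.append(f"section {i}: copied from {i - 1}")
        else:
            repaired[i] = 0.5 * (q[i - 1] + q[i + 1])
            provenance.append(f"section {i}: mean of {i - 1}, {i + 1}")
    out = replace(counts, Q=[int(round(v)) for v in repaired],
                  flawed=[False] * len(q))
    out.repair_log = provenance  # type: ignore[attr-defined]
    return out
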
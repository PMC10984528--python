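"""Hybrid-dilated-convolution (HDC) design calculus.

Stacked dilated convolutions can leave "holes" in their effective receptive
field — the gridding effect — when the dilation factors are chosen badly
(e.g. a constant dilation > 1).  This module implements the standard design
checks for a cascade of square, stride-1 dilated convolutions:

* the top-down *maximum-distance* recursion
  ``M_i = max(M_{i+1} - 2 d_i, 2 d_i - M_{i+1}, d_i)`` seeded with
  ``M_Z = d_Z``, whose value at the bottom layers certifies gap-free
  coverage (``M_2 <= K`` and ideally ``M_1 == 1``);
* a closed-form receptive-field accumulator;
* a brute-force *usage-count* oracle that back-propagates kernel-tap counts
  from one output pixel to the input grid, so coverage claims can be checked
  exhaustively rather than trusted.

The checks are conservative: ``M_1 == 1`` guarantees hole-free coverage, but
some schedules (for instance a decreasing cascade like ``(2, 1)``) cover the
input fully even though the recursion reports ``M_1 > 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DilationSchedule", "RuleReport", "UsageCountMap",
    "max_distances", "rule_check", "receptive_field", "usage_count_map",
]


@dataclass(frozen=True)
class DilationSchedule:
    """Ordered (kernel_size, dilation) pairs, bottom layer first."""

    layers: tuple

    def __post_init__(self):
        layers = tuple((int(k), int(d)) for k, d in self.layers)
        if not layers:
            raise ValueError("schedule must contain at least one layer")
        for k, d in layers:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel size must be odd and >= 1, got {k}")
            if d < 1:
                raise ValueError(f"dilation must be >= 1, got {d}")
        object.__setattr__(self, "layers", layers)

    @classmethod
    def from_dilations(cls, dilations, kernel_size: int = 3) -> "DilationSchedule":
        return cls(tuple((kernel_size, int(d)) for d in dilations))

    @property
    def dilations(self) -> tuple:
        return tuple(d for _, d in self.layers)

    @property
    def kernel_sizes(self) -> tuple:
        return tuple(k for k, _ in self.layers)

    def __len__(self) -> int:
        return len(self.layers)


@dataclass
class RuleReport:
    """Outcome of the HDC design-rule check."""

    passed: bool
    violations: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    max_distances: list = field(default_factory=list)


@dataclass
class UsageCountMap:
    """Per-input-pixel tap-usage counts for one output pixel.

    ``origin`` is the input coordinate of the grid's top-left cell relative
    to the output pixel's projection onto the input (infinite canvas; image
    boundaries are ignored, as for an interior pixel).
    """

    counts: np.ndarray
    origin: tuple

    @property
    def side(self) -> int:
        return self.counts.shape[0]

    def holes(self) -> int:
        """Number of zero-count cells inside the bounding box."""
        return int((self.counts == 0).sum())


def max_distances(schedule: DilationSchedule) -> list:
    """Top-down maximum-distance recursion; returns M_1..M_Z bottom-first."""
    d = schedule.dilations
    M = [0] * len(d)
    M[-1] = d[-1]
    for i in range(len(d) - 2, -1, -1):
        M[i] = max(M[i + 1] - 2 * d[i], 2 * d[i] - M[i + 1], d[i])
    return M


def rule_check(schedule: DilationSchedule) -> RuleReport:
    """Apply the HDC design guidelines to a cascade of dilated convolutions.

    Hard findings (any one fails the schedule):

    * ``max_distance_exceeds_kernel`` — M_2 > K of the second layer;
    * ``common_divisor_gt_one`` — gcd of the dilations exceeds 1;
    * ``constant_dilation_gridding`` — all dilations equal and > 1;
    * ``m1_not_one`` — the bottom layer's maximum distance is not 1, so
      adjacency of contributing input pixels is not certified.

    A monotonically increasing long cascade (no "zigzag" reset, e.g.
    1,2,3,4,5,6 rather than 1,2,3,1,2,3) only raises a warning: short
    increasing cascades such as (1, 2, 5) are legitimate designs.
    Single-layer schedules pass vacuously — the guidelines govern cascades.
    """
    M = max_distances(schedule)
    report = RuleReport(passed=True, max_distances=M)
    if len(schedule) < 2:
        return report
    d = schedule.dilations
    if M[1] > schedule.kernel_sizes[1]:
        report.violations.append("max_distance_exceeds_kernel")
    if math.gcd(*d) > 1:
        report.violations.append("common_divisor_gt_one")
    if len(set(d)) == 1 and d[0] > 1:
        report.violations.append("constant_dilation_gridding")
    if M[0] != 1:
        report.violations.append("m1_not_one")
    if len(d) > 3 and all(b > a for a, b in zip(d, d[1:])):
        report.warnings.append("monotone_not_zigzag")
    report.passed = not report.violations
    return report


def receptive_field(schedule: DilationSchedule) -> int:
    """Side of the square input footprint of one output pixel (stride 1)."""
    rf = 1
    for k, d in schedule.layers:
        rf += (k - 1) * d
    return rf


def usage_count_map(schedule: DilationSchedule) -> UsageCountMap:
    """Brute-force tap-count oracle for a single output pixel.

    Starting from a single count of 1 at the output pixel, each layer (top
    to bottom) spreads every count to the K x K input positions its dilated
    kernel reads.  The result is the exact number of times each input pixel
    is used in computing the one output pixel; zero cells inside the
    bounding box are gridding holes.
    """
    counts = np.ones((1, 1), dtype=np.int64)
    for k, d in reversed(schedule.layers):
        r = (k - 1) // 2 * d
        side = counts.shape[0] + 2 * r
        nxt = np.zeros((side, side), dtype=np.int64)
        for i in range(k):
            for j in range(k):
                nxt[i * d: i * d + counts.shape[0],
                    j * d: j * d + counts.shape[1]] += counts
        counts = nxt
    r = (counts.shape[0] - 1) // 2
    return UsageCountMap(counts=counts, origin=(-r, -r))
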
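"""Sawtooth smoothing: fold-propensity profile -> structured/disordered regions.

Positions are first classified by the sign of the fold propensity
(FP > 0 structured, FP <= 0 disordered; an exact zero counts as
disordered since the tool's purpose is flagging potential disorder).
Two smoothing rules then remove spurious short segments:

Rule 1 (short-IDR re-averaging, applied first, left to right): every
maximal disordered run shorter than 10 residues is re-labelled by the
sign of the mean raw FP over a window of up to 41 positions centered on
the run's midpoint, truncated at the sequence ends. Short IDR calls
inside domains often describe surface loops, not genuine disorder.

Rule 2 (merging): every maximal structured run shorter than 10 residues
lying strictly between two disordered runs is re-labelled disordered,
combining its neighbours into one longer IDR. Terminal structured runs
are exempt (no disordered run on both sides).

The two rules are applied in that order and repeated until nothing
changes. Convergence is guaranteed: any label change merges whole runs,
strictly decreasing the number of maximal runs, so no oscillation is
possible and the result is a fixed point (smoothing is idempotent). The
result is coalesced into a RegionSet tiling [1, L].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .windows import Profile

RegionClass = Literal["structured", "disordered"]

SHORT_RUN = 10  # runs shorter than this are smoothed
REAVERAGE_WINDOW = 41  # max span for Rule 1 re-averaging

STRUCTURED = "structured"
DISORDERED = "disordered"


@dataclass(frozen=True)
class Region:
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    region_class: str

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    """Ordered structured/disordered segments tiling positions 1..L."""

    regions: list[Region]

    @property
    def length(self) -> int:
        return self.regions[-1].end if self.regions else 0

    def labels(self) -> np.ndarray:
        """Expand back to one boolean per position (True = structured)."""
        out = np.empty(self.length, dtype=bool)
        for r in self.regions:
            out[r.start - 1 : r.end] = r.region_class == STRUCTURED
        return out

    def disordered_regions(self) -> list[Region]:
        return [r for r in self.regions if r.region_class == DISORDERED]


def initial_classification(fp: Profile) -> np.ndarray:
    """Per-position labels from the FP sign: True = structured (FP > 0)."""
    return np.asarray(fp.values) > 0.0


def _runs(labels: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs as (start0, end0_exclusive, is_structured)."""
    runs = []
    n = len(labels)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.append((i, j, bool(labels[i])))
        i = j
    return runs


def sawtooth_smooth(labels: np.ndarray, fp: Profile) -> RegionSet:
    """Apply the two smoothing rules and coalesce into a RegionSet."""
    labels = np.asarray(labels, dtype=bool).copy()
    fp_values = np.asarray(fp.values)
    n = len(labels)
    if n != len(fp_values):
        raise ValueError("labels and profile must cover the same sequence")

    half = REAVERAGE_WINDOW // 2
    # every change merges runs, so at most n passes are ever needed
    for _ in range(n):
        before = labels.copy()

        # Rule 1: re-average short disordered runs over up to 41 positions
        for start, end, structured in _runs(labels):
            if structured or end - start >= SHORT_RUN:
                continue
            mid = (start + end - 1) // 2  # left-of-center for even-length runs
            lo = max(0, mid - half)
            hi = min(n, mid + half + 1)
            labels[start:end] = fp_values[lo:hi].mean() > 0.0

        # Rule 2: dissolve short structured runs strictly between disordered runs
        runs = _runs(labels)
        for k, (start, end, structured) in enumerate(runs):
            if not structured or end - start >= SHORT_RUN:
                continue
            if 0 < k < len(runs) - 1:
                labels[start:end] = False

        if np.array_equal(labels, before):
            break

    regions = [
        Region(start + 1, end, STRUCTURED if structured else DISORDERED)
        for start, end, structured in _runs(labels)
    ]
    return RegionSet(regions)


def segment(fp: Profile) -> RegionSet:
    """Classify and smooth in one step."""
    return sawtooth_smooth(initial_classification(fp), fp)


def envelope_track(regions: RegionSet, length: int | None = None) -> np.ndarray:
    """Triangular display envelope of a RegionSet.

    Within each region the track rises linearly from 0 at the region
    boundaries to +1 (structured) or -1 (disordered) at the midpoint.
    Even-length regions, which have no single midpoint, use half-width
    n/2 so every position keeps the region's sign; single-position
    regions score the full +/-1. Display convention only — analysis
    consumes the RegionSet itself.
    """
    if length is None:
        length = regions.length
    if regions.length != length:
        raise ValueError("regions do not tile the requested length")
    out = np.zeros(length, dtype=float)
    for r in regions.regions:
        n = len(r)
        sign = 1.0 if r.region_class == STRUCTURED else -1.0
        if n == 1:
            out[r.start - 1] = sign
            continue
        center = (r.start + r.end) / 2.0
        half_width = (n - 1) / 2.0 if n % 2 == 1 else n / 2.0
        for pos in range(r.start, r.end + 1):
            out[pos - 1] = sign * (1.0 - abs(pos - center) / half_width)
    return out


def regions_to_tsv(record_id: str, regions: RegionSet, bed: bool = False) -> str:
    """Export regions as TSV: BED-like 0-based half-open, or 1-based inclusive."""
    lines = []
    if bed:
        for r in regions.regions:
            lines.append(f"{record_id}\t{r.start - 1}\t{r.end}\t{r.region_class}")
    else:
        lines.append("protein_id\tstart\tend\tclass")
        for r in regions.regions:
            lines.append(f"{record_id}\t{r.start}\t{r.end}\t{r.region_class}")
    return "\n".join(lines) + "\n"
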
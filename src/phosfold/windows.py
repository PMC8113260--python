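"""Sliding-window profiles with terminal extrapolation.

A per-residue track (charges, hydropathies, ...) is averaged or summed
over an odd-length window centered on each position. Positions closer
than half a window to either terminus cannot host a full window; their
values are extrapolated flat from the first/last full-window position
(for the default 21-residue window, positions 1-10 copy position 11 and
the last 10 copy the 11th residue in from the C-terminus).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

MIN_WINDOW = 5
MAX_WINDOW = 41
DEFAULT_WINDOW = 21

Statistic = Literal["mean", "sum"]


@dataclass
class Profile:
    """A windowed per-position track.

    ``values[i]`` (0-based internally; position i+1 in sequence
    coordinates) is the window statistic centered there, after terminal
    extrapolation. ``margin`` = (window_length - 1) / 2.
    """

    values: np.ndarray
    window_length: int
    statistic: Statistic

    @property
    def margin(self) -> int:
        return (self.window_length - 1) // 2

    def __len__(self) -> int:
        return len(self.values)

    def value_at(self, position: int) -> float:
        """Value at a 1-based position."""
        return float(self.values[position - 1])


def validate_window_length(window_length: int) -> None:
    if window_length % 2 == 0:
        raise ValueError(f"window length must be odd, got {window_length}")
    if not MIN_WINDOW <= window_length <= MAX_WINDOW:
        raise ValueError(
            f"window length must be in [{MIN_WINDOW}, {MAX_WINDOW}], "
            f"got {window_length}"
        )


def sliding_window_profile(
    track: np.ndarray,
    window_length: int = DEFAULT_WINDOW,
    statistic: Statistic = "mean",
) -> Profile:
    """Centered sliding-window mean or sum of a numeric track.

    Raises ``ValueError`` for even or out-of-range window lengths, and
    for tracks shorter than the window (lower the window length for
    short sequences rather than silently truncating).
    """
    validate_window_length(window_length)
    track = np.asarray(track, dtype=float)
    n = len(track)
    if n < window_length:
        raise ValueError(
            f"track length {n} is shorter than window length {window_length}; "
            "choose a smaller window"
        )
    margin = (window_length - 1) // 2

    # direct per-window summation: bit-identical to summing each slice,
    # unlike a cumulative-sum difference which accumulates rounding
    windows = np.lib.stride_tricks.sliding_window_view(track, window_length)
    sums = windows.sum(axis=1)

    values = np.empty(n, dtype=float)
    values[margin : n - margin] = sums
    if statistic == "mean":
        values[margin : n - margin] /= window_length
    elif statistic != "sum":
        raise ValueError(f"unknown statistic {statistic!r}")
    values[:margin] = values[margin]
    values[n - margin :] = values[n - margin - 1]
    return Profile(values=values, window_length=window_length, statistic=statistic)
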
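"""Deterministic text exports of per-position results.

The position table is the tool's downloadable-data equivalent: one row
per residue with both charge profiles, both fold-propensity profiles,
the smoothed region class, the display envelope, and annotation flags.
Floats print with a fixed number of decimals so identical inputs yield
byte-identical files.
"""

from __future__ import annotations

import numpy as np

from .records import ProteinRecord
from .segmentation import RegionSet, envelope_track
from .windows import Profile

POSITION_TABLE_COLUMNS = (
    "index",
    "residue",
    "charge_unmod",
    "charge_phos",
    "fp_unmod",
    "fp_phos",
    "class",
    "envelope",
    "is_phospho_site",
    "domain_name",
)


def _values(track: Profile | np.ndarray) -> np.ndarray:
    return track.values if isinstance(track, Profile) else np.asarray(track, dtype=float)


def export_position_table(
    record: ProteinRecord,
    charge_unmod: Profile | np.ndarray,
    charge_phos: Profile | np.ndarray,
    fp_unmod: Profile,
    fp_phos: Profile,
    regions: RegionSet,
    precision: int = 4,
) -> str:
    """Render the per-position TSV for one protein.

    The charge columns are per-residue charge tracks (so a phospho-site
    row shows exactly the -2 adjustment); the fp columns are the
    windowed fold-propensity profiles. All tracks must cover the full
    sequence; a length mismatch is an internal consistency failure and
    raises.
    """
    n = len(record.sequence)
    charge_unmod = _values(charge_unmod)
    charge_phos = _values(charge_phos)
    tracks = {
        "charge_unmod": charge_unmod,
        "charge_phos": charge_phos,
        "fp_unmod": fp_unmod.values,
        "fp_phos": fp_phos.values,
    }
    for name, values in tracks.items():
        if len(values) != n:
            raise ValueError(
                f"track {name} has length {len(values)}, sequence has {n}"
            )
    if regions.length != n:
        raise ValueError(f"regions cover {regions.length} positions, sequence has {n}")

    envelope = envelope_track(regions, n)
    labels = regions.labels()
    domain_by_pos = [""] * n
    for d in record.domains:
        for p in range(d.start, min(d.end, n) + 1):
            if not domain_by_pos[p - 1]:
                domain_by_pos[p - 1] = d.name

    fmt = f"{{:.{precision}f}}".format
    lines = ["\t".join(POSITION_TABLE_COLUMNS)]
    for i in range(n):
        pos = i + 1
        lines.append(
            "\t".join(
                (
                    str(pos),
                    record.sequence[i],
                    fmt(charge_unmod[i]),
                    fmt(charge_phos[i]),
                    fmt(fp_unmod.values[i]),
                    fmt(fp_phos.values[i]),
                    "structured" if labels[i] else "disordered",
                    fmt(envelope[i]),
                    "1" if pos in record.phospho_sites else "0",
                    domain_by_pos[i],
                )
            )
        )
    return "\n".join(lines) + "\n"


def difference_to_tsv(bin_values: np.ndarray, difference: np.ndarray) -> str:
    lines = ["window_net_charge\tdifference"]
    for value, diff in zip(bin_values, difference):
        lines.append(f"{value}\t{diff:.6f}")
    return "\n".join(lines) + "\n"
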
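"""Charge-hydropathy fold propensity.

Per-position fold propensity combines the windowed mean Kyte-Doolittle
hydropathy <H> (normalized to [0, 1]) with the windowed mean net charge
<R> through the linear charge-hydropathy boundary separating natively
folded from natively unfolded proteins:

    FP(i) = slope * <H>(i) - |<R>(i)| - intercept

with slope 2.785 and intercept 1.151 by default. Positive FP predicts a
folded window, negative an intrinsically disordered one. In
phosphorylated mode each phospho site contributes -2 to the charge term
only; hydropathy is left untouched, so phosphorylation shifts windows
toward (or, for strongly positive windows passing through neutrality,
transiently away from) disorder purely through charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .charges import ChargeParams, PhosphoMode, residue_charge_vector
from .records import ProteinRecord
from .windows import DEFAULT_WINDOW, Profile, sliding_window_profile

#: default normalization mapping raw Kyte-Doolittle [-4.5, 4.5] onto [0, 1]
KD_OFFSET = 4.5
KD_DIVISOR = 9.0


@dataclass
class FoldPropensityParams:
    """Parameters of the charge-hydropathy fold-propensity score.

    ``hydropathy_scale`` maps residues to raw hydropathies;
    ``normalization = (offset, divisor)`` rescales them as
    (raw + offset) / divisor, which must land every residue in [0, 1].
    ``slope`` and ``intercept`` are the folded/unfolded boundary
    coefficients; ``permissive`` maps unknown residues to the scale
    midpoint (0.5 normalized) instead of raising.
    """

    hydropathy_scale: dict[str, float] = field(
        default_factory=lambda: dict(KYTE_DOOLITTLE)
    )
    normalization: tuple[float, float] = (KD_OFFSET, KD_DIVISOR)
    slope: float = 2.785
    intercept: float = 1.151
    window_length: int = DEFAULT_WINDOW
    permissive: bool = False

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        offset, divisor = self.normalization
        for aa, raw in self.hydropathy_scale.items():
            h = (raw + offset) / divisor
            if not 0.0 <= h <= 1.0:
                raise ValueError(
                    f"normalized hydropathy of {aa!r} is {h:.3f}, outside [0, 1]; "
                    "fix the normalization bounds"
                )


def load_hydropathy_scale(tsv_text: str) -> dict[str, float]:
    """Load an alternative scale from two-column TSV (residue, value)."""
    scale: dict[str, float] = {}
    for raw in tsv_text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"hydropathy scale row needs 2 columns: {raw!r}")
        scale[fields[0].strip().upper()] = float(fields[1])
    return scale


def normalized_hydropathy(
    sequence: str, params: FoldPropensityParams | None = None
) -> np.ndarray:
    """Per-residue normalized hydropathy in [0, 1]."""
    if params is None:
        params = FoldPropensityParams()
    offset, divisor = params.normalization
    out = np.empty(len(sequence), dtype=float)
    for i, aa in enumerate(sequence):
        try:
            raw = params.hydropathy_scale[aa]
        except KeyError:
            if params.permissive:
                out[i] = 0.5
                continue
            raise KeyError(
                f"residue {aa!r} has no hydropathy value; validate the sequence "
                "or set permissive=True"
            ) from None
        out[i] = (raw + offset) / divisor
    return out


def charge_profile(
    record: ProteinRecord,
    phospho_mode: PhosphoMode = "unmodified",
    window_length: int = DEFAULT_WINDOW,
    charge_params: ChargeParams | None = None,
    statistic: str = "mean",
) -> Profile:
    """Windowed net-charge profile (the charge track of the viewer)."""
    track = residue_charge_vector(record, phospho_mode, charge_params)
    return sliding_window_profile(track, window_length, statistic)  # type: ignore[arg-type]


def fold_propensity_profile(
    record: ProteinRecord,
    phospho_mode: PhosphoMode = "unmodified",
    params: FoldPropensityParams | None = None,
    charge_params: ChargeParams | None = None,
) -> Profile:
    """Fold-propensity profile of a record.

    Both <H> and <R> use the same window and the same terminal
    extrapolation, so FP inherits the flat extrapolated margins.
    """
    if params is None:
        params = FoldPropensityParams()
    if charge_params is None:
        charge_params = ChargeParams(permissive=params.permissive)

    h_track = normalized_hydropathy(record.sequence, params)
    mean_h = sliding_window_profile(h_track, params.window_length, "mean")
    mean_r = charge_profile(
        record, phospho_mode, params.window_length, charge_params, "mean"
    )
    fp = params.slope * mean_h.values - np.abs(mean_r.values) - params.intercept
    return Profile(values=fp, window_length=params.window_length, statistic="mean")
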
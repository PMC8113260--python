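"""Per-residue charge at neutral pH, with the phosphorylation adjustment.

The integer charge convention at neutral pH: aspartate and glutamate
carry -1, lysine and arginine +1, histidine 0 by default (configurable,
its imidazole pKa sits near neutrality), every other residue and the
termini 0. Each phosphorylation site adds -2 elementary charges — the
phosphate's dominant ionisation state at neutral pH replacing the
neutral hydroxyl on S/T/Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .records import CANONICAL_RESIDUES, ProteinRecord

PhosphoMode = Literal["unmodified", "phosphorylated"]

_DEFAULT_CHARGES: dict[str, float] = {aa: 0.0 for aa in CANONICAL_RESIDUES}
_DEFAULT_CHARGES.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.0})


@dataclass
class ChargeParams:
    """Charge model parameters (elementary charge units).

    ``phospho_delta`` is the charge added at each phospho site, -2 by
    default. ``histidine_charge`` overrides H without editing the full
    map. ``permissive`` assigns charge 0 to non-canonical residues
    instead of raising.
    """

    residue_charge: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CHARGES)
    )
    phospho_delta: float = -2.0
    histidine_charge: float = 0.0
    permissive: bool = False

    def charge_of(self, residue: str) -> float:
        if residue == "H":
            return self.histidine_charge
        try:
            return self.residue_charge[residue]
        except KeyError:
            if self.permissive:
                return 0.0
            raise KeyError(
                f"residue {residue!r} has no charge assignment; "
                "validate the sequence or set permissive=True"
            ) from None


def residue_charge_vector(
    record: ProteinRecord,
    phospho_mode: PhosphoMode = "unmodified",
    params: ChargeParams | None = None,
) -> np.ndarray:
    """Per-residue charge track for a record, one value per position.

    In ``phosphorylated`` mode every annotated site receives
    ``params.phospho_delta`` on top of its base residue charge (so a
    phospho-serine scores -2 with defaults); all other positions are
    identical between the two modes.
    """
    if params is None:
        params = ChargeParams()
    charges = np.array(
        [params.charge_of(aa) for aa in record.sequence], dtype=float
    )
    if phospho_mode == "phosphorylated":
        for p in record.phospho_sites:
            charges[p - 1] += params.phospho_delta
    elif phospho_mode != "unmodified":
        raise ValueError(f"unknown phospho_mode {phospho_mode!r}")
    return charges
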
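"""Seeded generators of synthetic annotated proteins and protein sets.

The generators emulate the block architecture typical of phase-
separating RNA-binding proteins: a hydrophobic, folded-like N-terminal
block (an RRM-like domain) followed by a low-hydropathy, charge-
enriched disordered block (an RGG-like region), with phospho sites
planted on S/T/Y residues at a controlled density. They provide
ground-truth inputs for the profile, segmentation, and set-comparison
machinery: the planted per-IDR-residue phospho density p fixes the
expected dNCPR at exactly -2p.

All randomness flows from a single integer seed; per-protein substreams
are derived by counter (``default_rng([seed, i])``), so a generated set
is a stable prefix of any larger set with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .charges import ChargeParams
from .propensity import FoldPropensityParams, fold_propensity_profile
from .records import PHOSPHO_ACCEPTORS, ProteinRecord
from .segmentation import RegionSet, segment

#: folded-like block: hydrophobic, mean normalized hydropathy ~0.8
STRUCTURED_COMPOSITION: dict[str, float] = {
    "L": 0.25, "I": 0.15, "V": 0.15, "A": 0.20, "F": 0.10, "G": 0.15,
}

#: RGG-like disordered block: low hydropathy, mild positive net charge
RGG_LIKE_COMPOSITION: dict[str, float] = {
    "G": 0.45, "S": 0.20, "R": 0.12, "K": 0.03,
    "D": 0.05, "E": 0.05, "N": 0.05, "Q": 0.05,
}


@dataclass
class BlockSpec:
    """One protein as an ordered list of compositional blocks.

    ``blocks`` is a list of (length, composition) pairs where each
    composition maps residues to probabilities summing to 1.
    ``phospho_density`` is the probability that each sampled S/T/Y
    residue is annotated as a phospho site.
    """

    blocks: list[tuple[int, dict[str, float]]]
    phospho_density: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("BlockSpec needs at least one block")
        if not 0.0 <= self.phospho_density <= 1.0:
            raise ValueError("phospho_density must be in [0, 1]")
        for length, comp in self.blocks:
            if length < 1:
                raise ValueError("block length must be >= 1")
            total = sum(comp.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"block composition sums to {total}, not 1")
        if self.phospho_density > 0:
            sty_mass = sum(
                comp.get(aa, 0.0)
                for _, comp in self.blocks
                for aa in PHOSPHO_ACCEPTORS
            )
            if sty_mass == 0:
                raise ValueError(
                    "phospho_density > 0 requires S/T/Y mass in some block"
                )


def composition_fold_propensity(
    composition: dict[str, float],
    params: FoldPropensityParams | None = None,
    charge_params: ChargeParams | None = None,
) -> float:
    """Expected fold propensity of a window drawn from a composition.

    slope * E[H] - |E[q]| - intercept; useful for designing blocks that
    land on the intended side of the folded/unfolded boundary.
    """
    if params is None:
        params = FoldPropensityParams()
    if charge_params is None:
        charge_params = ChargeParams()
    offset, divisor = params.normalization
    mean_h = sum(
        frac * (params.hydropathy_scale[aa] + offset) / divisor
        for aa, frac in composition.items()
    )
    mean_q = sum(frac * charge_params.charge_of(aa) for aa, frac in composition.items())
    return params.slope * mean_h - abs(mean_q) - params.intercept


def generate_protein(
    spec: BlockSpec,
    record_id: str = "SYN0001",
    rng: np.random.Generator | None = None,
    expected_block_classes: Sequence[str | None] | None = None,
) -> ProteinRecord:
    """Sample one ProteinRecord from a BlockSpec, deterministically.

    ``expected_block_classes`` optionally asserts, per block, that the
    composition's expected fold propensity has the intended sign
    ("structured" or "disordered"; None skips the check).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if expected_block_classes is not None:
        for (_, comp), want in zip(spec.blocks, expected_block_classes):
            if want is None:
                continue
            fp = composition_fold_propensity(comp)
            got = "structured" if fp > 0 else "disordered"
            if got != want:
                raise ValueError(
                    f"block composition scores FP={fp:.3f} ({got}), "
                    f"expected {want}"
                )
    parts = []
    for length, comp in spec.blocks:
        residues = sorted(comp)
        probs = np.array([comp[aa] for aa in residues])
        probs = probs / probs.sum()
        parts.append("".join(rng.choice(residues, size=length, p=probs)))
    sequence = "".join(parts)

    sites: set[int] = set()
    if spec.phospho_density > 0:
        for pos, aa in enumerate(sequence, start=1):
            if aa in PHOSPHO_ACCEPTORS and rng.random() < spec.phospho_density:
                sites.add(pos)
    return ProteinRecord(id=record_id, sequence=sequence, phospho_sites=frozenset(sites))


@dataclass
class SetSpec:
    """A set of block-architecture proteins with planted phospho density.

    ``phospho_density`` here is per predicted-IDR residue: sites are
    planted on S/T/Y inside the predicted disordered regions at a rate
    that makes the expected number of sites equal density * IDR length,
    so the expected IDR-scope dNCPR is exactly -2 * density.

    ``idr_charge_target`` selects the windowed-charge family of the
    disordered block: "near_neutral_positive_tail" (core-like: near
    neutrality with positive-charge enrichment) or "broad" (client-like:
    wider per-protein net-charge spread).
    """

    n_proteins: int = 50
    structured_length: tuple[int, int] = (80, 150)
    idr_length: tuple[int, int] = (250, 400)
    idr_charge_target: str = "near_neutral_positive_tail"
    phospho_density: float = 0.017
    seed: int = 0
    id_prefix: str = "SYN"

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0.0 <= self.phospho_density <= 1.0:
            raise ValueError("phospho_density must be in [0, 1]")
        if self.idr_charge_target not in {"near_neutral_positive_tail", "broad"}:
            raise ValueError(f"unknown idr_charge_target {self.idr_charge_target!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "SetSpec":
        kwargs = dict(data)
        for key in ("structured_length", "idr_length"):
            if key in kwargs:
                kwargs[key] = tuple(int(x) for x in kwargs[key])
        return cls(**kwargs)


def _idr_composition(target: str, rng: np.random.Generator) -> dict[str, float]:
    comp = dict(RGG_LIKE_COMPOSITION)
    if target == "near_neutral_positive_tail":
        # mild per-protein jitter in arginine content, net charge stays >= 0
        r = float(rng.uniform(0.10, 0.15))
        comp["G"] += comp["R"] - r
        comp["R"] = r
    elif target == "broad":
        # per-protein net-charge bias spanning negative to positive
        bias = float(rng.uniform(-0.10, 0.12))
        pos, neg = 0.08, 0.08
        if bias >= 0:
            pos += bias
        else:
            neg -= bias
        comp["R"], comp["K"] = pos * 0.8, pos * 0.2
        comp["D"], comp["E"] = neg / 2, neg / 2
        comp["G"] = 1.0 - sum(v for k, v in comp.items() if k != "G")
    return comp


def generate_set(
    spec: SetSpec,
    fold_params: FoldPropensityParams | None = None,
    with_regions: bool = False,
) -> list[ProteinRecord] | list[tuple[ProteinRecord, RegionSet]]:
    """Generate a deterministic set of annotated proteins.

    Each protein is a structured block followed by a disordered block;
    its fold-propensity profile is segmented (unmodified mode) and
    phospho sites are planted on S/T/Y within the *predicted* disordered
    regions at the spec's per-IDR-residue density. With
    ``with_regions=True`` the computed RegionSet is returned alongside
    each record, ready for :func:`phosfold.analysis.compare_sets`.
    """
    if fold_params is None:
        fold_params = FoldPropensityParams()
    out: list = []
    for i in range(spec.n_proteins):
        rng = np.random.default_rng([spec.seed, i])
        n_struct = int(rng.integers(spec.structured_length[0], spec.structured_length[1] + 1))
        n_idr = int(rng.integers(spec.idr_length[0], spec.idr_length[1] + 1))
        block_spec = BlockSpec(
            blocks=[
                (n_struct, STRUCTURED_COMPOSITION),
                (n_idr, _idr_composition(spec.idr_charge_target, rng)),
            ],
            phospho_density=0.0,
        )
        record = generate_protein(block_spec, record_id=f"{spec.id_prefix}{i:04d}", rng=rng)

        fp = fold_propensity_profile(record, "unmodified", fold_params)
        regions = segment(fp)
        sites = _plant_idr_sites(record.sequence, regions, spec.phospho_density, rng)
        record = ProteinRecord(
            id=record.id, sequence=record.sequence, phospho_sites=frozenset(sites)
        )
        out.append((record, regions) if with_regions else record)
    return out


def _plant_idr_sites(
    sequence: str,
    regions: RegionSet,
    density: float,
    rng: np.random.Generator,
) -> set[int]:
    """Bernoulli-plant sites on IDR S/T/Y at per-IDR-residue density."""
    if density == 0.0:
        return set()
    idr_positions = [
        p
        for r in regions.disordered_regions()
        for p in range(r.start, r.end + 1)
    ]
    sty = [p for p in idr_positions if sequence[p - 1] in PHOSPHO_ACCEPTORS]
    if not idr_positions:
        return set()
    if not sty:
        raise ValueError("predicted IDRs contain no S/T/Y to phosphorylate")
    # per-S/T/Y rate q chosen so E[#sites] = density * |IDR|
    q = min(1.0, density * len(idr_positions) / len(sty))
    return {p for p in sty if rng.random() < q}
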
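"""Domain types for annotated protein sequences.

A :class:`ProteinRecord` bundles one amino-acid sequence with its
phosphorylation sites and (optional) domain annotations, all in 1-based
UniProt-style coordinates. Validation is report-returning: a
:class:`ValidationReport` collects errors (which must block downstream
computation) and warnings (which do not).
"""

from __future__ import annotations

from dataclasses import dataclass, field

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
PHOSPHO_ACCEPTORS = frozenset("STY")


@dataclass(frozen=True)
class Domain:
    """A named region, 1-based inclusive on both ends."""

    name: str
    start: int
    end: int


@dataclass
class ProteinRecord:
    """One protein sequence with phospho-site and domain annotations.

    Parameters
    ----------
    id
        Text identifier (e.g. a UniProt accession or any FASTA id).
    sequence
        Amino-acid sequence, canonical one-letter codes, position 1 is
        the first residue.
    phospho_sites
        Set of 1-based positions carrying a phosphate group.
    domains
        Display annotations; list of :class:`Domain`.
    """

    id: str
    sequence: str
    phospho_sites: frozenset[int] = frozenset()
    domains: tuple[Domain, ...] = ()

    def __post_init__(self) -> None:
        self.phospho_sites = frozenset(self.phospho_sites)
        self.domains = tuple(
            d if isinstance(d, Domain) else Domain(*d) for d in self.domains
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ValidationIssue:
    code: str
    message: str
    position: int | None = None


@dataclass
class ValidationReport:
    """Errors and warnings from validating a record.

    A record whose report has ``errors`` must not be fed to profile or
    analysis code; warnings are informational.
    """

    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error(self, code: str, message: str, position: int | None = None) -> None:
        self.errors.append(ValidationIssue(code, message, position))

    def warn(self, code: str, message: str, position: int | None = None) -> None:
        self.warnings.append(ValidationIssue(code, message, position))


def validate_record(
    record: ProteinRecord,
    *,
    window_length: int | None = None,
    permissive: bool = False,
) -> ValidationReport:
    """Check a record against the coordinate and alphabet invariants.

    Errors: empty sequence, non-canonical residues (unless
    ``permissive``), out-of-range phospho positions or domain bounds.
    Warnings: phospho sites on residues other than S/T/Y (phosphate
    chemistry targets serine, threonine and tyrosine, but annotations
    are taken at face value), sequences shorter than ``window_length``,
    and non-canonical residues in permissive mode.
    """
    report = ValidationReport()
    seq = record.sequence
    n = len(seq)

    if n == 0:
        report.error("empty-sequence", f"{record.id}: sequence is empty")
        return report

    for i, aa in enumerate(seq, start=1):
        if aa not in CANONICAL_RESIDUES:
            if permissive:
                report.warn(
                    "non-canonical-residue",
                    f"{record.id}: residue {aa!r} at position {i} mapped to "
                    "neutral charge / mean hydropathy",
                    i,
                )
            else:
                report.error(
                    "non-canonical-residue",
                    f"{record.id}: residue {aa!r} at position {i} is not one of "
                    "the 20 canonical amino acids",
                    i,
                )

    for p in sorted(record.phospho_sites):
        if not 1 <= p <= n:
            report.error(
                "position-out-of-range",
                f"{record.id}: phospho position {p} outside 1..{n}",
                p,
            )
        elif seq[p - 1] not in PHOSPHO_ACCEPTORS:
            report.warn(
                "phospho-site-not-sty",
                f"{record.id}: phospho site at {p} is {seq[p - 1]!r}, not S/T/Y",
                p,
            )

    for d in record.domains:
        if not 1 <= d.start <= d.end <= n:
            report.error(
                "domain-out-of-range",
                f"{record.id}: domain {d.name!r} span {d.start}-{d.end} "
                f"outside 1..{n}",
                d.start,
            )

    if window_length is not None and n < window_length:
        report.warn(
            "sequence-shorter-than-window",
            f"{record.id}: length {n} < window length {window_length}",
        )

    return report
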
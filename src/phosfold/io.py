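"""Reading and writing the package's text formats.

Formats
-------
FASTA
    Standard single-letter FASTA, parsed with Bio.SeqIO.
phospho TSV
    ``protein_id<TAB>position<TAB>residue``; header row optional,
    lines starting with ``#`` ignored. Positions are 1-based.
domain TSV
    ``protein_id<TAB>domain_name<TAB>start<TAB>end``; same dialect.
region TSV
    1-based inclusive: ``protein_id<TAB>start<TAB>end<TAB>class`` and a
    BED-like 0-based half-open variant.
id list
    One protein id per line, ``#`` comments ignored.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

from Bio import SeqIO

from .records import Domain, ProteinRecord, ValidationReport


class ParseError(ValueError):
    """Raised for malformed input files."""


def _data_lines(text: str) -> list[tuple[int, list[str]]]:
    """Split TSV text into (lineno, fields), skipping blanks/comments."""
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        out.append((lineno, line.split("\t")))
    return out


def parse_fasta(fasta_text: str) -> list[tuple[str, str]]:
    """Parse FASTA text into (id, sequence) pairs, uppercasing residues."""
    stripped = fasta_text.lstrip()
    if stripped and not stripped.startswith(">"):
        first_line = fasta_text.splitlines()[0] if fasta_text.splitlines() else ""
        raise ParseError(
            f"malformed FASTA: expected '>' header, got {first_line!r} on line 1"
        )
    entries = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(_io.StringIO(fasta_text), "fasta")
    ]
    if not entries:
        raise ParseError("malformed FASTA: no records found")
    for rid, seq in entries:
        if not seq:
            raise ParseError(f"malformed FASTA: record {rid!r} has empty sequence")
    return entries


def parse_phospho_table(
    text: str, report: ValidationReport
) -> dict[str, set[int]]:
    """Parse the phospho TSV into id -> set of 1-based positions.

    Non-integer positions are row errors; duplicate (id, position) pairs
    are deduplicated with a warning. The residue column is carried for
    the user's benefit only and is not cross-checked here (that happens
    in validate_record against the actual sequence).
    """
    sites: dict[str, set[int]] = {}
    for lineno, fields in _data_lines(text):
        if len(fields) < 2:
            report.error(
                "phospho-row-malformed",
                f"phospho table line {lineno}: expected at least 2 columns",
            )
            continue
        pid, pos_s = fields[0].strip(), fields[1].strip()
        if lineno == 1 and not _is_int(pos_s):
            # tolerated header row
            if pos_s.lower() in {"position", "pos"}:
                continue
        if not _is_int(pos_s):
            report.error(
                "phospho-position-not-integer",
                f"phospho table line {lineno}: position {pos_s!r} is not an integer",
            )
            continue
        pos = int(pos_s)
        bucket = sites.setdefault(pid, set())
        if pos in bucket:
            report.warn(
                "phospho-duplicate",
                f"phospho table line {lineno}: duplicate site {pid}:{pos}, deduplicated",
                pos,
            )
        bucket.add(pos)
    return sites


def parse_domain_table(
    text: str, report: ValidationReport
) -> dict[str, list[Domain]]:
    """Parse the domain TSV into id -> list of Domain."""
    domains: dict[str, list[Domain]] = {}
    for lineno, fields in _data_lines(text):
        if len(fields) < 4:
            report.error(
                "domain-row-malformed",
                f"domain table line {lineno}: expected 4 columns",
            )
            continue
        pid, name, start_s, end_s = (f.strip() for f in fields[:4])
        if lineno == 1 and not (_is_int(start_s) and _is_int(end_s)):
            if start_s.lower() == "start":
                continue
        if not (_is_int(start_s) and _is_int(end_s)):
            report.error(
                "domain-bounds-not-integer",
                f"domain table line {lineno}: start/end must be integers",
            )
            continue
        domains.setdefault(pid, []).append(Domain(name, int(start_s), int(end_s)))
    return domains


def _is_int(s: str) -> bool:
    try:
        int(s)
    except ValueError:
        return False
    return True


def parse_protein_tables(
    fasta_text: str,
    phospho_table: str = "",
    domain_table: str = "",
    report: ValidationReport | None = None,
) -> list[ProteinRecord]:
    """Assemble ProteinRecords from FASTA text plus annotation tables.

    One record per FASTA entry, in FASTA order; phospho positions and
    domains are attached by id, verbatim (1-based). Table rows whose id
    matches no FASTA entry produce a warning on ``report``. Coordinate
    range checking is left to :func:`phosfold.records.validate_record`.
    """
    if report is None:
        report = ValidationReport()
    entries = parse_fasta(fasta_text)
    sites = parse_phospho_table(phospho_table, report) if phospho_table.strip() else {}
    doms = parse_domain_table(domain_table, report) if domain_table.strip() else {}

    known = {rid for rid, _ in entries}
    for pid in sorted(set(sites) - known):
        report.warn("phospho-unmatched-id", f"phospho table id {pid!r} not in FASTA")
    for pid in sorted(set(doms) - known):
        report.warn("domain-unmatched-id", f"domain table id {pid!r} not in FASTA")

    return [
        ProteinRecord(
            id=rid,
            sequence=seq,
            phospho_sites=frozenset(sites.get(rid, set())),
            domains=tuple(doms.get(rid, [])),
        )
        for rid, seq in entries
    ]


# ---------------------------------------------------------------- writers


def write_fasta(records: list[ProteinRecord], width: int = 60) -> str:
    lines = []
    for rec in records:
        lines.append(f">{rec.id}")
        for i in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[i : i + width])
    return "\n".join(lines) + "\n"


def write_phospho_table(records: list[ProteinRecord]) -> str:
    lines = ["protein_id\tposition\tresidue"]
    for rec in records:
        for p in sorted(rec.phospho_sites):
            res = rec.sequence[p - 1] if 1 <= p <= len(rec.sequence) else "?"
            lines.append(f"{rec.id}\t{p}\t{res}")
    return "\n".join(lines) + "\n"


def write_domain_table(records: list[ProteinRecord]) -> str:
    lines = ["protein_id\tdomain_name\tstart\tend"]
    for rec in records:
        for d in rec.domains:
            lines.append(f"{rec.id}\t{d.name}\t{d.start}\t{d.end}")
    return "\n".join(lines) + "\n"


def read_id_list(text: str) -> list[str]:
    """Read a set-membership file: one protein id per line."""
    ids = []
    for _, fields in _data_lines(text):
        ids.append(fields[0].strip())
    return ids


def read_text(path: str | Path) -> str:
    return Path(path).read_text()
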
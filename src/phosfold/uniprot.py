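"""Optional adapter: build ProteinRecords from saved UniProt exports.

Works offline on files the user has already downloaded — either the
UniProtKB flat-text format (parsed with Bio.SwissProt) or the REST JSON
format. Phospho sites are taken as every MOD_RES feature whose
description begins with "Phospho" (all evidence codes, at face value);
Pfam cross-references become display domains, using the feature's span
when the export carries one and the whole sequence otherwise.

The core library never touches the network; this module only reads
saved exports.
"""

from __future__ import annotations

import io
import json

from Bio import SwissProt

from .records import Domain, ProteinRecord


def record_from_uniprot_text(text: str) -> ProteinRecord:
    """Parse one entry in UniProtKB flat-text format."""
    entry = SwissProt.read(io.StringIO(text))
    accession = entry.accessions[0] if entry.accessions else entry.entry_name
    sequence = entry.sequence
    sites: set[int] = set()
    domains: list[Domain] = []
    for feature in entry.features:
        if feature.type == "MOD_RES":
            desc = (feature.qualifiers or {}).get("note", "")
            if str(desc).startswith("Phospho"):
                pos = feature.location.start + 1  # Bio uses 0-based starts
                sites.add(int(pos))
        elif feature.type == "DOMAIN":
            desc = (feature.qualifiers or {}).get("note", "") or "domain"
            domains.append(
                Domain(
                    str(desc),
                    int(feature.location.start) + 1,
                    int(feature.location.end),
                )
            )
    return ProteinRecord(
        id=accession,
        sequence=sequence,
        phospho_sites=frozenset(sites),
        domains=tuple(domains),
    )


def record_from_uniprot_json(text: str) -> ProteinRecord:
    """Parse one entry in UniProt REST JSON format."""
    data = json.loads(text)
    accession = data.get("primaryAccession") or data.get("accession") or "UNKNOWN"
    sequence = data["sequence"]["value"]
    sites: set[int] = set()
    domains: list[Domain] = []
    for feature in data.get("features", []):
        ftype = feature.get("type", "")
        loc = feature.get("location", {})
        start = loc.get("start", {}).get("value")
        end = loc.get("end", {}).get("value")
        if ftype == "Modified residue" and str(
            feature.get("description", "")
        ).startswith("Phospho"):
            if start is not None:
                sites.add(int(start))
        elif ftype == "Domain" and start is not None and end is not None:
            domains.append(
                Domain(feature.get("description", "domain"), int(start), int(end))
            )
    return ProteinRecord(
        id=accession,
        sequence=sequence,
        phospho_sites=frozenset(sites),
        domains=tuple(domains),
    )
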
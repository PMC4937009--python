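"""File I/O helpers: FASTA input and JSON per-residue parameter tables."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from Bio import SeqIO

from .descriptors import DESCRIPTORS, RULES, ResidueParamTable

log = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs in file order."""
    path = Path(path)
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        log.warning("%s: no FASTA records found", path)
    return records


def write_param_tables(tables: dict[str, ResidueParamTable], path: str | Path) -> None:
    """Serialize parameter tables as a flat JSON document."""
    doc = {
        desc: {"rule": t.rule, "values": t.values}
        for desc, t in tables.items()
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_param_tables(path: str | Path) -> dict[str, ResidueParamTable]:
    """Load parameter tables written by :func:`write_param_tables`."""
    doc = json.loads(Path(path).read_text())
    tables: dict[str, ResidueParamTable] = {}
    for desc, entry in doc.items():
        rule = entry.get("rule", RULES.get(desc))
        tables[desc] = ResidueParamTable(
            descriptor=desc, rule=rule,
            values={k: float(v) for k, v in entry["values"].items()},
        )
    missing = [d for d in DESCRIPTORS if d not in tables]
    if missing:
        raise ValueError(f"parameter file {path} missing descriptors: {missing}")
    return tables
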
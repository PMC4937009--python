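"""Reference peptide dataset: 84 aggregation-prone regions (APR), 22
tregitopes and the 42 control 5-mers sliced from them.

The packaged table carries, for every peptide, the eight sequence-level
physicochemical descriptors (AM, AC, ROT, HBA, QPCaco, IP, NON, QPlogS)
and the printed AEx score. Integrity is re-checked on every load against
frozen group counts and column sums, so silent fixture corruption cannot
propagate into downstream statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

GROUPS = ("APR", "TREGITOPE", "CONTROL")

#: Descriptor columns in fixture order.
DESCRIPTOR_COLUMNS = (
    "AM", "AC", "ROT", "HBA", "QPCaco", "IP", "NON", "QPlogS", "AEx_printed",
)

#: The control 5-mer excluded during control-set derivation because it was
#: drawn twice from the tregitope pool.
DOUBLE_SELECTED_WINDOW = "VSWYQ"


class FixtureError(ValueError):
    """Raised when the packaged reference table fails validation."""


@dataclass(frozen=True)
class SequenceRecord:
    """One reference peptide with its printed descriptor values.

    Counts (am, ac, rot, non) are sequence sums of per-residue integer
    counts; hba and ip are real-valued sums; qpcaco and qplogs are
    mean-aggregated. ``aex_printed`` is the published AEx score, kept
    verbatim (including the one anomalous row, VVSVL).
    """

    id: int
    sequence: str
    group: str
    am: int
    ac: int
    rot: int
    hba: float
    qpcaco: float
    ip: float
    non: int
    qplogs: float
    aex_printed: float

    def descriptor_values(self) -> dict[str, float]:
        """Printed sequence-level descriptors keyed by descriptor name."""
        return {
            "AM": self.am, "AC": self.ac, "ROT": self.rot, "HBA": self.hba,
            "QPCaco": self.qpcaco, "IP": self.ip, "NON": self.non,
            "QPlogS": self.qplogs,
        }


@dataclass(frozen=True)
class FixtureChecksum:
    n_total: int
    n_per_group: dict[str, int]
    column_sums: dict[str, float]


#: Frozen at packaging time; recomputed and compared on every load.
EXPECTED_CHECKSUM = FixtureChecksum(
    n_total=148,
    n_per_group={"APR": 84, "TREGITOPE": 22, "CONTROL": 42},
    column_sums={
        "AM": 1069.0,
        "AC": 1079.0,
        "ROT": 4128.0,
        "HBA": 3709.7,
        "QPCaco": 895.33,
        "IP": 9205.11,
        "NON": 184.0,
        "QPlogS": -7.332,
        "AEx_printed": -24.63,
    },
)

_INT_FIELDS = ("AM", "AC", "ROT", "NON")


def _parse_row(lineno: int, fields: list[str]) -> SequenceRecord:
    if len(fields) != 12:
        raise FixtureError(f"row at line {lineno}: expected 12 fields, got {len(fields)}")
    try:
        rec = SequenceRecord(
            id=int(fields[0]), sequence=fields[1], group=fields[2],
            am=int(fields[3]), ac=int(fields[4]), rot=int(fields[5]),
            hba=float(fields[6]), qpcaco=float(fields[7]), ip=float(fields[8]),
            non=int(fields[9]), qplogs=float(fields[10]),
            aex_printed=float(fields[11]),
        )
    except ValueError as exc:
        raise FixtureError(f"row at line {lineno} (id {fields[0]}): {exc}") from exc
    if rec.group not in GROUPS:
        raise FixtureError(f"record {rec.id}: unknown group {rec.group!r}")
    bad = set(rec.sequence) - set(CANONICAL_RESIDUES)
    if bad:
        raise FixtureError(
            f"record {rec.id} ({rec.sequence}): non-canonical residues {sorted(bad)}"
        )
    if min(rec.am, rec.ac, rec.rot, rec.non) < 0:
        raise FixtureError(f"record {rec.id}: negative count descriptor")
    return rec


def fixture_path() -> Path:
    return Path(resources.files("aexapr").joinpath("data/table1.tsv"))


def load_reference_table(path: str | Path | None = None) -> list[SequenceRecord]:
    """Load and validate the 148-peptide reference table.

    Parameters
    ----------
    path
        Optional alternative TSV (same header) — used for round-trip
        testing; by default the packaged fixture is read.

    Returns
    -------
    list of SequenceRecord in table order (ids 1..148).

    Raises
    ------
    FixtureError
        If the file is missing a row, contains an invalid value, or its
        recomputed checksum disagrees with the frozen one.
    """
    p = Path(path) if path is not None else fixture_path()
    lines = p.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t")[0] != "id":
        raise FixtureError(f"{p}: missing header line")
    records = [_parse_row(i + 2, line.split("\t")) for i, line in enumerate(lines[1:]) if line]
    _validate(records)
    return records


def _validate(records: list[SequenceRecord]) -> None:
    chk = compute_checksum(records)
    if chk.n_total != EXPECTED_CHECKSUM.n_total:
        raise FixtureError(
            f"expected {EXPECTED_CHECKSUM.n_total} records, found {chk.n_total}"
        )
    if chk.n_per_group != EXPECTED_CHECKSUM.n_per_group:
        raise FixtureError(f"group counts {chk.n_per_group} != expected")
    for col, want in EXPECTED_CHECKSUM.column_sums.items():
        got = chk.column_sums[col]
        if not math.isclose(got, want, abs_tol=1e-6):
            # identify the most aberrant row for the message
            raise FixtureError(f"column {col}: sum {got} != expected {want}")
    for i, rec in enumerate(records, start=1):
        if rec.id != i:
            raise FixtureError(f"record order broken at id {rec.id} (position {i})")
    r118, r121 = records[117], records[120]
    if r118.descriptor_values() != r121.descriptor_values() or r118.sequence != r121.sequence:
        raise FixtureError("records 118 and 121 (GGLVQ duplicates) differ")


def compute_checksum(records: list[SequenceRecord]) -> FixtureChecksum:
    per_group = {g: sum(1 for r in records if r.group == g) for g in GROUPS}
    getters = {
        "AM": lambda r: r.am, "AC": lambda r: r.ac, "ROT": lambda r: r.rot,
        "HBA": lambda r: r.hba, "QPCaco": lambda r: r.qpcaco, "IP": lambda r: r.ip,
        "NON": lambda r: r.non, "QPlogS": lambda r: r.qplogs,
        "AEx_printed": lambda r: r.aex_printed,
    }
    sums = {col: round(sum(get(r) for r in records), 6) for col, get in getters.items()}
    return FixtureChecksum(len(records), per_group, sums)


def reference_table_tsv(records: list[SequenceRecord]) -> str:
    """Serialize records in the fixture TSV format (round-trip safe)."""
    header = "id\tsequence\tgroup\t" + "\t".join(DESCRIPTOR_COLUMNS)
    lines = [header]
    for r in records:
        lines.append(
            f"{r.id}\t{r.sequence}\t{r.group}\t{r.am}\t{r.ac}\t{r.rot}\t"
            f"{r.hba:.2f}\t{r.qpcaco:.2f}\t{r.ip:.2f}\t{r.non}\t"
            f"{r.qplogs:.3f}\t{r.aex_printed:.2f}"
        )
    return "\n".join(lines) + "\n"


def write_reference_table(records: list[SequenceRecord], path: str | Path) -> None:
    Path(path).write_text(reference_table_tsv(records), encoding="utf-8")


def derive_control_set(tregitopes: list[str]) -> list[str]:
    """Slice each tregitope into its first two 5-mers and drop the
    double-selected window.

    For every input sequence the residues 1-5 and 6-10 (1-based,
    inclusive) are extracted. The window VSWYQ arises as the first 5-mer
    of two distinct tregitopes; both occurrences are excluded. Duplicate
    windows originating from different tregitopes (GGLVQ, MHWVR) are
    kept as separate entries. Output order: all first windows, then all
    second windows.

    Raises
    ------
    ValueError
        If any input is shorter than 10 residues.
    """
    for seq in tregitopes:
        if len(seq) < 10:
            raise ValueError(f"tregitope {seq!r} shorter than 10 residues")
    first = [s[0:5] for s in tregitopes]
    second = [s[5:10] for s in tregitopes]
    windows = first + second
    return [w for w in windows if w != DOUBLE_SELECTED_WINDOW]


def random_peptides(n: int, length: int, seed: int) -> list[str]:
    """Reproducible random peptides, uniform over the 20 canonical residues."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(CANONICAL_RESIDUES))
    draws = rng.integers(0, len(letters), size=(n, length))
    return ["".join(letters[row]) for row in draws]
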
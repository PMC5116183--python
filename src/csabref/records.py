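"""Peptide records and file I/O shared by every other module.

The unit of analysis is a *mature* peptide sequence: the secreted form after
signal- and propeptide cleavage.  Propeptide presence/absence is carried as a
ternary flag per terminus because it is itself a phylogenetic character
(present = 1, absent = 0, unknown = '-').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 standard residues plus the ambiguity codes accepted in input.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_RESIDUES = STANDARD_RESIDUES | frozenset("XBZU")


class Ternary(str, Enum):
    """Three-valued presence flag used for propeptide termini."""

    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"

    @property
    def code(self) -> str:
        """Single-character matrix code: present=1, absent=0, unknown='-'."""
        return {"present": "1", "absent": "0", "unknown": "-"}[self.value]

    @classmethod
    def from_code(cls, code: str) -> "Ternary":
        try:
            return {"1": cls.PRESENT, "0": cls.ABSENT, "-": cls.UNKNOWN}[code]
        except KeyError:
            raise ValueError(
                f"illegal propeptide code {code!r}; expected 1, 0 or -"
            ) from None


class ParseError(ValueError):
    """Raised for malformed sequence or table input."""


@dataclass(frozen=True)
class PeptideRecord:
    """One mature peptide.

    Parameters
    ----------
    id:
        Unique identifier token (unique within any collection).
    sequence:
        Uppercase amino-acid sequence.  Standard residues plus X/B/Z/U are
        legal; only literal ``C`` ever counts as a cysteine downstream
        (selenocysteine ``U`` deliberately does not).
    description:
        Free text from the FASTA header (everything after the id).
    has_n_propeptide, has_c_propeptide:
        Ternary flags for an N-/C-terminal propeptide in the precursor.
    taxon_group:
        Optional coarse taxon label (e.g. ``Hexapoda``), opaque metadata.
    """

    id: str
    sequence: str
    description: str = ""
    has_n_propeptide: Ternary = Ternary.UNKNOWN
    has_c_propeptide: Ternary = Ternary.UNKNOWN
    taxon_group: str | None = None
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, record_id=self.id)

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(sequence: str, record_id: str = "?") -> None:
    """Reject empty sequences and illegal residue characters.

    Offsets in error messages are 1-based, matching the human-readable
    reports elsewhere in the package.
    """
    if not sequence:
        raise ParseError(f"record {record_id!r}: empty sequence")
    for offset, ch in enumerate(sequence, start=1):
        if ch not in ALLOWED_RESIDUES:
            raise ParseError(
                f"record {record_id!r}: illegal residue {ch!r} at offset {offset}"
            )


def _clean_sequence(raw: str, record_id: str) -> str:
    """Uppercase, strip terminal stop '*' (interior '*' is an error)."""
    seq = raw.upper()
    while seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        raise ParseError(f"record {record_id!r}: interior stop character '*'")
    return seq


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read a multi-record FASTA file into :class:`PeptideRecord` objects.

    Sequences are uppercased and a terminal ``*`` stop is stripped; input
    order is preserved.  Duplicate ids, illegal residues and empty sequences
    raise :class:`ParseError`.
    """
    path = Path(path)
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ParseError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        seq = _clean_sequence(str(entry.seq), rid)
        desc = entry.description
        if desc.startswith(rid):
            desc = desc[len(rid):].strip()
        records.append(PeptideRecord(id=rid, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA (wrapped lines, LF endings)."""
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", newline="\n") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(seq_records)


def read_propeptide_table(
    path: str | Path, records: Sequence[PeptideRecord]
) -> list[PeptideRecord]:
    """Apply a propeptide sidecar table to a record collection.

    The table is tab-separated with header columns ``id``, ``n_propeptide``,
    ``c_propeptide`` and values in {1, 0, -}.  Records absent from the table
    keep flag ``unknown``; table ids with no matching record are logged as
    warnings (not fatal).  Returns a new list in the original record order.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "n_propeptide", "c_propeptide"}
    if not required.issubset(table.columns):
        raise ParseError(
            f"{path}: propeptide table needs columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    flags: dict[str, tuple[Ternary, Ternary]] = {}
    for _, row in table.iterrows():
        flags[row["id"]] = (
            Ternary.from_code(row["n_propeptide"]),
            Ternary.from_code(row["c_propeptide"]),
        )
    known = {r.id for r in records}
    for rid in flags:
        if rid not in known:
            logger.warning("propeptide table id %r matches no record", rid)
    out = []
    for rec in records:
        if rec.id in flags:
            n_flag, c_flag = flags[rec.id]
            rec = replace(rec, has_n_propeptide=n_flag, has_c_propeptide=c_flag)
        out.append(rec)
    return out


def write_propeptide_table(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write the sidecar table consumed by :func:`read_propeptide_table`."""
    rows = [
        {
            "id": r.id,
            "n_propeptide": r.has_n_propeptide.code,
            "c_propeptide": r.has_c_propeptide.code,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=["id", "n_propeptide", "c_propeptide"])
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class RecordAnnotation:
    """Flat per-record annotation bundle rendered into the output table.

    Produced by :func:`csabref.pipeline.annotate_record`; all fields are
    plain strings/ints so the table is stable across runs.
    """

    record_id: str
    n_cysteines: int
    slots: str = ""          # e.g. "2,3,4,6,8,9"
    notation: str = ""
    family: str = "none"
    bonds: str = ""
    gamma_core: str = ""     # 1-based inclusive span, e.g. "12-27"
    kcxn: bool = False
    n_loop: int | None = None


ANNOTATION_COLUMNS = [
    "id",
    "n_cysteines",
    "slots",
    "notation",
    "family",
    "bonds",
    "gamma_core",
    "kcxn",
    "n_loop",
]


def write_annotation_table(
    annotations: Sequence[RecordAnnotation], path: str | Path
) -> None:
    """Write one tab-separated row per record, in input order.

    Column order is fixed (:data:`ANNOTATION_COLUMNS`) and the output is
    byte-stable across runs for identical input.
    """
    rows = []
    for ann in annotations:
        rows.append(
            {
                "id": ann.record_id,
                "n_cysteines": ann.n_cysteines,
                "slots": ann.slots,
                "notation": ann.notation,
                "family": ann.family,
                "bonds": ann.bonds,
                "gamma_core": ann.gamma_core,
                "kcxn": int(ann.kcxn),
                "n_loop": "" if ann.n_loop is None else ann.n_loop,
            }
        )
    frame = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
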
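"""Cysteine-anchored multiple alignment.

Mapped reference cysteines occupy fixed, shared columns; everything else is
laid out deterministically around them.  This formalizes the manual
practice of aligning CS-αβ sequences "with adjustments to ensure accurate
alignment of the cysteines": no substitution scoring is involved, anchoring
is purely structural.

Layout
------
Columns are, left to right: an N-flank region, then for each reference slot
that is assigned in at least one record a single anchor column, with an
inter-slot region between consecutive slot columns, and a C-flank region.
Each record's residues between two of *its* assigned slots are
left-justified against the leading anchor (so they fill the first
inter-slot region after it, and any further anchor columns the record lacks
are gapped).  Residues upstream of a record's first assigned slot are
right-justified against the C2 anchor when that first slot is ≥ 2 — an
AdDLP-like peptide whose first cysteine is C3 therefore shows its flank
upstream of the C2 column and a fully gapped C2–C3 region — and against the
C1 column otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .mapping import ArrayMapping
from .records import PeptideRecord

logger = logging.getLogger(__name__)

GAP = "-"

#: The six regions used for AdDLP-relative indel coding, as
#: (name, left anchor slot or None for sequence start,
#:  right anchor slot or None for sequence end).
REGIONS = {
    "flank_c2": (None, 2),
    "c2_c3": (2, 3),
    "c3_c4": (3, 4),
    "c6_c8": (6, 8),
    "c8_c9": (8, 9),
    "after_c9": (9, None),
}


@dataclass(frozen=True)
class AnchoredAlignment:
    """A gapped alignment with reference cysteines in fixed columns.

    ``anchor_columns`` maps each materialized slot to its column (shared by
    all rows); ``rows`` maps record id to its gapped sequence, in input
    order.
    """

    rows: dict[str, str]
    anchor_columns: dict[int, int]

    @property
    def column_count(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def record_ids(self) -> tuple[str, ...]:
        return tuple(self.rows)

    def ungapped(self, record_id: str) -> str:
        return self.rows[record_id].replace(GAP, "")


def _cell_layout(mappings: Sequence[ArrayMapping]):
    """Compute cell widths: N-flank, per-slot-pair regions, C-flank.

    Returns (flank_n_width, region_widths dict {(k, k+1): w},
    flank_c_width, materialized slot set).
    """
    region_w = {(k, k + 1): 0 for k in range(1, 10)}
    flank_n_w = 0
    flank_c_w = 0
    materialized: set[int] = set()
    for m in mappings:
        slots = m.slots
        materialized.update(slots)
        first, last = slots[0], slots[-1]
        flank_len = m.assignment[first]
        if first == 1:
            flank_n_w = max(flank_n_w, flank_len)
        else:
            region_w[(1, 2)] = max(region_w[(1, 2)], flank_len)
        for a, b in zip(slots, slots[1:]):
            region_w[(a, a + 1)] = max(region_w[(a, a + 1)], m.spacing(a, b))
        tail_len = len(m.sequence) - m.assignment[last] - 1
        if last == 10:
            flank_c_w = max(flank_c_w, tail_len)
        else:
            region_w[(last, last + 1)] = max(region_w[(last, last + 1)], tail_len)
    return flank_n_w, region_w, flank_c_w, materialized


def build_anchored_alignment(mappings: Sequence[ArrayMapping]) -> AnchoredAlignment:
    """Build the anchored alignment for a collection of mapped records.

    Anchor columns are placed at the cumulative maxima of per-record region
    lengths; an anchor column exists only for slots assigned in at least
    one record.  Deterministic for identical input.
    """
    if not mappings:
        raise ValueError("cannot align an empty mapping collection")
    seen: set[str] = set()
    for m in mappings:
        if m.record_id in seen:
            raise ValueError(f"duplicate record id {m.record_id!r}")
        seen.add(m.record_id)

    flank_n_w, region_w, flank_c_w, materialized = _cell_layout(mappings)

    # column offsets for each cell, walking F, col1?, r12, col2?, ..., T
    offset = 0
    region_start: dict[tuple[int, int], int] = {}
    col_of_slot: dict[int, int] = {}
    flank_n_start = offset
    offset += flank_n_w
    for k in range(1, 11):
        if k in materialized:
            col_of_slot[k] = offset
            offset += 1
        if k < 10:
            region_start[(k, k + 1)] = offset
            offset += region_w[(k, k + 1)]
    flank_c_start = offset
    offset += flank_c_w
    total = offset

    rows: dict[str, str] = {}
    for m in mappings:
        row = [GAP] * total
        slots = m.slots
        first, last = slots[0], slots[-1]
        seq = m.sequence
        # N-flank: right-justified against col(1) or the C2 anchor
        flank = seq[: m.assignment[first]]
        if first == 1:
            start = flank_n_start + flank_n_w - len(flank)
        else:
            end = region_start[(1, 2)] + region_w[(1, 2)]
            start = end - len(flank)
        row[start : start + len(flank)] = flank
        # anchors and between-slot residues, left-justified
        for s in slots:
            row[col_of_slot[s]] = seq[m.assignment[s]]
        for a, b in zip(slots, slots[1:]):
            segment = seq[m.assignment[a] + 1 : m.assignment[b]]
            start = region_start[(a, a + 1)]
            row[start : start + len(segment)] = segment
        # C-flank: left-justified after the last anchor
        tail = seq[m.assignment[last] + 1 :]
        if last == 10:
            start = flank_c_start
        else:
            start = region_start[(last, last + 1)]
        row[start : start + len(tail)] = tail
        text = "".join(row)
        if text.replace(GAP, "") != seq:
            raise ValueError(
                f"internal layout error for {m.record_id!r}: row does not "
                "ungap to the original sequence"
            )
        rows[m.record_id] = text

    return AnchoredAlignment(rows=rows, anchor_columns=col_of_slot)


def gap_spaces(alignment: AnchoredAlignment, record_id: str, region: str) -> int:
    """Count gap columns in one of the six coding regions of a record's row.

    For interior regions the count is strictly between the two bounding
    anchor columns; for the flank regions it runs from the row start to the
    C2 column (exclusive) or from the C9 column (exclusive) to the row end.
    Raises ``KeyError`` for an unknown region name and ``ValueError`` when a
    bounding slot has no anchor column in this alignment.
    """
    if region not in REGIONS:
        raise KeyError(
            f"unknown region {region!r}; expected one of {sorted(REGIONS)}"
        )
    left, right = REGIONS[region]
    row = alignment.rows[record_id]
    try:
        lo = 0 if left is None else alignment.anchor_columns[left] + 1
        hi = len(row) if right is None else alignment.anchor_columns[right]
    except KeyError as exc:
        raise ValueError(
            f"region {region!r}: slot {exc.args[0]} has no anchor column "
            "in this alignment"
        ) from None
    return row[lo:hi].count(GAP)


def region_gap_spans(
    alignment: AnchoredAlignment, record_id: str
) -> dict[str, int | None]:
    """Gap counts for all six coding regions (None where undefined)."""
    out: dict[str, int | None] = {}
    for name in REGIONS:
        try:
            out[name] = gap_spaces(alignment, record_id, name)
        except ValueError:
            out[name] = None
    return out


def _needs_quoting(label: str) -> bool:
    return not all(ch.isalnum() or ch in "_." for ch in label)


def nexus_label(label: str) -> str:
    """Quote a taxon label per NEXUS token rules when necessary."""
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def export_alignment(
    alignment: AnchoredAlignment, path: str | Path, fmt: str = "fasta"
) -> None:
    """Write the alignment as gapped FASTA or a protein NEXUS DATA block."""
    path = Path(path)
    if not alignment.rows:
        raise ValueError("cannot export an empty alignment")
    if fmt == "fasta":
        with open(path, "w", newline="\n") as fh:
            for rid, row in alignment.rows.items():
                fh.write(f">{rid}\n")
                for i in range(0, len(row), 60):
                    fh.write(row[i : i + 60] + "\n")
    elif fmt == "nexus":
        ntax = len(alignment.rows)
        nchar = alignment.column_count
        width = max(len(nexus_label(r)) for r in alignment.rows)
        with open(path, "w", newline="\n") as fh:
            fh.write("#NEXUS\n")
            fh.write("BEGIN DATA;\n")
            fh.write(f"    DIMENSIONS NTAX={ntax} NCHAR={nchar};\n")
            fh.write(
                "    FORMAT DATATYPE=PROTEIN GAP=- MISSING=? INTERLEAVE=NO;\n"
            )
            fh.write("    MATRIX\n")
            for rid, row in alignment.rows.items():
                fh.write(f"        {nexus_label(rid):<{width}}  {row}\n")
            fh.write("    ;\n")
            fh.write("END;\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'fasta' or 'nexus'")
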
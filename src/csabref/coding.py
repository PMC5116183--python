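"""AdDLP-relative indel coding and partitioned NEXUS export.

AdDLP (*Anaeromyxobacter dehalogenans* defensin-like peptide) is the
hypothesized ancestor of the CS-αβ superfamily, so insertions and deletions
relative to it are informative characters.  Six areas of the anchored
alignment are coded against AdDLP's lengths — (1) 3 residues upstream of
C2, (2) 17 gap spaces between C2 and C3, (3) 3 residues between C3 and C4,
(4) 11 gap spaces between C6 and C8, (5) 1 residue between C8 and C9,
(6) 9 residues after C9 — with observed < reference → 0, equal → 1,
greater → 2.  Areas 1, 3, 5 and 6 count the record's own residues; areas 2
and 4 count gap columns in the anchored alignment.  Any area touching a
slot the record lacks is coded '-'.  N- and C-terminal propeptides are
coded present = 1, absent = 0, unknown = '-'.

The resulting matrix is exported as a single mixed-datatype NEXUS DATA
block (protein + standard spans) with charset/partition definitions and,
on request, a MrBayes settings block.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .alignment import AnchoredAlignment, gap_spaces, nexus_label
from .mapping import ArrayMapping
from .records import PeptideRecord

#: AdDLP's area lengths, in the fixed area order 1–6.
ADDLP_REFERENCE_LENGTHS = (3, 17, 3, 11, 1, 9)

#: (area name, slots the area touches, counting rule) in area order.
_AREA_SLOTS = (
    ("flank_c2", (2,)),
    ("c2_c3", (2, 3)),
    ("c3_c4", (3, 4)),
    ("c6_c8", (6, 8)),
    ("c8_c9", (8, 9)),
    ("after_c9", (9,)),
)

INDEL_SYMBOLS = frozenset("012-")
PRO_SYMBOLS = frozenset("01-")


@dataclass(frozen=True)
class IndelCodeScheme:
    """Reference lengths for the six areas plus the three-way code rule."""

    reference_lengths: tuple[int, int, int, int, int, int] = ADDLP_REFERENCE_LENGTHS

    def code(self, area: int, observed: int) -> str:
        """Code one observed length against area ``area`` (1-based)."""
        ref = self.reference_lengths[area - 1]
        if observed < ref:
            return "0"
        if observed == ref:
            return "1"
        return "2"


def code_indels(
    mapping: ArrayMapping,
    alignment: AnchoredAlignment,
    scheme: IndelCodeScheme | None = None,
) -> str:
    """Six-character indel code string for one mapped, aligned record.

    Areas 1, 3, 5, 6 are coded from the record's residue counts (upstream
    of its C2; between C3/C4; between C8/C9; after C9) and areas 2, 4 from
    gap spaces in the anchored alignment.  An area touching an unassigned
    slot is '-'.
    """
    scheme = scheme or IndelCodeScheme()
    if mapping.record_id not in alignment.rows:
        raise KeyError(f"record {mapping.record_id!r} is not in the alignment")
    a = mapping.assignment
    codes: list[str] = []
    for area_number, (region, touched) in enumerate(_AREA_SLOTS, start=1):
        if any(s not in a for s in touched):
            codes.append("-")
            continue
        if region == "flank_c2":
            observed = a[2]  # residues upstream of the record's C2
        elif region == "c3_c4":
            observed = mapping.spacing(3, 4)
        elif region == "c8_c9":
            observed = mapping.spacing(8, 9)
        elif region == "after_c9":
            observed = len(mapping.sequence) - a[9] - 1
        else:  # c2_c3, c6_c8 are defined as alignment gap spaces
            observed = gap_spaces(alignment, mapping.record_id, region)
        codes.append(scheme.code(area_number, observed))
    return "".join(codes)


def code_propeptides(record: PeptideRecord) -> str:
    """Two-character propeptide code: N-terminal then C-terminal."""
    return record.has_n_propeptide.code + record.has_c_propeptide.code


@dataclass(frozen=True)
class CharacterMatrix:
    """Protein + indel + propeptide characters, ready for NEXUS export.

    Columns are ordered protein block (the gapped alignment), then the six
    indel codes, then the two propeptide codes; ``spans`` gives the 1-based
    inclusive character ranges of the three partitions.
    """

    taxa: tuple[str, ...]
    protein_rows: dict[str, str]
    indel_rows: dict[str, str]
    pro_rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("empty character matrix")
        lengths = {len(self.protein_rows[t]) for t in self.taxa}
        if len(lengths) != 1:
            raise ValueError(f"protein rows have unequal lengths {sorted(lengths)}")
        for t in self.taxa:
            if len(self.indel_rows[t]) != 6 or set(self.indel_rows[t]) - INDEL_SYMBOLS:
                raise ValueError(f"bad indel codes for {t!r}: {self.indel_rows[t]!r}")
            if len(self.pro_rows[t]) != 2 or set(self.pro_rows[t]) - PRO_SYMBOLS:
                raise ValueError(f"bad propeptide codes for {t!r}: {self.pro_rows[t]!r}")

    @property
    def n_protein(self) -> int:
        return len(self.protein_rows[self.taxa[0]])

    @property
    def nchar(self) -> int:
        return self.n_protein + 8

    @property
    def spans(self) -> dict[str, tuple[int, int]]:
        n = self.n_protein
        return {"protein": (1, n), "indel": (n + 1, n + 6), "pro": (n + 7, n + 8)}

    def row(self, taxon: str) -> str:
        return self.protein_rows[taxon] + self.indel_rows[taxon] + self.pro_rows[taxon]


def build_matrix(
    alignment: AnchoredAlignment,
    indel_codes: Mapping[str, str],
    pro_codes: Mapping[str, str],
) -> CharacterMatrix:
    """Assemble the partitioned matrix from alignment rows and code maps."""
    taxa = alignment.record_ids
    missing = [t for t in taxa if t not in indel_codes or t not in pro_codes]
    if missing:
        raise ValueError(f"missing character codes for records {missing}")
    return CharacterMatrix(
        taxa=taxa,
        protein_rows={t: alignment.rows[t] for t in taxa},
        indel_rows={t: indel_codes[t] for t in taxa},
        pro_rows={t: pro_codes[t] for t in taxa},
    )


_MRBAYES_BLOCK = """\
BEGIN MRBAYES;
    charset protein = {p_lo}-{p_hi};
    charset indel = {i_lo}-{i_hi};
    charset pro = {r_lo}-{r_hi};
    partition byclass = 3: protein, indel, pro;
    set partition = byclass;
    lset applyto=(1) rates=invgamma;
    prset applyto=(1) aamodelpr=mixed;
    lset applyto=(2,3) rates=gamma;
    prset applyto=(1,2,3) ratepr=variable;
    [ run settings used interactively, not executed by this file: ]
    [ mcmc ngen=2000000 temp=0.5; ]
END;
"""


def write_nexus(
    matrix: CharacterMatrix,
    path: str | Path,
    include_mrbayes_block: bool = False,
) -> None:
    """Write the partitioned matrix as mixed-datatype NEXUS (MrBayes dialect).

    One DATA block declares DATATYPE=MIXED with a PROTEIN span for the
    alignment and a STANDARD span for the indel + propeptide codes, GAP=-
    MISSING=?.  In the standard span '-' visually preserves the published
    missing-data coding (a header comment says so; parsers read it as gap,
    which MrBayes treats as missing for standard data).  Charsets for the
    three partitions are written in a SETS block and, when
    ``include_mrbayes_block`` is set, a MrBayes command block carries the
    published lset/prset/ratepr settings.  Output bytes are deterministic.
    """
    path = Path(path)
    spans = matrix.spans
    p_lo, p_hi = spans["protein"]
    i_lo, i_hi = spans["indel"]
    r_lo, r_hi = spans["pro"]
    width = max(len(nexus_label(t)) for t in matrix.taxa)
    lines = [
        "#NEXUS",
        "[ CS-αβ reference-array character matrix ]",
        "[ protein span uses GAP=- MISSING=?; in the standard span '-' ]",
        "[ denotes missing or unknown data, per the published coding ]",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.nchar};",
        f"    FORMAT DATATYPE=MIXED(PROTEIN:{p_lo}-{p_hi},STANDARD:{i_lo}-{r_hi})"
        " GAP=- MISSING=? INTERLEAVE=NO;",
        "    MATRIX",
    ]
    for taxon in matrix.taxa:
        lines.append(f"        {nexus_label(taxon):<{width}}  {matrix.row(taxon)}")
    lines += [
        "    ;",
        "END;",
        "BEGIN SETS;",
        f"    CHARSET protein = {p_lo}-{p_hi};",
        f"    CHARSET indel = {i_lo}-{i_hi};",
        f"    CHARSET pro = {r_lo}-{r_hi};",
        "END;",
    ]
    text = "\n".join(lines) + "\n"
    if include_mrbayes_block:
        text += _MRBAYES_BLOCK.format(
            p_lo=p_lo, p_hi=p_hi, i_lo=i_lo, i_hi=i_hi, r_lo=r_lo, r_hi=r_hi
        )
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write(text)


_DIM_RE = re.compile(r"DIMENSIONS\s+NTAX=(\d+)\s+NCHAR=(\d+)", re.I)
_MIXED_RE = re.compile(r"DATATYPE=MIXED\(PROTEIN:(\d+)-(\d+),STANDARD:(\d+)-(\d+)\)", re.I)
_CHARSET_RE = re.compile(r"CHARSET\s+(\w+)\s*=\s*(\d+)-(\d+)\s*;", re.I)


def read_nexus_matrix(path: str | Path) -> CharacterMatrix:
    """Parse a matrix written by :func:`write_nexus` back into memory.

    Supports exactly this package's mixed-datatype dialect (general NEXUS
    readers do not accept MIXED matrices); used as the round-trip check
    that written files re-parse to identical taxa, spans and characters.
    """
    text = Path(path).read_text(encoding="utf-8")
    no_comments = re.sub(r"\[[^\]]*\]", "", text)
    dim = _DIM_RE.search(no_comments)
    mixed = _MIXED_RE.search(no_comments)
    charsets = {
        name.lower(): (int(lo), int(hi))
        for name, lo, hi in _CHARSET_RE.findall(no_comments)
    }
    if not dim or not mixed:
        raise ValueError(f"{path}: not a csabref mixed-datatype NEXUS file")
    ntax, nchar = int(dim.group(1)), int(dim.group(2))
    n_protein = int(mixed.group(2))
    matrix_part = no_comments.split("MATRIX", 1)[1].split(";", 1)[0]
    taxa: list[str] = []
    protein: dict[str, str] = {}
    indel: dict[str, str] = {}
    pro: dict[str, str] = {}
    for line in matrix_part.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            end = line.index("'", 1)
            while line[end : end + 2] == "''":
                end = line.index("'", end + 2)
            taxon = line[1:end].replace("''", "'")
            row = line[end + 1 :].strip()
        else:
            taxon, row = line.split(None, 1)
            row = row.strip()
        if len(row) != nchar:
            raise ValueError(f"{path}: row for {taxon!r} has {len(row)} != {nchar} chars")
        taxa.append(taxon)
        protein[taxon] = row[:n_protein]
        i_lo, i_hi = charsets["indel"]
        r_lo, r_hi = charsets["pro"]
        indel[taxon] = row[i_lo - 1 : i_hi]
        pro[taxon] = row[r_lo - 1 : r_hi]
    if len(taxa) != ntax:
        raise ValueError(f"{path}: found {len(taxa)} taxa, header says {ntax}")
    return CharacterMatrix(
        taxa=tuple(taxa), protein_rows=protein, indel_rows=indel, pro_rows=pro
    )
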
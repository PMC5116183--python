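"""Sequence-level motif detection: cysteines, the γ-core, CSH spacing.

The γ-core is an 8–16 residue motif of cysteine-containing defense peptides
that generally contains a conserved GXC (or mirrored CXG) whose cysteine
aligns with reference slot C6 in the CS-αβ superfamily.  Detection here is
purely sequence based — no structure prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

from .records import PeptideRecord

if TYPE_CHECKING:  # pragma: no cover
    from .mapping import ArrayMapping

GAMMA_MIN = 8          # γ-core envelope, residues
GAMMA_MAX = 16
CSH_SPACING_34 = 3     # residues between C3 and C4, standard for the motif
CSH_SPACING_89 = 1     # residues between C8 and C9, standard for the motif


@dataclass(frozen=True)
class CysteineProfile:
    """Ordered 0-based positions of every literal 'C' in a sequence."""

    positions: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class GammaCoreHit:
    """One candidate γ-core.

    ``span`` is a 0-based half-open window of 8–16 residues containing the
    tripattern; ``core_cys`` is the position of the C in GXC/CXG.  ``kcxn``
    flags the channel-toxin signature: the four residues starting one before
    the core read K, C, any, N.  Hits within 8 residues of a terminus are
    reported with ``truncated=True`` rather than dropped.
    """

    span: tuple[int, int]
    core_cys: int
    orientation: str  # "GXC" or "CXG"
    kcxn: bool
    truncated: bool = False

    def __post_init__(self) -> None:
        start, end = self.span
        if not self.truncated and not (GAMMA_MIN <= end - start <= GAMMA_MAX):
            raise ValueError(f"γ-core span length {end - start} outside 8–16")
        if not (start <= self.core_cys < end):
            raise ValueError("core cysteine outside span")


def cysteine_profile(record: PeptideRecord) -> CysteineProfile:
    """Locate every literal 'C' (ambiguity codes and 'U' never count)."""
    return CysteineProfile(
        positions=tuple(i for i, ch in enumerate(record.sequence) if ch == "C")
    )


def _window(seq_len: int, tri_start: int) -> tuple[tuple[int, int], bool]:
    """Maximal ≤16-residue window centered on the tripattern, clipped.

    Returns the span and whether it had to be truncated below 8 residues.
    """
    center = tri_start + 1
    start = max(0, center - GAMMA_MAX // 2)
    end = min(seq_len, start + GAMMA_MAX)
    start = max(0, end - GAMMA_MAX)
    # keep the tripattern inside the window (always true by construction,
    # but guard against pathological short sequences)
    start = min(start, tri_start)
    end = max(end, tri_start + 3) if seq_len >= tri_start + 3 else seq_len
    truncated = (end - start) < GAMMA_MIN
    return (start, end), truncated


def find_gamma_core(
    record: PeptideRecord, profile: CysteineProfile | None = None
) -> list[GammaCoreHit]:
    """Report every GXC / CXG tripattern as a candidate γ-core hit.

    All candidates are returned, sorted by core cysteine position; choosing
    among them (anchoring at slot 6 or 7) is the mapper's job.  The KCXN
    check uses exact residues K and N with no substitution tolerance.
    """
    seq = record.sequence
    hits: list[GammaCoreHit] = []
    for i in range(len(seq) - 2):
        tri = seq[i : i + 3]
        if tri[0] == "G" and tri[2] == "C":
            orientation, core = "GXC", i + 2
        elif tri[0] == "C" and tri[2] == "G":
            orientation, core = "CXG", i
        else:
            continue
        span, truncated = _window(len(seq), i)
        kcxn = (
            core - 1 >= 0
            and core + 2 < len(seq)
            and seq[core - 1] == "K"
            and seq[core] == "C"
            and seq[core + 2] == "N"
        )
        hits.append(
            GammaCoreHit(
                span=span,
                core_cys=core,
                orientation=orientation,
                kcxn=kcxn,
                truncated=truncated,
            )
        )
    hits.sort(key=lambda h: (h.core_cys, h.orientation))
    return hits


def n_loop_length(mapping: "ArrayMapping") -> int | None:
    """Residues strictly between the C2 and C3 slots (the variable n-loop).

    Returns ``None`` when either slot is unassigned (e.g. AdDLP-like
    CSH-only peptides, which have no C2).
    """
    a = mapping.assignment
    if 2 not in a or 3 not in a:
        return None
    return a[3] - a[2] - 1


def csh_spacing_ok(mapping: "ArrayMapping") -> bool:
    """True iff the CSH spacings are standard: C3–C4 = 3 and C8–C9 = 1.

    Raises ``ValueError`` when any CSH slot (3, 4, 8, 9) is unassigned,
    signalling a non-CSH input.
    """
    a = mapping.assignment
    missing = [s for s in (3, 4, 8, 9) if s not in a]
    if missing:
        raise ValueError(
            f"not a CSH mapping: slots {missing} unassigned for {mapping.record_id!r}"
        )
    return (
        a[4] - a[3] - 1 == CSH_SPACING_34 and a[9] - a[8] - 1 == CSH_SPACING_89
    )
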
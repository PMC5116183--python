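"""Assignment of peptide cysteines to the ten-slot reference array.

Most CS-αβ peptides have 6–10 cysteines; aligning them to a single
ten-cysteine reference array (slots C1–C10) makes their structural
correspondence explicit: slots 3, 4, 8, 9 form the cysteine-stabilized
α-helix (CSH) motif, slots 2 and 6 complete the CS-αβ fold's third bond,
and the γ-core cysteine generally occupies slot 6 (slot 7 in mytilins).

The literature performs this alignment by eye; here it is an explicit
combinatorial optimization.  Every order-preserving assignment of cysteines
to slots (unassigned cysteines become "extras") is scored:

* +8 for a γ-core cysteine anchored at slot 6 (or at slot 7 when the
  mytilin exception applies: slots 3/4/8/9 assigned at exact CSH spacings
  and no γ-anchored slot 6);
* +4 for each exact CSH spacing (3 residues between C3/C4, 1 between
  C8/C9);
* +3 for an exact family-template slot-set match, reduced by 1 per residue
  of deviation from the template's canonical region-length ranges and
  floored at zero, so a deviating match never scores below no match
  (deviation is measured against the best-fitting template when two share
  a slot set);
* −2 per extra (unslotted) cysteine.

Ties are broken by preferring a template match, then minimal deviation,
then the leftmost assignment (lexicographically smallest slot then
position tuples).  The optimizer enumerates all assignments with vectorized
scoring, so it is exactly equivalent to brute force.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .families import TEMPLATES, FamilyTemplate, templates_by_slots
from .motifs import CysteineProfile, GammaCoreHit, cysteine_profile, find_gamma_core, n_loop_length
from .records import PeptideRecord

_BIG_DEV = 10**6
MAX_CYSTEINES = 12  # macin envelope is 8–12; beyond that is outside the model


class MappingError(ValueError):
    """Raised when a sequence cannot be mapped to the reference array."""


@dataclass(frozen=True)
class ArrayMapping:
    """An assignment of observed cysteines to reference slots C1–C10.

    ``assignment`` maps slot number → 0-based residue position, strictly
    increasing in position with slot number.  Cysteines not assigned to a
    slot appear in ``extras`` as ``(label, position)`` pairs, labelled
    ``C^i/j^`` when between assigned slots i and j, ``C^/f^`` before the
    first assigned slot and ``C^l/^`` after the last.  ``regions`` holds the
    compact spacer token for each consecutive assigned-slot pair (key
    ``"i-j"``) plus ``"flank_n"``/``"flank_c"``.  ``anchor_used`` records
    which slot (6 or 7), if any, was anchored by a γ-core cysteine.
    """

    record_id: str
    sequence: str
    assignment: dict[int, int]
    extras: tuple[tuple[str, int], ...] = ()
    regions: dict[str, str] = field(default_factory=dict)
    anchor_used: int | None = None

    def __post_init__(self) -> None:
        slots = sorted(self.assignment)
        positions = [self.assignment[s] for s in slots]
        if positions != sorted(set(positions)):
            raise MappingError("slot positions must be strictly increasing")
        for pos in positions:
            if self.sequence[pos] != "C":
                raise MappingError(f"slot residue at {pos} is not a cysteine")
        all_cys = {i for i, ch in enumerate(self.sequence) if ch == "C"}
        covered = set(positions) | {p for _, p in self.extras}
        if covered != all_cys:
            raise MappingError(
                "conservation violated: every cysteine must be assigned or extra"
            )

    @property
    def slots(self) -> tuple[int, ...]:
        return tuple(sorted(self.assignment))

    @property
    def slot_set(self) -> frozenset[int]:
        return frozenset(self.assignment)

    def spacing(self, i: int, j: int) -> int:
        """Residues strictly between the cysteines at slots i and j."""
        return self.assignment[j] - self.assignment[i] - 1


@dataclass(frozen=True)
class Bond:
    """One disulfide assignment between two cysteines.

    Endpoints are reference-slot numbers (int) or extra-cysteine labels
    (str, e.g. ``"C^3/4^"``).  ``status`` is ``verified`` (experimental),
    ``inferred`` (from family homology) or ``unknown``.
    """

    left: int | str
    right: int | str
    status: str

    def __post_init__(self) -> None:
        if isinstance(self.left, int) and isinstance(self.right, int):
            if not self.left < self.right:
                raise ValueError("slot bonds must have left < right")
        if self.status not in ("verified", "inferred", "unknown"):
            raise ValueError(f"illegal bond status {self.status!r}")


@dataclass(frozen=True)
class BondSet:
    """Bonds plus cysteines whose bonding is unknown (unpaired)."""

    bonds: tuple[Bond, ...] = ()
    unknown_singles: tuple[int | str, ...] = ()

    def __post_init__(self) -> None:
        seen: set = set()
        for b in self.bonds:
            for ep in (b.left, b.right):
                if ep in seen:
                    raise ValueError(f"cysteine {ep!r} appears in two bonds")
                seen.add(ep)


@dataclass(frozen=True)
class FamilyLabel:
    """A spacing-family classification plus a free-text confidence note."""

    label: str
    note: str = ""


# ---------------------------------------------------------------------------
# slot-assignment optimizer
# ---------------------------------------------------------------------------


def _gamma_cys_positions(
    record: PeptideRecord, profile: CysteineProfile, hits: list[GammaCoreHit]
) -> frozenset[int]:
    cys = set(profile.positions)
    return frozenset(h.core_cys for h in hits if h.core_cys in cys)


def map_to_reference(
    record: PeptideRecord,
    profile: CysteineProfile | None = None,
    gamma_hits: list[GammaCoreHit] | None = None,
    *,
    mytilin_exception: bool = True,
) -> ArrayMapping:
    """Optimal order-preserving assignment of cysteines to slots C1–C10.

    Raises :class:`MappingError` for sequences with fewer than 2 cysteines
    (not a candidate CS-αβ sequence) or more than 12 (outside the
    superfamily envelope modelled; even ten-cysteine macins carry at most
    two extras).  Deterministic: equal inputs give identical mappings.
    """
    if profile is None:
        profile = cysteine_profile(record)
    if profile.count < 2:
        raise MappingError(
            f"record {record.id!r}: {profile.count} cysteine(s); "
            "not a candidate CS-αβ sequence (need ≥ 2)"
        )
    if profile.count > MAX_CYSTEINES:
        raise MappingError(
            f"record {record.id!r}: {profile.count} cysteines exceed the "
            f"{MAX_CYSTEINES}-cysteine envelope modelled here; even "
            "ten-cysteine macins have at most two extras. Check that the "
            "input is a single mature peptide."
        )
    if gamma_hits is None:
        gamma_hits = find_gamma_core(record, profile)
    gamma_set = _gamma_cys_positions(record, profile, gamma_hits)

    slots, positions = _optimize(
        profile.positions, gamma_set, mytilin_exception=mytilin_exception
    )
    return _build_mapping(record, profile, slots, positions, gamma_set)


def _optimize(
    cys_positions: tuple[int, ...],
    gamma_set: frozenset[int],
    *,
    mytilin_exception: bool,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Enumerate and score all assignments; return (slots, positions)."""
    k = len(cys_positions)
    pos = np.asarray(cys_positions)
    in_gamma = np.array([p in gamma_set for p in cys_positions])
    slot_index = templates_by_slots()

    per_m: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    best_score = None
    for m in range(1, min(k, 10) + 1):
        cys_combos = np.array(list(itertools.combinations(range(k), m)))
        slot_combos = np.array(list(itertools.combinations(range(1, 11), m)))
        n_s, n_c = len(slot_combos), len(cys_combos)
        P = pos[cys_combos]                     # (C, m) residue positions
        G = in_gamma[cys_combos]                # (C, m) γ-core membership
        sp = P[:, 1:] - P[:, :-1] - 1 if m > 1 else np.empty((n_c, 0), int)

        score = np.full((n_s, n_c), -2 * (k - m), dtype=np.int64)

        ok34 = np.zeros((n_s, n_c), bool)
        ok89 = np.zeros((n_s, n_c), bool)
        has34 = np.zeros(n_s, bool)
        has89 = np.zeros(n_s, bool)
        for j in range(m - 1):
            r34 = (slot_combos[:, j] == 3) & (slot_combos[:, j + 1] == 4)
            if r34.any():
                ok34[r34] = sp[:, j] == 3
                has34 |= r34
                score[r34] += 4 * (sp[:, j] == 3)
            r89 = (slot_combos[:, j] == 8) & (slot_combos[:, j + 1] == 9)
            if r89.any():
                ok89[r89] = sp[:, j] == 1
                has89 |= r89
                score[r89] += 4 * (sp[:, j] == 1)

        g6 = np.zeros((n_s, n_c), bool)
        g7 = np.zeros((n_s, n_c), bool)
        for j in range(m):
            r6 = slot_combos[:, j] == 6
            if r6.any():
                g6[r6] = G[:, j]
            r7 = slot_combos[:, j] == 7
            if r7.any():
                g7[r7] = G[:, j]
        csh_exact = (has34[:, None] & ok34) & (has89[:, None] & ok89)
        anchor = np.where(g6, 8, 0)
        if mytilin_exception:
            anchor = np.where(~g6 & g7 & csh_exact, 8, anchor)
        score += anchor

        dev = np.full((n_s, n_c), _BIG_DEV, dtype=np.int64)
        match = np.zeros(n_s, bool)
        for si in range(n_s):
            fs = frozenset(int(s) for s in slot_combos[si])
            candidates = slot_index.get(fs)
            if not candidates:
                continue
            best_dev = None
            for t in candidates:
                order = t.slot_order
                d = np.zeros(n_c, dtype=np.int64)
                for idx, pair in enumerate(zip(order, order[1:])):
                    lo, hi = t.regions[pair]
                    g = sp[:, idx]
                    d += np.clip(lo - g, 0, None) + np.clip(g - hi, 0, None)
                best_dev = d if best_dev is None else np.minimum(best_dev, d)
            dev[si] = best_dev
            match[si] = True
            score[si] += np.maximum(0, 3 - best_dev)

        per_m.append((slot_combos, cys_combos, score, dev, match))
        m_max = int(score.max())
        if best_score is None or m_max > best_score:
            best_score = m_max

    # gather every assignment achieving the optimum, then tie-break
    candidates = []
    for slot_combos, cys_combos, score, dev, match in per_m:
        for si, ci in np.argwhere(score == best_score):
            slots = tuple(int(s) for s in slot_combos[si])
            p = tuple(int(pos[c]) for c in cys_combos[ci])
            d = int(dev[si, ci])
            candidates.append(((not bool(match[si]), d, slots, p), slots, p))
    candidates.sort(key=lambda item: item[0])
    _, slots, positions = candidates[0]
    return slots, positions


def _extra_label(p: int, assignment: dict[int, int]) -> str:
    prev_slot = None
    next_slot = None
    for slot in sorted(assignment):
        if assignment[slot] < p:
            prev_slot = slot
        elif assignment[slot] > p and next_slot is None:
            next_slot = slot
    left = "" if prev_slot is None else str(prev_slot)
    right = "" if next_slot is None else str(next_slot)
    return f"C^{left}/{right}^"


def _build_mapping(
    record: PeptideRecord,
    profile: CysteineProfile,
    slots: tuple[int, ...],
    positions: tuple[int, ...],
    gamma_set: frozenset[int],
) -> ArrayMapping:
    assignment = dict(zip(slots, positions))
    assigned = set(positions)
    extras = tuple(
        (_extra_label(p, assignment), p)
        for p in profile.positions
        if p not in assigned
    )
    anchor_used = None
    for anchor_slot in (6, 7):
        if assignment.get(anchor_slot) in gamma_set:
            anchor_used = anchor_slot
            break
    regions = _region_tokens(record.sequence, assignment)
    return ArrayMapping(
        record_id=record.id,
        sequence=record.sequence,
        assignment=assignment,
        extras=extras,
        regions=regions,
        anchor_used=anchor_used,
    )


# ---------------------------------------------------------------------------
# compact spacing notation
# ---------------------------------------------------------------------------


def _encode_segment(segment: str) -> str:
    """Spacer token for the residues between two boxed cysteines.

    Run lengths of non-cysteine residues become decimal digits and each
    extra cysteine a literal ``C``; an empty segment is ``"0"`` (adjacent
    boxed cysteines).  So ``XXC`` → ``2C`` (pattern CXXCC between boxes).
    """
    if not segment:
        return "0"
    parts: list[str] = []
    run = 0
    for ch in segment:
        if ch == "C":
            if run:
                parts.append(str(run))
                run = 0
            parts.append("C")
        else:
            run += 1
    if run:
        parts.append(str(run))
    return "".join(parts)


def _region_tokens(sequence: str, assignment: dict[int, int]) -> dict[str, str]:
    slots = sorted(assignment)
    tokens: dict[str, str] = {}
    first, last = assignment[slots[0]], assignment[slots[-1]]
    tokens["flank_n"] = _encode_segment(sequence[:first]) if first else ""
    tokens["flank_c"] = (
        _encode_segment(sequence[last + 1 :]) if last + 1 < len(sequence) else ""
    )
    for a, b in zip(slots, slots[1:]):
        segment = sequence[assignment[a] + 1 : assignment[b]]
        tokens[f"{a}-{b}"] = _encode_segment(segment)
    return tokens


def encode_notation(mapping: ArrayMapping) -> str:
    """Render the box/spacer notation for a mapping.

    Assigned slots are filled boxes ``[Cn]``, unassigned slots within and
    around the array explicit empty boxes ``[]``, spacer tokens use the
    digit/``C`` grammar of :func:`decode_notation`, and flank tokens
    carry residues (and terminal extra cysteines) outside the outermost
    assigned slots.  Tokens are joined with ``-``.
    """
    slots = mapping.slots
    parts: list[str] = []
    parts.extend("[]" for _ in range(1, slots[0]))
    if mapping.regions.get("flank_n"):
        parts.append(mapping.regions["flank_n"])
    parts.append(f"[C{slots[0]}]")
    for a, b in zip(slots, slots[1:]):
        parts.append(mapping.regions[f"{a}-{b}"])
        parts.extend("[]" for _ in range(a + 1, b))
        parts.append(f"[C{b}]")
    if mapping.regions.get("flank_c"):
        parts.append(mapping.regions["flank_c"])
    parts.extend("[]" for _ in range(slots[-1] + 1, 11))
    return "-".join(parts)


def decode_notation(token: str) -> str:
    """Expand a spacer token to the C/X pattern between its two boxes.

    Exact inverse of the encoding: ``"2C"`` → ``"CXXCC"``, ``"C2C"`` →
    ``"CCXXCC"``, ``"2C1"`` → ``"CXXCXC"``, ``"0"`` → ``"CC"``.
    """
    if not token or any(ch not in "0123456789C" for ch in token):
        raise ValueError(f"illegal spacer token {token!r}: digits and C only")
    middle: list[str] = []
    num = ""
    for ch in token:
        if ch.isdigit():
            num += ch
        else:
            if num:
                middle.append("X" * int(num))
                num = ""
            middle.append("C")
    if num:
        middle.append("X" * int(num))
    return "C" + "".join(middle) + "C"


# ---------------------------------------------------------------------------
# family classification and bond inference
# ---------------------------------------------------------------------------


def classify_family(
    mapping: ArrayMapping, *, long_extension_threshold: int = 10
) -> FamilyLabel:
    """Classify a mapping against the family spacing templates.

    An exact slot-set match yields that family; the drosomycin/plant versus
    long-chain-toxin pair (identical slot sets) is split on the C9–C10
    spacing: more than ``long_extension_threshold`` residues indicates the
    long C-terminal extension of long-chain scorpion toxins.  A mapping
    matching no template is ``unassigned`` with the nearest template named
    in the note.  Extra cysteines never block classification (macins run to
    12 cysteines) but are mentioned in the note.
    """
    slot_set = mapping.slot_set
    matches = [t for t in TEMPLATES.values() if t.slots == slot_set]
    notes: list[str] = []
    if mapping.extras:
        labels = ", ".join(label for label, _ in mapping.extras)
        notes.append(f"extra cysteines: {labels}")
    if not matches:
        nearest = min(
            TEMPLATES.values(),
            key=lambda t: (len(t.slots ^ slot_set), t.name),
        )
        notes.insert(0, f"no template match; nearest is {nearest.name}")
        return FamilyLabel(label="unassigned", note="; ".join(notes))
    if len(matches) > 1:
        # drosomycin/plant vs long-chain toxin: same slots, different C9–C10
        extension = mapping.spacing(9, 10)
        chosen = (
            TEMPLATES["longchain_toxin"]
            if extension > long_extension_threshold
            else TEMPLATES["drosomycin_plant"]
        )
        notes.insert(0, f"C9–C10 spacing {extension}")
    else:
        chosen = matches[0]
    if chosen.note:
        notes.append(chosen.note)
    return FamilyLabel(label=chosen.name, note="; ".join(notes))


def infer_bonds(
    mapping: ArrayMapping,
    family: FamilyLabel,
    verified: set[tuple[int, int]] | None = None,
) -> BondSet:
    """Disulfide assignments implied by the family template.

    Template bonds get status ``inferred`` (homology-based, nothing more);
    pairs listed in ``verified`` are upgraded.  Assigned slots outside any
    template bond, and all extra cysteines, are reported with status
    ``unknown``; when exactly two extras remain they are listed as one
    hypothesized pair (the mytimacin-5 convention, where an even cysteine
    count suggests an additional bond).
    """
    verified = verified or set()
    bonds: list[Bond] = []
    paired: set[int] = set()
    template = TEMPLATES.get(family.label)
    if template is not None:
        for i, j in template.bonds:
            if i not in mapping.assignment or j not in mapping.assignment:
                raise MappingError(
                    f"template bond C{i}–C{j} references an unassigned slot "
                    f"for {mapping.record_id!r} (template/assignment mismatch)"
                )
            status = "verified" if (i, j) in verified else "inferred"
            bonds.append(Bond(i, j, status))
            paired.update((i, j))
    singles: list[int | str] = [s for s in mapping.slots if s not in paired]
    extra_labels = [label for label, _ in mapping.extras]
    if len(extra_labels) == 2:
        bonds.append(Bond(extra_labels[0], extra_labels[1], "unknown"))
    else:
        singles.extend(extra_labels)
    return BondSet(bonds=tuple(bonds), unknown_singles=tuple(singles))


#: Conventional listing order: the three core bonds first, then the
#: family-specific peripheral bonds, then anything else.
_BOND_ORDER = {
    (2, 6): 0,
    (3, 8): 1,
    (4, 9): 2,
    (2, 7): 3,
    (1, 7): 4,
    (5, 10): 5,
    (1, 10): 6,
}


def _bond_sort_key(bond: Bond):
    if isinstance(bond.left, int) and isinstance(bond.right, int):
        pair = (bond.left, bond.right)
        return (0, _BOND_ORDER.get(pair, 100), pair)
    return (1, 0, (str(bond.left), str(bond.right)))


def _endpoint_name(ep: int | str) -> str:
    return f"C{ep}" if isinstance(ep, int) else str(ep)


def describe_bonds(bondset: BondSet) -> str:
    """Render a bond set in the reference-array description grammar.

    Verified bonds appear bare; inferred and unknown assignments are
    grouped in one trailing parenthesis (bonds first, then unpaired
    cysteines), e.g. theromacin: ``(C2–C6, C3–C8, C4–C9, C1–C7, C5–C10)``.
    An en-dash joins bond partners; items are comma-space separated.
    """
    verified = sorted((b for b in bondset.bonds if b.status == "verified"), key=_bond_sort_key)
    other = sorted((b for b in bondset.bonds if b.status != "verified"), key=_bond_sort_key)

    def render(bond: Bond) -> str:
        return f"{_endpoint_name(bond.left)}–{_endpoint_name(bond.right)}"

    parts = [render(b) for b in verified]
    grouped = [render(b) for b in other]
    grouped.extend(
        _endpoint_name(s)
        for s in sorted(
            bondset.unknown_singles,
            key=lambda s: (isinstance(s, str), s if isinstance(s, str) else f"{s:02d}"),
        )
    )
    if grouped:
        parts.append("(" + ", ".join(grouped) + ")")
    return ", ".join(parts)


def toxin_flag(
    mapping: ArrayMapping,
    gamma_hit: GammaCoreHit | None,
    family: FamilyLabel | None = None,
    *,
    short_nloop_threshold: int = 6,
) -> bool:
    """Heuristic channel-toxin signal: KCXN in the γ-core plus a short n-loop.

    True iff the given γ-core hit anchors slot C6, carries the KCXN
    signature, and the n-loop (C2–C3) is at most ``short_nloop_threshold``
    residues.  This is a sequence heuristic, never an activity claim: the
    source evidence is that KCXN-bearing peptides with short n-loops (e.g.
    charybdotoxin, GKCMN) tend to be channel toxins while GYCAG-type cores
    are not.  False whenever the preconditions are unmet.
    """
    if gamma_hit is None or 6 not in mapping.assignment:
        return False
    if mapping.assignment[6] != gamma_hit.core_cys or not gamma_hit.kcxn:
        return False
    n_loop = n_loop_length(mapping)
    return n_loop is not None and n_loop <= short_nloop_threshold
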
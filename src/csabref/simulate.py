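"""Seeded generator of CS-αβ-like peptides for every family template.

Sequences are built directly from a :class:`~csabref.families.FamilyTemplate`:
cysteines are planted exactly at template-implied relative positions,
inter-slot region lengths are drawn uniformly from the template envelopes,
and all other positions are uniform over the 19 non-cysteine standard
residues (composition does not affect any computation here except motif
content, which is planted explicitly).  A G·x·C γ-core tripattern is
planted ending at the γ-slot cysteine (slot 6, or 7 for mytilin-like
templates); CSH-only templates plant none, matching AdDLP, which lacks the
GXC/CXG motif.  Everything is reproducible bit-for-bit from (template, n,
seed); there is no global random state.

Real data these fixtures do not emulate: taxon-specific residue
composition, correlated region lengths, or evolution along a tree.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .families import GENERATOR_TEMPLATES, TEMPLATES, FamilyTemplate
from .records import PeptideRecord, Ternary

#: Background alphabet: the 20 standard residues minus cysteine.
NON_CYS = "ADEFGHIKLMNPQRSTVWY"


def get_template(name: str) -> FamilyTemplate:
    """Look up a generator template by family name."""
    if name not in GENERATOR_TEMPLATES:
        raise KeyError(
            f"unknown template {name!r}; valid templates: "
            + ", ".join(GENERATOR_TEMPLATES)
        )
    return TEMPLATES[name]


def _draw_length(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo < 0 or hi < lo:
        raise ValueError(f"infeasible region range ({lo}, {hi})")
    return int(rng.integers(lo, hi + 1))


def _build_sequence(
    template: FamilyTemplate,
    rng: np.random.Generator,
    plant_kcxn: bool,
) -> str:
    slots = template.slot_order
    lengths: dict[tuple[int, int], int] = {}
    for pair in zip(slots, slots[1:]):
        lo, hi = template.regions[pair]
        # the two residues before the γ-slot cysteine carry the planted
        # G·x tripattern, so that region must be at least 2 long
        if template.gamma_slot is not None and pair[1] == template.gamma_slot:
            lo = max(lo, 2)
            hi = max(hi, lo)
        lengths[pair] = _draw_length(rng, lo, hi)
    flank_n = _draw_length(rng, *template.flank_n)
    flank_c = _draw_length(rng, *template.flank_c)

    def residues(n: int) -> list[str]:
        return [NON_CYS[i] for i in rng.integers(0, len(NON_CYS), n)]

    chars: list[str] = residues(flank_n)
    cys_at: dict[int, int] = {}
    for idx, slot in enumerate(slots):
        cys_at[slot] = len(chars)
        chars.append("C")
        if idx < len(slots) - 1:
            chars.extend(residues(lengths[(slot, slots[idx + 1])]))
    chars.extend(residues(flank_c))

    if template.gamma_slot is not None:
        core = cys_at[template.gamma_slot]
        chars[core - 2] = "G"
        if plant_kcxn:
            chars[core - 1] = "K"
            chars[core + 2] = "N"
    # γ-core content is planted, never accidental: scrub G·x·C / C·x·G
    # tripatterns that background residues happen to form at other
    # cysteines (AdDLP-like peptides genuinely lack the motif entirely)
    gamma_core = cys_at.get(template.gamma_slot)
    planted_g = None if gamma_core is None else gamma_core - 2
    background = NON_CYS.replace("G", "")
    for pc in cys_at.values():
        if pc == gamma_core:
            continue
        if pc >= 2 and chars[pc - 2] == "G" and pc - 2 != planted_g:
            chars[pc - 2] = background[int(rng.integers(0, len(background)))]
        if pc + 2 < len(chars) and chars[pc + 2] == "G" and pc + 2 != planted_g:
            chars[pc + 2] = background[int(rng.integers(0, len(background)))]
    return "".join(chars)


def generate(
    template: FamilyTemplate | str,
    n: int,
    seed: int,
    *,
    plant_kcxn: bool = False,
    id_prefix: str | None = None,
) -> list[PeptideRecord]:
    """Generate ``n`` seeded records from a family template.

    Each record carries the generating family in ``metadata['family']``
    (for recovery experiments) and the template's default propeptide flags.
    Identical arguments give byte-identical output.
    """
    if isinstance(template, str):
        template = get_template(template)
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = np.random.default_rng(seed)
    prefix = id_prefix or template.name
    n_flag, c_flag = (Ternary(v) for v in template.propeptides)
    records = []
    for i in range(n):
        seq = _build_sequence(template, rng, plant_kcxn)
        records.append(
            PeptideRecord(
                id=f"{prefix}_{i + 1:04d}",
                sequence=seq,
                description=f"synthetic {template.name} fixture",
                has_n_propeptide=n_flag,
                has_c_propeptide=c_flag,
                metadata={"family": template.name},
            )
        )
    return records


def _protected_positions(sequence: str) -> set[int]:
    """Cysteines plus the G anchors of any GXC/CXG tripattern."""
    protected = {i for i, ch in enumerate(sequence) if ch == "C"}
    for i in range(len(sequence) - 2):
        if sequence[i] == "G" and sequence[i + 2] == "C":
            protected.add(i)
        if sequence[i] == "C" and sequence[i + 2] == "G":
            protected.add(i + 2)
    return protected


def perturb(
    records: list[PeptideRecord], rate: float, seed: int
) -> list[PeptideRecord]:
    """Substitute non-anchor positions independently at the given rate.

    Cysteines and the G of any γ-core tripattern are never touched, and
    substitutions never introduce a cysteine, so cysteine profiles — and
    hence slot mappings — see only background noise.  Substituted residues
    always differ from the original.
    """
    if not 0 <= rate <= 1:
        raise ValueError(f"rate {rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        protected = _protected_positions(rec.sequence)
        chars = list(rec.sequence)
        hit = rng.random(len(chars)) < rate
        for i, flip in enumerate(hit):
            if not flip or i in protected:
                continue
            choices = [c for c in NON_CYS if c != chars[i]]
            chars[i] = choices[int(rng.integers(0, len(choices)))]
        out.append(replace(rec, sequence="".join(chars)))
    return out
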
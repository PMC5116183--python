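"""Slot assignment, notation codec, family classification, bond inference.

The optimizer is checked against an independently written brute-force
oracle: plain-Python enumeration of every order-preserving assignment of
cysteines to slots, scored by a from-scratch implementation of the
documented scoring rule.
"""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csabref.families import TEMPLATES, templates_by_slots
from csabref.mapping import (
    ArrayMapping,
    Bond,
    BondSet,
    MappingError,
    classify_family,
    decode_notation,
    describe_bonds,
    encode_notation,
    infer_bonds,
    map_to_reference,
    toxin_flag,
)
from csabref.motifs import cysteine_profile, find_gamma_core
from csabref.records import PeptideRecord
from csabref.simulate import generate


def rec(seq: str) -> PeptideRecord:
    return PeptideRecord(id="t", sequence=seq)


# ---------------------------------------------------------------------------
# independent scoring + enumeration oracle
# ---------------------------------------------------------------------------


def oracle_score(slots, positions, gamma_set, k):
    """From-scratch implementation of the documented assignment score."""
    a = dict(zip(slots, positions))
    score = -2 * (k - len(slots))
    sp34 = a[4] - a[3] - 1 if 3 in a and 4 in a else None
    sp89 = a[9] - a[8] - 1 if 8 in a and 9 in a else None
    if sp34 == 3:
        score += 4
    if sp89 == 1:
        score += 4
    csh_exact = sp34 == 3 and sp89 == 1
    if 6 in a and a[6] in gamma_set:
        score += 8
    elif 7 in a and a[7] in gamma_set and csh_exact:
        score += 8
    dev = None
    for t in templates_by_slots().get(frozenset(slots), []):
        d = 0
        order = t.slot_order
        for (x, y) in zip(order, order[1:]):
            lo, hi = t.regions[(x, y)]
            g = a[y] - a[x] - 1
            d += max(0, lo - g) + max(0, g - hi)
        dev = d if dev is None else min(dev, d)
    if dev is not None:
        score += max(0, 3 - dev)
    return score, dev


def oracle_best(record):
    """Exhaustive enumeration over all order-preserving assignments."""
    cys = cysteine_profile(record).positions
    gamma = {
        h.core_cys for h in find_gamma_core(record) if record.sequence[h.core_cys] == "C"
    }
    k = len(cys)
    best = None
    for m in range(1, min(k, 10) + 1):
        for slot_tuple in itertools.combinations(range(1, 11), m):
            for pos_tuple in itertools.combinations(cys, m):
                score, dev = oracle_score(slot_tuple, pos_tuple, gamma, k)
                key = (
                    -score,
                    dev is None,
                    dev if dev is not None else 10**6,
                    slot_tuple,
                    pos_tuple,
                )
                if best is None or key < best[0]:
                    best = (key, slot_tuple, pos_tuple)
    return best[1], best[2]


class TestMapToReference:
    def test_insect_fixture_gets_insect_slots(self, family_mappings):
        assert family_mappings["insect_type"].slots == (2, 3, 4, 6, 8, 9)

    def test_asabf_fixture_gets_asabf_slots(self, family_mappings):
        assert family_mappings["asabf_6cys"].slots == (3, 4, 5, 6, 8, 9)

    def test_csh_only_fixture_gets_csh_slots(self, family_mappings):
        assert family_mappings["csh_only"].slots == (3, 4, 8, 9)

    @pytest.mark.parametrize("seq", ["AAAA", "ACAAA"])
    def test_too_few_cysteines_rejected(self, seq):
        with pytest.raises(MappingError, match="not a candidate"):
            map_to_reference(rec(seq))

    def test_more_than_twelve_cysteines_rejected(self):
        with pytest.raises(MappingError, match="envelope"):
            map_to_reference(rec("CA" * 13))

    def test_conservation_and_order(self, family_mappings):
        for m in family_mappings.values():
            positions = [m.assignment[s] for s in m.slots]
            assert positions == sorted(positions)
            covered = set(positions) | {p for _, p in m.extras}
            assert covered == {
                i for i, ch in enumerate(m.sequence) if ch == "C"
            }

    @pytest.mark.parametrize(
        "family",
        ["csh_only", "insect_type", "asabf_6cys", "mollusk_nematode_8", "macin_10"],
    )
    def test_optimizer_equals_bruteforce_oracle(self, family):
        record = generate(family, 1, seed=303)[0]
        m = map_to_reference(record)
        slots, positions = oracle_best(record)
        assert m.slots == slots
        assert tuple(m.assignment[s] for s in m.slots) == positions

    def test_oracle_equivalence_on_irregular_sequences(self):
        # sequences that match no template and carry extras
        for seq in ["CCAAACAAC", "ACACACACAC", "GACAAAAAAAAACAAC"]:
            record = rec(seq)
            m = map_to_reference(record)
            slots, positions = oracle_best(record)
            assert m.slots == slots
            assert tuple(m.assignment[s] for s in m.slots) == positions

    def test_deterministic(self, family_records):
        for record in family_records.values():
            assert map_to_reference(record) == map_to_reference(record)

    def test_mytilin_gxc_anchors_slot7(self):
        # mollusk-like spacing whose GXC cysteine sits one slot late:
        # slot-6 anchoring would break both CSH spacings
        t = TEMPLATES["mytilin_type"]
        seq_parts = []
        import numpy as np

        rng = np.random.default_rng(7)
        from csabref.simulate import _build_sequence

        seq = _build_sequence(t, rng, plant_kcxn=False)
        m = map_to_reference(rec(seq))
        assert m.anchor_used == 7
        assert m.slots == t.slot_order


class TestNotation:
    @pytest.mark.parametrize(
        "token,pattern",
        [("2C", "CXXCC"), ("C2C", "CCXXCC"), ("2C1", "CXXCXC"), ("0", "CC")],
    )
    def test_decode_published_examples(self, token, pattern):
        assert decode_notation(token) == pattern

    @pytest.mark.parametrize("bad", ["", "2-", "x", "C X"])
    def test_decode_rejects_illegal_tokens(self, bad):
        with pytest.raises(ValueError):
            decode_notation(bad)

    def test_adjacent_cysteines_encode_as_zero(self):
        m = map_to_reference(rec("AACAAACAAAAAACCA"))
        pair = f"{m.slots[-2]}-{m.slots[-1]}"
        # last two cysteines are adjacent in sequence
        assert m.regions[pair] == "0" or "0" in m.regions.values()

    @given(
        st.lists(
            st.one_of(st.integers(0, 9), st.just("C")), min_size=0, max_size=6
        )
    )
    @settings(derandomize=True, max_examples=300)
    def test_encode_decode_round_trip_on_random_segments(self, parts):
        # build an explicit inter-box segment, encode it via a mapping of
        # two boxed cysteines, and decode the token back
        segment = "".join("X" * p if isinstance(p, int) else "C" for p in parts)
        from csabref.mapping import _encode_segment

        token = _encode_segment(segment)
        assert decode_notation(token) == "C" + segment + "C"

    def test_full_mapping_round_trip(self, family_mappings):
        for m in family_mappings.values():
            slots = m.slots
            seq = m.sequence
            for a, b in zip(slots, slots[1:]):
                lo, hi = m.assignment[a], m.assignment[b]
                pattern = "".join(
                    "C" if ch == "C" else "X" for ch in seq[lo : hi + 1]
                )
                assert decode_notation(m.regions[f"{a}-{b}"]) == pattern

    def test_empty_boxes_for_unassigned_slots(self, family_mappings):
        text = encode_notation(family_mappings["insect_type"])
        # slots 1, 5, 7, 10 unassigned -> four empty boxes
        assert text.count("[]") == 4
        assert "[C2]" in text and "[C6]" in text


class TestClassifyFamily:
    def test_slot_sets_map_to_labels(self, family_mappings):
        for name, m in family_mappings.items():
            assert classify_family(m).label == name

    def test_long_extension_disambiguates_toxin(self):
        droso = generate("drosomycin_plant", 1, seed=5)[0]
        toxin = generate("longchain_toxin", 1, seed=5)[0]
        m_droso = map_to_reference(droso)
        m_toxin = map_to_reference(toxin)
        assert m_droso.slot_set == m_toxin.slot_set
        assert classify_family(m_droso).label == "drosomycin_plant"
        assert classify_family(m_toxin).label == "longchain_toxin"
        assert m_toxin.spacing(9, 10) > 10

    def test_no_match_reports_nearest_template(self):
        m = map_to_reference(rec("ACAAAAAAAAACAAAAC"))
        label = classify_family(m)
        if label.label == "unassigned":
            assert "nearest is" in label.note

    def test_threshold_is_configurable(self):
        toxin = generate("longchain_toxin", 1, seed=5)[0]
        m = map_to_reference(toxin)
        wide = classify_family(m, long_extension_threshold=100)
        assert wide.label == "drosomycin_plant"


class TestBonds:
    def test_insect_bond_description(self, family_mappings):
        m = family_mappings["insect_type"]
        bonds = infer_bonds(m, classify_family(m))
        assert describe_bonds(bonds) == "(C2–C6, C3–C8, C4–C9)"

    def test_theromacin_style_bond_description(self, family_mappings):
        m = family_mappings["macin_10"]
        bonds = infer_bonds(m, classify_family(m))
        assert describe_bonds(bonds) == "(C2–C6, C3–C8, C4–C9, C1–C7, C5–C10)"

    def test_csh_only_bonds(self, family_mappings):
        m = family_mappings["csh_only"]
        bonds = infer_bonds(m, classify_family(m))
        assert describe_bonds(bonds) == "(C3–C8, C4–C9)"

    def test_bond_counts_forced_by_templates(self, family_mappings):
        expected = {"macin_10": 5, "insect_type": 3, "mollusk_nematode_8": 4}
        for name, n_bonds in expected.items():
            m = family_mappings[name]
            bonds = infer_bonds(m, classify_family(m))
            assert len(bonds.bonds) == n_bonds

    def test_verified_bonds_listed_bare(self, family_mappings):
        m = family_mappings["insect_type"]
        bonds = infer_bonds(m, classify_family(m), verified={(2, 6)})
        assert describe_bonds(bonds) == "C2–C6, (C3–C8, C4–C9)"

    def test_two_extras_become_hypothesized_pair(self):
        # mytimacin-5-like: macin_10 slots plus one extra between C3 and C4
        # and one after C10
        base = TEMPLATES["macin_10"]
        record = generate(base, 1, seed=17)[0]
        seq = record.sequence
        m0 = map_to_reference(record)
        a = m0.assignment
        # insert extras: one C between slots 3 and 4, one at the C-terminus
        insert_at = a[3] + 2
        seq2 = seq[:insert_at] + "C" + seq[insert_at:] + "AAC"
        m = map_to_reference(rec(seq2))
        assert m.slots == tuple(range(1, 11))
        labels = [label for label, _ in m.extras]
        assert labels == ["C^3/4^", "C^10/^"]
        fam = classify_family(m)
        assert fam.label == "macin_10"
        text = describe_bonds(infer_bonds(m, fam))
        assert "C^3/4^–C^10/^" in text
        assert text.startswith("(C2–C6, C3–C8, C4–C9, C1–C7, C5–C10")

    def test_empty_bondset_renders_empty(self):
        assert describe_bonds(BondSet()) == ""

    def test_duplicate_slot_in_bonds_rejected(self):
        with pytest.raises(ValueError, match="two bonds"):
            BondSet(bonds=(Bond(2, 6, "inferred"), Bond(2, 7, "inferred")))

    def test_template_mismatch_is_internal_error(self, family_mappings):
        m = family_mappings["csh_only"]
        from csabref.mapping import FamilyLabel

        with pytest.raises(MappingError, match="unassigned slot"):
            infer_bonds(m, FamilyLabel(label="insect_type"))


class TestToxinFlag:
    def _kcxn_record(self, nloop):
        t = TEMPLATES["insect_type"].with_regions(r2_3=nloop)
        return generate(t, 1, seed=23, plant_kcxn=True)[0]

    def _flag(self, record):
        m = map_to_reference(record)
        hits = find_gamma_core(record)
        anchored = [
            h for h in hits if m.anchor_used and h.core_cys == m.assignment[m.anchor_used]
        ]
        return toxin_flag(m, anchored[0] if anchored else None)

    def test_kcxn_with_short_nloop_flags(self):
        assert self._flag(self._kcxn_record(nloop=4)) is True

    def test_kcxn_with_long_nloop_does_not_flag(self):
        assert self._flag(self._kcxn_record(nloop=16)) is False

    def test_plain_gamma_core_does_not_flag(self):
        t = TEMPLATES["insect_type"].with_regions(r2_3=4)
        record = generate(t, 1, seed=23, plant_kcxn=False)[0]
        assert self._flag(record) is False

    def test_missing_preconditions_give_false(self, family_mappings):
        m = family_mappings["csh_only"]
        assert toxin_flag(m, None) is False
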
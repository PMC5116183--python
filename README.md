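# csabref

Ten-cysteine reference-array annotation for the CS-αβ (scorpion-toxin-like)
superfamily of defensive peptides.

## The problem

Invertebrate "defensins", scorpion toxins, plant defensins, drosomycins,
nematode antibacterial factors (ABFs) and macins all share the
cysteine-stabilized αβ (CS-αβ) fold — an α-helix packed against two
antiparallel β-sheets, held by three or more disulfide bonds — but their
names encode history, not structure: insect defensins are conventionally
written C1–C4, C2–C5, C3–C6 while nematode ABFs are C1–C5, C2–C6, C3–C7,
C4–C8, hiding the fact that the first three bonds are structurally the
same. A single **ten-cysteine reference array** (slots C1–C10) fixes this:
slots C3, C4, C8, C9 form the cysteine-stabilized helix (CSH) motif, C2 and
C6 complete the CS-αβ fold's third bond, and the cysteine of the γ-core
motif (an 8–16-residue β-hairpin region usually containing GXC or CXG)
generally falls on C6. In reference numbering, insect defensins become
(C2–C6, C3–C8, C4–C9), nematode ABFs add C5–C10, drosomycin/plant defensins
add C1–C10, and ten-cysteine macins such as theromacin read
(C2–C6, C3–C8, C4–C9, C1–C7, C5–C10) — similarities and differences are
explicit.

`csabref` turns that conceptual alignment into a reproducible tool for
anyone curating or comparing cysteine-rich defense peptides. It:

* maps the cysteines of a mature peptide onto slots C1–C10 by exact
  combinatorial optimization (γ-core anchoring, CSH spacing rewards,
  family-template matching; ties broken deterministically);
* emits the compact box/spacer notation (`2C` between two boxes ⇔
  `CXXCC`, `C2C` ⇔ `CCXXCC`, `2C1` ⇔ `CXXCXC`) and names extra cysteines
  `C^3/4^`-style by their flanking slots;
* classifies the spacing family (insect-type, ASABF-6Cys, mollusk/nematode
  eight-cysteine, mytilin-type, drosomycin/plant, long-chain toxin,
  8/10-cysteine macin, CSH-only) and writes the homology-inferred bond
  description, parenthesized because inferred;
* flags the KCXN γ-core signature, which together with a short n-loop
  (the variable C2–C3 region, 4–16 residues in insect-type peptides)
  heuristically indicates channel-toxin rather than antimicrobial activity;
* builds a cysteine-anchored multiple alignment (anchor cysteines in fixed
  shared columns, no substitution scoring) and codes six AdDLP-relative
  indel characters plus two propeptide characters per sequence
  (AdDLP, a four-cysteine CSH-only bacterial peptide, is the hypothesized
  ancestor; reference lengths 3, 17, 3, 11, 1, 9; observed < reference → 0,
  equal → 1, greater → 2, missing → `-`);
* exports the protein + indel + propeptide partitions as a mixed-datatype
  NEXUS matrix with the MrBayes settings block (`rates=invgamma`,
  `aamodelpr=mixed` on protein, `rates=gamma` on indel/pro,
  `ratepr=variable`).

A seeded generator produces synthetic fixtures for every family template,
so the entire test suite runs without downloads.

## Worked example

```bash
csabref simulate --template insect_type --n 2 --seed 7 --out fixtures
csabref annotate --in fixtures/insect_type.fasta \
    --propeptides fixtures/insect_type_propeptides.tsv --out annot
cat annot/annotation.tsv
```

```
id                n_cysteines  slots        notation                                                   family       bonds                  gamma_core  kcxn  n_loop
insect_type_0001  6            2,3,4,6,8,9  []-6-[C2]-16-[C3]-3-[C4]-10-[]-[C6]-7-[]-[C8]-1-[C9]-6-[]  insect_type  (C2–C6, C3–C8, C4–C9)  30-45       0     16
insect_type_0002  6            2,3,4,6,8,9  []-3-[C2]-15-[C3]-3-[C4]-11-[]-[C6]-7-[]-[C8]-1-[C9]-5-[]  insect_type  (C2–C6, C3–C8, C4–C9)  27-42       0     15
```

Reading the first row: the peptide's six cysteines occupy slots
C2–C4, C6, C8, C9 — the classic insect-defensin array. The notation shows
filled boxes `[Cn]` for occupied slots, `[]` for empty ones, and spacer
tokens counting the residues between boxes (16 residues in the n-loop
between C2 and C3; the standard CSH spacings 3 and 1). The three disulfide
bonds are inferred from family homology, hence parenthesized. The γ-core
spans residues 30–45 (1-based), carries no KCXN signature (`kcxn` 0), and
the n-loop is 16 residues.

```bash
csabref code --in fixtures/insect_type.fasta \
    --propeptides fixtures/insect_type_propeptides.tsv --out coded --mrbayes
head -12 coded/matrix.nex
```

```
#NEXUS
[ CS-αβ reference-array character matrix ]
[ protein span uses GAP=- MISSING=?; in the standard span '-' ]
[ denotes missing or unknown data, per the published coding ]
BEGIN DATA;
    DIMENSIONS NTAX=2 NCHAR=64;
    FORMAT DATATYPE=MIXED(PROTEIN:1-56,STANDARD:57-64) GAP=- MISSING=? INTERLEAVE=NO;
    MATRIX
        insect_type_0001  STGDHHCVWAMTETELTHIHRTYCLMMCPNMYTTRPGY-CLGVFVPECACLAEMYL20101010
        insect_type_0002  ---HMKCGYADFYRVFRKMAPT-CQENCHYVFMWVRQGSCLDGNRMPCVCRIQPE-10101010
    ;
END;
```

The 56 protein columns hold the anchored alignment (every mapped cysteine
in a fixed column); characters 57–62 are the six AdDLP-relative indel codes
and 63–64 the two propeptide codes (here `10`: N-terminal propeptide
present, C-terminal absent).

The same operations are available as a library:

```python
from csabref import annotate_record, generate

record = generate("macin_10", 1, seed=1)[0]
result = annotate_record(record)
print(result.annotation.bonds)   # (C2–C6, C3–C8, C4–C9, C1–C7, C5–C10)
```

## Layout

| Module | Contents |
| --- | --- |
| `csabref.records` | `PeptideRecord`, FASTA / propeptide-table / annotation-table I/O |
| `csabref.motifs` | cysteine profile, γ-core (GXC/CXG) detection, CSH spacing, n-loop |
| `csabref.families` | the family spacing templates (slot sets, region envelopes, bonds) |
| `csabref.mapping` | slot assignment, notation codec, classification, bond inference |
| `csabref.alignment` | cysteine-anchored alignment, gap-space accounting, FASTA/NEXUS export |
| `csabref.coding` | AdDLP-relative indel codes, propeptide codes, partitioned NEXUS |
| `csabref.simulate` | seeded synthetic fixtures per family template |
| `csabref.cli` | `csabref annotate / align / code / simulate` |

See `docs/methods.md` for the model, parameter defaults and the design
decisions behind the scoring and layout rules.
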
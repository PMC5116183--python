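# Methods

## The reference-array model

`csabref` treats a mature peptide as a sequence of residues in which only
literal `C` characters are cysteines (ambiguity codes X/B/Z and
selenocysteine U are legal input but never anchor anything — a deliberately
conservative reading). The model is a ten-slot reference array C1–C10 with
three structural commitments:

* slots 3, 4, 8, 9 are the cysteine-stabilized helix (CSH) motif, with
  standard spacings of exactly 3 residues between C3/C4 and 1 residue
  between C8/C9;
* slots 2 and 6 complete the CS-αβ fold's third disulfide;
* the cysteine of the γ-core motif (GXC or CXG inside an 8–16-residue
  window) generally occupies slot 6; in mytilins it occupies slot 7.

A mapping assigns each observed cysteine either to a slot
(order-preserving, injective) or to an "extras" list; conservation —
every cysteine accounted for exactly once — is enforced structurally.

## Slot assignment as optimization

The published practice aligns sequences to the array by eye; here the
assignment is the exact optimum of an explicit score over **all**
order-preserving assignments:

| term | value |
| --- | --- |
| γ-core cysteine at slot 6 | +8 |
| γ-core cysteine at slot 7, CSH spacings exact, slot 6 not γ-anchored | +8 |
| each exact CSH spacing (C3–C4 = 3; C8–C9 = 1) | +4 |
| slot set equals a family template | +max(0, 3 − deviation) |
| each extra (unslotted) cysteine | −2 |

*Deviation* is the total residue distance of the observed inter-slot
spacings from the matched template's canonical ranges; when two templates
share a slot set (drosomycin/plant vs long-chain toxin) the better-fitting
one is used. The template term is floored at zero: early versions used an
unfloored `3 − deviation` and a single stretched region could then make
the correct slot set score *worse* than abandoning the template entirely,
shifting assignments off-template — the floor removes that perverse
incentive while the tie-break still rewards matching. Ties are resolved
deterministically: prefer a template match, then smaller deviation, then
the lexicographically smallest (slot tuple, position tuple).

The optimizer enumerates every assignment (vectorized per assignment
size; for k cysteines and 10 slots there are C(10+k, k) − 1 of them,
≈ 184 000 at k = 10), so it is provably identical to brute force; the test
suite checks this equivalence against an independently written
plain-Python enumeration with its own scorer.

Sequences with fewer than 2 cysteines are rejected as non-candidates;
more than 12 exceed the modelled envelope (macins run to 12) and are
rejected with guidance. 11–12-cysteine inputs map with up to two extras.

## Family templates

Nine templates are encoded (slot sets from the family descriptions):
`csh_only` {3,4,8,9}, `insect_type` {2,3,4,6,8,9}, `asabf_6cys`
{3,4,5,6,8,9}, `mollusk_nematode_8` {2,3,4,5,6,8,9,10}, `mytilin_type`
{2,3,4,5,7,8,9,10}, `drosomycin_plant` and `longchain_toxin`
{1,2,3,4,6,8,9,10}, `macin_8` {1,2,3,4,6,7,8,9}, `macin_10` {1..10}.
Mollusk defensins and myticins have nearly identical spacing and are
deliberately not distinguished; fungal-specific spacing families are not
encoded and classify as `unassigned` with the nearest template named.

Region-length ranges stated in the source literature are the insect-type
n-loop (C2–C3: 4–16 residues), the CSH spacings (3 and 1), and "long"
C9–C10 extension for long-chain toxins. All other ranges are this
package's own envelopes, fixed once from representative sequences
(sapecin A's inter-cysteine spacings 12, 3, 9, 5, 1) and kept broad; they
serve both as generator defaults and as the deviation priors above.

Two genuinely open points were decided here:

* **Mytilin geometry.** With ranges overlapping the mollusk template, an
  eight-cysteine sequence is ambiguous between "γ-cysteine at C6"
  (mollusk) and "at C7" (mytilin); spacing must be what forces C7. The
  mytilin template therefore places the γ-core cysteine displaced toward
  C8 (C5–C7: 4–10; C7–C8: 2–3), so the mollusk reading always carries
  deviation and the C7 reading wins.
* **Mytilin bonds.** No explicit mytilin bond list is published; the
  package infers (C2–C7, C3–C8, C4–C9, C5–C10) by analogy, with C7 taking
  the third-bond role of C6, and says so in the classification note.

## Classification thresholds

* `long_extension_threshold` (residues between C9 and C10, default 10):
  above it, the shared drosomycin/long-chain slot set is read as a
  long-chain toxin. Drosomycin-type C9–C10 spacers are short; the default
  sits between the template envelopes (≤ 6 vs ≥ 15).
* `short_nloop_threshold` (residues between C2 and C3, default 6): the
  KCXN-in-γ-core toxin heuristic fires only when the n-loop is at most
  this long (a short loop avoids steric hindrance at the channel). The
  flag is a sequence heuristic, never an activity claim, and is reported
  separately from annotation (`AnnotationResult.toxin_heuristic`).

Both are positive integers, configurable per run and recorded in the run
manifest.

## Bond descriptions

Template bonds carry status `inferred` (homology only); user-supplied
experimentally verified pairs upgrade to `verified`. Rendering follows the
published convention: verified bonds bare, everything inferred/unknown in
one trailing parenthesis, core bonds first (C2–C6, C3–C8, C4–C9) then
peripheral bonds (C1–C7, C5–C10, C1–C10), then unpaired cysteines and
extras. Note this is *not* sorted by first slot — the published examples
(theromacin, mytimacin 5) dictate the core-first order. When exactly two
extra cysteines remain, they are listed as one hypothesized pair
(`C^3/4^–C^10/^` for a mytimacin-5-like peptide), since an even count
suggests an additional bond; otherwise extras are listed singly.

## Anchored alignment layout

Columns are: an N-flank region, one anchor column per slot **assigned in
at least one record** (unused slots get no column, so identical inputs
align gap-free), inter-slot regions, and a C-flank region. Region widths
are the maxima of per-record demands. Within a row:

* residues between two of the record's assigned slots are left-justified
  against the leading anchor (keeping the γ-core contiguous with C6);
* residues upstream of the first assigned slot are right-justified
  against the C2 anchor column when that first slot is ≥ 2, and against
  C1 otherwise. This reproduces the published accounting for AdDLP-like
  rows: the flank counts as "residues upstream of C2" while the whole
  C2–C3 region stays gapped;
* residues after the last assigned slot are left-justified after it.

Extra cysteines occupy ordinary residue columns. Gap spaces for a region
are counted strictly between the bounding anchor columns (or from the row
edge for the two flank regions); the arithmetic identity *gaps = anchored
width − residues in region* is property-tested.

## Indel and propeptide coding

The six areas are coded against AdDLP's reference lengths
(3, 17, 3, 11, 1, 9) with observed < reference → 0, equal → 1, greater →
2. Areas 1, 3, 5, 6 count the record's own residues; areas 2 and 4 count
alignment gap spaces — an asymmetry kept on purpose because that is how
the published rules are worded ("amino acids" vs "gap spaces"). Any area
touching a slot the record lacks is `-`. Under this rule an AdDLP-like
record itself codes `--1-11`: the contract codes by slot presence, not by
alignment column, which is the one place this implementation knowingly
departs from how the original matrix (where AdDLP, as the reference
taxon, was presumably all 1s) must have been filled in by hand.
Propeptides code present → 1, absent → 0, unknown → `-` per terminus.

Indel characters are treated as unordered states (whether the original
analysis ordered them is unstated; unordered is the weaker assumption).

## NEXUS output

One DATA block with `DATATYPE=MIXED(PROTEIN:…,STANDARD:…)` (MrBayes
dialect), `GAP=- MISSING=?`, and charsets for the protein/indel/pro
partitions. The published coding writes missing as `-`, which collides
with the gap symbol; the file keeps the visible `-` characters in the
standard span and documents the convention in a header comment (MrBayes
treats gap and missing identically for standard data). The optional
MrBayes block carries exactly the published settings (`rates=invgamma`
and `aamodelpr=mixed` on protein, `rates=gamma` on indel and pro,
`ratepr=variable`); the two-million-generation / temperature-0.5 run
parameters appear as comments only — running MrBayes is out of scope.
General-purpose NEXUS readers do not parse MIXED matrices, so the
round-trip check uses the package's own reader for the mixed file, while
the protein-only export from `export_alignment` is validated with
DendroPy. Taxon labels are quoted per NEXUS token rules when needed.

## Synthetic fixtures

The generator emulates the eight recoverable family patterns
(`mytilin_type` is classification-only, its full slot set not being
explicitly described). Cysteines are planted exactly at template-implied
positions, region lengths drawn uniformly from the template envelopes,
background residues uniform over the 19 non-cysteine standard residues. A
G·x·C γ-core is planted ending at the γ-slot cysteine (the KCXN signature
plantable on request); CSH-only fixtures plant none, since AdDLP lacks
the motif. Accidental G·x·C / C·x·G tripatterns at other cysteines are
scrubbed — γ-core content is planted, never incidental (without this, a
random G two residues before a CSH cysteine occasionally mis-anchors it
at slot 6 and zero-mutation recovery is not exact). `perturb` substitutes
non-anchor positions independently at a given rate, never touching
cysteines or γ-core G anchors and never introducing a cysteine.

All randomness flows through explicitly seeded NumPy generators; there is
no global random state, and identical inputs give byte-identical output.

What passing recovery tests show is that the *mapping and classification
machinery* is exact and noise-tolerant under these conditions; they say
nothing about sequences whose region lengths fall outside the template
envelopes, about real taxon-specific composition, or about indel
processes correlated across regions, none of which the generator
emulates.

## Problem sizes used in the test and acceptance suites

Recovery experiments run 100 seeded replicates per family at mutation
rates 0 and 0.1; the notation round trip covers 1 000 generated fixtures
across all families; oracle-equivalence checks run the full brute-force
enumeration on fixtures of every family (up to 10 cysteines ≈ 184 000
assignments each); the indel-rule sweep is exhaustive over lengths 0–40
per area. The acceptance script reproduces the four published coding-rule
worked examples from one- and two-record fixtures with pinned region
geometries.

## Known limitations

* Family templates cover the patterns described in the text; fungal
  families with spacing found almost exclusively in fungi are not encoded
  and report `unassigned`.
* "Inferred" bonds are homology statements only; no connectivity
  prediction is attempted, and no antimicrobial-spectrum prediction is
  offered (nomenclature and activity are known to be uncorrelated in this
  superfamily).
* The γ-core detector is purely pattern-based (no β-hairpin prediction);
  peptides active without a clear γ-core (e.g. sapecin B) are outside its
  reach by design.
* Gap-space counts are defined on this package's own anchored alignment;
  a different aligner would yield different area-2/4 counts for the same
  sequences.
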
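# Methods

`phycodelim` implements the molecular workflow used when erecting new
species of coccoid green algae from ITS2 rDNA evidence and fatty-acid
profiles.  This note documents the models, the numerical choices, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## ITS2 delimitation by the hybrid stem

The ITS2 spacer lies between the 5.8S and 28S (LSU) rRNA genes.  In the
folded transcript the 3' end of 5.8S anneals with the complementary 5'
start of 28S; this "hybrid stem" (also written 5.8S/LSU stem) brackets
the spacer, so locating the two anchor motifs and confirming their
annealing delimits the ITS2 without any external annotation.

`delimit_its2` takes an `AnchorConfig`: the 5.8S tail motif, the 28S
head motif, a minimum number of canonical rungs (`min_stem_len`,
default 6) and a mismatch budget (`max_mismatch`, default 2).  Annealing
is antiparallel: rung *t* pairs `tail[-1-t]` against `head[t]`; a rung
counts when it is Watson–Crick or G·U.  The leftmost tail occurrence is
combined with the nearest downstream head occurrence that anneals.  The
ITS2 is the 0-based half-open interval strictly between the motifs.
The default biological anchors are the broadly conserved eukaryote 5.8S
3' end / LSU 5' start; they are configuration, not hard-coded truth, and
every synthetic family carries its own anchors, so no test depends on
the biological defaults.

## Constrained folding

The reference implementation of ITS2 modelling in the literature is a
thermodynamic folder plus manual curation.  Here folding is a weighted
base-pair-maximisation dynamic programme — deterministic, exactly
checkable against exhaustive enumeration, and sufficient to express the
topological constraints of the ITS2 model.  Free energies in kcal/mol
are deliberately out of scope.

Scoring: GC pairs 3, AU 2, G·U wobble 1, plus a stacking bonus of 1 for
each pair whose inner neighbour is also paired; hairpin loops need at
least `min_loop = 3` unpaired bases; pseudoknots are excluded.  The
recurrences track "best score on [i, j]" and "best score with (i, j)
paired" so the stacking bonus is exact.  The traceback is frozen: the
5'-most pairable base is paired first, with the nearest co-optimal
partner, and stacked continuations are preferred — refolding any input
is bit-identical.

Two constraints of the four-helix ITS2 model can be imposed:

* **GGUAG** (`require_motifs`, default on): the leftmost occurrence of
  the conserved motif on the 5' side of helix III is held unpaired; a
  sequence without the motif is a constraint violation.
* **U/U opposition**: the pyrimidine–pyrimidine mismatch in helix II is
  supplied as an explicit pair of positions to hold unpaired.  Helices
  are unknown before folding, so this constraint cannot name "helix II"
  a priori; the pipeline discovers it instead (below).

`segment_helices` identifies the ring: top-level stems radiating from
the central loop are numbered I–IV in 5'→3' order of their 5' strands;
when a single enclosing chain surrounds the ring (the annealed anchors),
it is labeled the 5.8S/LSU stem.  Structures without exactly four ring
arms keep their labels in order found with a validity flag set false.

`annotate_barcode` marks the species-discrimination region.  The default
policy — the stem plus helices I–III, excluding helix IV — is inferred
from how barcode membership is reported in practice (helix IV changes
"outside", stem/helix I–III changes "within"); an explicit interval
overrides it, since the literature definition is not printed anywhere
reproducible.

### Curated folding in the pipeline

`curated_fold` emulates the manual step of model construction.  The
motif-constrained optimum is computed first; then every candidate U/U
opposition (a U opposite a U whose immediate flanks can pair) is tried
as an additional constraint.  Candidates are ranked by (four-helix ring
formed, U/U mismatch present in helix II, fold score), deterministically.
This mirrors the practice of accepting the structure that satisfies the
canonical model rather than the raw energy optimum.

## Structure comparison and the verdict

Two structures are aligned by Needleman–Wunsch on the sequences with a
bonus (default 1) for columns of equal pairing state (match 2, mismatch
−1, gap −2; ties: diagonal, then gap-in-A).  Classification applies a
strict precedence per column — gap > paired logic > unpaired logic:

* **CBC**: both positions of a pair change while both pairs stay
  canonical (U–A → C–G); partners must be aligned to each other, and a
  non-canonical resulting pair is never a CBC.
* **hCBC**: exactly one base of a canonical pair changes (U–G → C–G,
  G–C → G–U).
* **pairing_change**: paired in one structure, unpaired in the other, or
  partners not aligned; a base substitution at such a column is recorded
  with it.
* **transition / transversion** at positions unpaired in both.
* **deletion / insertion** at gap columns.

Region and barcode attribution come from structure A (the reference); a
discordance flag records when B disagrees.  "Single bases", as the field
tallies them in figure captions, is exposed as transitions +
transversions + the substitution component of pairing changes.

`delimit_species` applies the delimitation rule: one or more CBCs within
the barcode region → *distinct*; zero CBC, hCBC and single-base changes
within the barcode, and (when a similarity is supplied) similarity at or
above the floor → *conspecific*; otherwise *ambiguous*.  The similarity
floor defaults to 99.5%, inside the clade-internal ranges reported for
the genus (99.0–100%).  Whether hCBCs and single bases block
conspecificity is configurable because their evidential weight is not
settled; the defaults require all three classes to be absent, the
strictest reading of how conspecific strains are reported.

## Sequence similarity

`p_distance` is the proportion of differing sites among compared
columns; similarity is `(1 − p) × 100`.  Gap and IUPAC-ambiguity columns
are excluded pairwise by default (complete deletion available), T ≡ U,
comparison is case-insensitive.  Values are kept at full precision and
rounded to one decimal only in CSV/TSV output.  Pairwise deletion is the
default because reported pairwise ranges per clade are consistent with
per-pair column sets.

## Fatty-acid profiles

`parse_fa_shorthand` reads the `C:Dn-x` dialect (also `ωx` and
`omega-x`), keeping common names verbatim.  Saturation classes partition
each profile (SFA 0, MUFA 1, PUFA ≥ 2 double bonds); omega-3/omega-6
sums run across saturation classes.  Class totals are exact sums of the
member means; the omega-3/omega-6 ratio is rounded half-away-from-zero
to one decimal; summary SEs are propagated as the root of summed squared
SEs and reported as metadata only — replicate-level data behind printed
tables is generally unpublished, so printed SEs are carried, not
recomputed.  The two packaged strain tables (relative composition in %
of total FAs, and volumetric yields in mg L⁻¹, four strains each) are
transcribed fixtures; the test suite checks every printed class row
against the recomputed sums exactly at the printed precision.  Two
printed ratio cells in the source tables are inconsistent with their own
printed omega rows (they differ by one rounding unit or reflect a
transcription slip); the ratio check therefore validates against the
rounded quotient of the printed omega rows, which is the only
self-consistent reading.

`anova_oneway` wraps classical one-way ANOVA (scipy) with Tukey's HSD at
α = 0.05, with an explicit F = 0 guard for the degenerate all-equal-means
case.  Published F statistics for these tables are internally
inconsistent with the printed means/SEs, so ANOVA correctness is
validated structurally: F = 0 for identical groups, df (3, 8) for
4 strains × 3 replicates, and the two-group F equals the squared
two-sample t.  `gen_fa_replicates` simulates the replicates behind a
mean ± SE table (normal draws, SD = SE·√n, seeded).

## Synthetic data

The generator is first-class, tested code: it produces every input the
pipeline needs with exact ground truth.

A reference record is `flank + 5.8S tail + ITS2 + 28S head + flank`,
whose stem+ITS2 domain folds into the canonical model: four helix arms
(defaults 9, 9, 10, 8 bp) separated by spacers (8 nt), the GGUAG motif
as a 5'-side bulge in helix III, a U/U mismatch in helix II, and the
anchors annealing into an all-Watson–Crick stem.  Design rules that make
ground truth unambiguous:

* helix strands are mismatch-free GC-rich duplexes; loops are poly-A and
  spacers are drawn from {A, C}; the anchors are pure G–C.  Outside the
  constrained motifs no unpaired base can legally pair without breaking
  a planted helix, which keeps the planted fold at (or within ties of)
  the constrained optimum;
* planted CBCs draw replacements uniformly from canonical pairs with
  both bases changed, hCBCs with exactly one; substitutions record their
  expected transition/transversion call; deletions sit at spacer
  positions whose neighbours differ;
* all changes in one variant keep ≥ 3 positions apart, so mismatch and
  gap columns never cluster enough to divert the optimal alignment —
  planted-change recovery through `align_structures` +
  `classify_changes` is exact, verified over hundreds of seeds;
* rejection sampling keeps GGUAG and both anchor motifs unique per
  record; anchors are protected from mutation so variants remain
  delimitable.

`gen_alignment` plants exact pairwise divergence: for even difference
counts with room for disjoint per-row blocks every pair differs at
exactly `round(p·L)` columns; otherwise a cyclic per-column rotation is
used (exact for ≤ 4 rows) and the returned truth table — a direct column
count at construction — is authoritative in all cases.

What the generator does **not** emulate: substitution-model evolution
along a tree, rate heterogeneity, real ITS2 length variation, ambiguity
codes, or GC–MS noise structure.  Passing tests therefore demonstrate
the correctness of the algorithms under the planted model, not folding
accuracy on real transcripts.

## Problem sizes and determinism

Default test/verification sizes, chosen to exercise each oracle fully:
fold-vs-enumeration on 200 random RNAs of length ≤ 18; planted-change
recovery over 200 seeded families (~190 nt records); similarity oracles
on 30 random alignments up to 12 × 400.  All randomness flows through
`numpy.random.default_rng` seeds; every generator is a pure function of
its spec and seed, pipeline bundles are byte-identical across reruns,
and JSON output is key-sorted with no timestamps.

## Known limitations

* The folding model is topological, not thermodynamic; it will not
  reproduce the exact structures a free-energy folder draws for real
  accessions, and ΔG values are not computed.
* Blind refolding of two related sequences can settle on different
  co-optimal margins, in which case a planted pair change may surface as
  pairing changes and the verdict degrades conservatively to
  *ambiguous* (observed in roughly one in six random synthetic pairs).
  Comparison on supplied (true or curated) structures is exact; this is
  why classification accepts external structure files.
* The barcode default is an inference from usage, overridable per run.
* The delimitation rule treats indels within the barcode as
  non-blocking for conspecificity, matching how conspecific strains are
  reported (deletions listed separately from "single bases").
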
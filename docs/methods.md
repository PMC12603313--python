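# Methods

`auxinmir` re-implements, as a tested and reusable pipeline, an
integrated inference route from a flower transcriptome plus small-RNA,
degradome and expression data to (a) functionally curated auxin
nuclear-signalling proteins (TIR1/AFB receptors, ARF transcription
factors) and (b) degradome-confirmed miRNA→target modules with precursor
validation and qPCR analytics.  This note documents the models, the
parameters that matter, the synthetic-data design, and the numerical
choices.

## Sequence primitives

**ORF curation.** All complete ORFs (ATG…stop, standard genetic code) on
both strands and three frames are emitted, sorted by length; codons
containing N are neither start nor stop and translate to X.  The default
`min_aa = 50` excludes spurious micro-ORFs.  Because transcripts are
oriented mRNAs, downstream stages use mRNA-sense ORFs; when a transcript
carries several complete ORFs (nested starts, frame-shifted
readthroughs are common), the classifier selects the candidate by
shared 4-mer content with the packaged reference — a cheap, robust proxy
for alignment identity.  Length alone is not a safe criterion: a
frame-shifted readthrough can exceed the annotated ORF.

**Global alignment.** Needleman–Wunsch/Gotoh with affine gaps (a gap of
length L costs `gap_open + (L−1)·gap_extend`; defaults 10/1, BLOSUM62
loaded from Biopython's substitution-matrix collection).  The fill is
row-vectorised; the in-row gap recurrence collapses to a running-max
transform.  Traceback tie-breaking is deterministic: diagonal, then gap
in the query, then gap in the reference.  With integer-valued matrices
and gap costs all intermediate values are exactly representable, so
tie-breaking is reproducible across platforms.  Coordinates are 0-based
half-open internally and 1-based in all user-facing reports, matching
the field's residue-numbering convention (e.g. Lys-410).

## Protein classification

Domain calls replace profile-HMM scans with identity-threshold alignment
to packaged reference anchors.  The shipped anchors are **synthetic**
stand-ins: seeded random protein backgrounds with the documented
functional residues planted at their documented 1-based positions (the
five ligand-orientation and six ligand-selectivity auxin-pocket
residues; the AC-domain triad with asparagine first; the B3
`SxxxxHGxxSxxR` motif; the PB1 canonical lysine and the acidic OPCA
patch `D-x-[DE]-x-D`).  They carry the residue grammar the classifier
tests, not the biology of any real accession — residue *positions* are
configuration data, and real curated references can be dropped in
without code changes.

* **TIR1/AFB:** F-box presence = identity ≥ `fbox_min_identity` (0.35)
  over the reference F-box span; LRR ring closure = aligned coverage ≥
  `lrr_coverage_threshold` (0.80) of the LRR region — a C-terminally
  truncated receptor whose LRR horseshoe cannot close is reported
  `incomplete`.  Pocket and AC residues are anchored through the global
  alignment; a substitution (e.g. Asn→Asp at the first AC position) is
  reported but does not revoke receptor status, mirroring how such
  variants are treated in practice.
* **ARF:** B3-DBD presence = identity ≥ `dbd_min_identity` (0.35) over
  the DBD span; the AuxRE-recognition motif is scanned with
  `dbd_max_mismatch = 1` tolerated literal mismatch so the
  ARF17/18-characteristic H→G variant is still detected *and* reported
  as a substitution.  DD (dimerisation) presence is coverage-based.
  The middle domain (MD) is the query region aligned inside the
  reference MD block (≥ `md_min_len` = 30 aa); this also finds the MD in
  proteins that lack the DBD flank.  MD composition typing: activator
  iff freq(Q) ≥ `q_min` (0.10) and Q, S, L all rank in the `top_k` (4)
  most frequent residues; repressor iff freq(P)+freq(G) ≥ `pg_min`
  (0.15) with Q below `q_min`; anything else is reported `unclassified`,
  never coerced.  The thresholds separate Q/S/L-concentrated from
  P/G/S/L-concentrated Dirichlet composition families completely (the
  suite verifies 100% separation).
* **PB1 typing:** domain presence requires identity ≥ `pb1_min_identity`
  (0.30) over the PB1 reference *and* a compact hit (aligned query
  extent ≤ `pb1_max_stretch` = 1.5 reference lengths) — without the
  compactness requirement the short reference threads through long
  unrelated queries and fakes hits.  Motif I = lysine at the canonical
  column; motif II = OPCA with ≤ 1 literal mismatch.  Naming follows the
  convention in which "type I" PB1 carries the OPCA motif but lacks the
  canonical lysine; both motif flags are surfaced so the nomenclature
  cannot corrupt downstream logic.
* **Architecture→role mapping:** DBD+MD+PB1 = canonical ARF; DBD-only =
  AuxRE masking; PB1-only = modulation of ARF–Aux/IAA polymerisation;
  DBD+MD without PB1 = auxin-independent (ARF17/18-like); remaining
  cases report `no_dbd`.  Aux/IAA-annotated transcripts are passed
  through unclassified.

## Precursor identification

A transcript qualifies as a precursor candidate if it contains the
mature miRNA (exact match by default, `max_mismatch` exposed), folds
into a stem-loop with the miRNA inside the stem, and its expression
co-varies with the miRNA.

**Folding** is Nussinov-style maximum base pairing over Watson–Crick
plus G:U wobble with `min_loop = 3`, not thermodynamic energy
minimisation: it is self-contained, exactly checkable against
enumeration of all nested structures, and the stem/loop membership
question is robust to the scoring model for designed stems.  The DP is
vectorised over pairing partners; traceback prefers leaving the left
base unpaired, then the smallest partner.  A `structure` hook on
`assess_stem_membership` accepts externally computed folds (e.g. an MFE
tool); every output records the engine used.  The folding window is the
miRNA span ± `flank` (150) nt, capped at `max_window` (400) — windowing
bounds the cubic DP cost; the study this emulates folded whole
transcripts.

**Stem membership:** `in_stem` requires a paired fraction ≥
`min_paired_frac` (0.6) of miRNA bases with all pair partners on one
side of the miRNA (the opposite arm of a single hairpin).  There is no
community-standard quantitative "in the stem" criterion; the fraction
and the junction-spanning case are this package's constructions and both
are surfaced in the output so users can re-filter.  The miRNA* span is
the partner extent with the conventional 2-nt Dicer-overhang offset.

**Correlation filter:** Spearman rho with average ranks, strict
`rho > 0.5`.  Equality at the threshold fails; a 1e-9 guard absorbs
float error in the rank correlation (achievable rho values are spaced
~6/(n³−n) apart, orders of magnitude wider).  At n = 8 paired samples
the filter's false-positive rate on independent pairs is fixed by the
permutation null: P(rho > 0.5) = 3963/40320 ≈ 9.8% — a known property
of the filter at this sample size, not an implementation artefact.

## Target scoring and degradome confirmation

Complementarity uses the de-facto plant small-RNA penalty convention:
mismatch 1.0, G:U 0.5, gap 2.0, all doubled at miRNA positions 2–13;
the duplex is antiparallel, so the miRNA is aligned against the
reversed window, window length within miRNA ± `max_bulge` (1), sites
kept at penalty ≤ `max_penalty` (4.5), overlapping hits deduplicated to
the minimum penalty.  Scanning is exact and fast: a vectorised "glocal"
pass (full miRNA, free target ends) over each transcript flags every
window end that could reach the threshold — any qualifying window
alignment is also a glocal alignment ending at that coordinate — and
only flagged windows are re-scored by the full DP.

The predicted slicing position is the transcript nucleotide opposite
miRNA position 10 (1-based from the miRNA 5′ end); the convention is
stated in every report to avoid ±1 drift.  Degradome tags (1-based
positions, + strand) grade each site on the standard category ladder:
0 unique maximum, 1 shared maximum, 2 above the median of tag-carrying
positions, 3 at/below it (r > 1 in all four), 4 exactly one read, no
evidence when no tag maps to the site.  The median is taken over
nonzero positions with tie-averaging.  T-plots are exported as TSV and
round-trip losslessly.  Confirmed edges join protein classifications
into the module-network table; a missing classification yields a
warning row, never a silent drop.

## Expression analytics

FPKM (counts / library-millions / kilobase) and RPM (counts /
library-millions) with explicit zero-total errors; per-row Z-scores use
the population standard deviation (heatmap convention), constant rows
are flagged and emitted as zeros.  qPCR relative expression uses
2^−ΔΔCt: technical replicates averaged on the Ct scale, ΔCt against the
reference gene per (group, biological replicate), ΔΔCt against the
*mean* ΔCt of the calibrator group's biological replicates (the common
convention; per-rep pairing would be an alternative), summarised as
mean ± sd over biological replicates.  Group comparisons: one-way ANOVA
with Tukey HSD and a compact letter display (insertion method over the
significance matrix, groups ordered by mean; deterministic); two-group
designs fall back to a two-sided t test; α = 0.05.

## Synthetic data

The generator emulates the statistical structure of the study data the
pipeline was designed for, with every planted feature recorded in
`ground_truth.json`; identical (config, seed) regenerates byte-identical
files (integer RNG paths; NumPy PCG64 seeded per section).

* **Proteins:** back-translated from the reference anchors with one
  fixed codon per amino acid (no codon-usage model — keeps recovery
  deterministic), wrapped in random UTRs; background substitutions at
  2% outside anchored positions; planted classes cover intact
  receptors, an AC-variant, a C-terminal truncation, all five ARF
  architectures (with the H→G motif edit on the ARF17/18-like class)
  and random decoys.  Default counts mirror the funnel structure of the
  study (a handful of receptor candidates among tens of decoys).
* **Hairpins:** arms are random G/C (the 3′ arm the reverse complement
  of the 5′), loops and flanks poly-A.  With no U/T in the transcript A
  cannot pair at all; every admissible pair consumes exactly one G and
  one C, the arms hold equal numbers of each, and a fully base-paired
  interval is impossible under the minimum-loop rule — so the designed
  rainbow stem is provably the *unique* maximum-pairing structure, and
  stem/loop ground truth is guaranteed by construction rather than by
  re-running the folder.  Loop-planted miRNAs carry at most 5 C
  residues, capping their pairable fraction at 5/21 ≈ 0.24, well below
  the 0.6 threshold.  This trades base-composition realism for provable
  structural truth; real precursors have imperfect stems the maximum
  -pairing model would treat more ambiguously.
* **Target sites:** perfect-complement sites are planted in the 3′ UTRs
  of classified transcripts (the module edges), and a penalty ladder
  (0–4.5 "hot", 5–8 "cold") is planted in dedicated decoy transcripts
  by substitution-only edits in the unweighted tail, so the gapless
  construction penalty is the designed penalty exactly.
* **Degradome:** 50 signal reads at each confirmed cleavage position,
  ≤ 5 noise positions with 1–3 reads; the expected category is computed
  from the drawn counts by a literal transcription of the ladder.
* **Expression:** pairs hit a target Spearman rho *exactly* by
  enumerating all 8! rank permutations and taking the closest
  achievable rho (recorded); decoy pairs are independent uniform draws.
  Ct tables plant folds {0.5, 1, 2, 4} with Gaussian Ct noise
  (sd 0.1) on a 3 biological × 3 technical design normalised to an
  actin-like reference.

What passing tests on this generator do **not** show: performance on
real assemblies (fragmented ORFs, sequencing error, isoforms), on
energy-model folding of imperfect stems, or on degradome libraries with
structured background; the generator's noise models are deliberately
explicit and simple.

## Problem sizes and runtime

The default bundle (163 transcripts, 100 hairpins, 123 miRNAs, 30
target sites, 500-sim qPCR and 1000-run Tukey calibrations) keeps the
full test suite and the acceptance script in the minutes range on one
CPU; sizes are configuration, so larger emulations only cost time.

## Known limitations

* Maximum base pairing ignores stacking energies; stem calls on real,
  imperfect precursors will differ from MFE folders in edge cases (the
  hook accepts external structures).
* Identity-threshold domain calls are weaker than profile HMMs for
  remote homologues; thresholds are exposed precisely because
  "high-quality domain" is not a sharply defined criterion.
* The degradome category ladder and the position-weighted penalty are
  conventions; upstream databases may have used different thresholds,
  so all outputs carry the scoring metadata.
* The Spearman filter's ~10% false-positive rate at n = 8 (exact null)
  means the rho > 0.5 rule is a coarse screen at small sample counts.
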
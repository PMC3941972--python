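# Methods

## Overview

The pipeline asks two questions of a pair of strains: *which repeat
families are over-represented in one strain?* (enrichment screen) and
*is the over-represented family young?* (site heterogeneity, TIR/ORF
annotation, fragment dating). A third component fits the sequential
ANOVA used for reciprocal-cross germline expression. Every stage is a
pure function of its inputs and seed; all coordinates are 0-based
half-open internally (GFF3 output converts to 1-based inclusive and
says so in its header).

## Read assignment

Reads are assigned to the consensus library by exact k-mer seeding
(default k = 15, ~9 seeds sampled along the read, both strands indexed)
followed by gapless extension along the seed diagonal, clipped at
consensus ends. The best candidate wins by identity, then aligned
length, then lexicographically smallest family id; a read is unassigned
when best identity < 0.85 or aligned fraction < 0.5. Candidates below
the aligned-fraction floor are excluded *before* ranking — otherwise a
short terminal overlap with identity 1.0 can outrank, and then
disqualify, a genuine full-length hit.

The assigner is deliberately gapless: the bundled simulator is
substitution-only (see below), so gapless diagonal extension is exact
there, and on substitution-only instances the assigner is checked
against an exhaustive all-offset scan and a Smith–Waterman local
aligner. Indel-containing reads from real data would need the SAM
import path (`assignments_from_sam`), which accepts externally mapped
reads into the same count table. Defaults (k = 15, identity 0.85,
aligned fraction 0.5) are permissive enough to capture reads from
~15%-diverged relic copies, which is what makes the heterogeneity
profile of a degraded population observable at all.

Normalization uses reads mapped to the host genome as denominator when
one is available; otherwise total QC-surviving reads are used and the
report's metadata flags the substitution. In simulations the truth
table provides the denominator as the count of reads originating wholly
in the genomic background; with equal coverage in both strains this
makes the fold ratio an unbiased estimator of the planted copy-number
ratio. The chi-squared test is Pearson's on the 2×2 family-vs-rest ×
strain table, 1 df, no continuity correction; no multiple-testing
correction is applied across families by default (a Bonferroni option
would be trivial for users who screen large libraries).

## QC

Trimming removes the maximal contiguous 3′ run of bases below Q20,
capped at 16 bp; a read is then discarded if more than 2 bases remain
below Q20 or it falls below a minimum length. The trim rule is
run-based rather than windowed — the simplest reading of "trim from the
3′ end" — and Phred+33 is the only supported encoding. Output reads
are always prefixes of input reads; survivor counts are monotone in the
two thresholds (property-tested).

## Site profiles

The pileup counts each aligned read base at its consensus position
(minus-strand reads enter reverse-complemented); N bases and indels are
excluded, so base counts sum exactly to depth. The major-variant
frequency h_i is computed from the aligned read bases, not agreement
with the consensus — a fixed non-consensus variant still yields h = 1,
which is the correct behavior for detecting a homogeneous
(recently-active) population that differs from the library consensus.
h is undefined below a depth floor (default 4; a frequency from fewer
reads is noise) and uncapped in depth. A family is called active-like
in a strain when its mean defined h ≥ 0.95.

One subtlety the synthetic tests exposed: heterogeneity is only
observable where relic copies *overlap*. A degraded population of
heavily truncated, barely-overlapping fragments yields h ≈ 1 at most
covered sites (each covered by one copy's reads), which is faithful to
the statistic, not a bug. The bundled two-strain preset therefore
models relics that retain 40–90% of their length so that most interior
positions are covered by several relics.

## Element annotation

Copies of a query are located by the same seed-and-chain machinery used
for fragment collection and extracted with up to 1000 bp of flank,
clipped at contig ends. The core consensus is the longest interval of
the first copy covered by a ≥ 85%-identity local alignment (Biopython
PairwiseAligner, match 2 / mismatch −3 / gap −7/−2) against *every*
other copy, with per-position majority vote (ties to copy 1); intervals
shorter than 50 bp are rejected because unrelated sequences share short
perfect local matches by chance.

TIR detection compares the 5′ terminus with the reverse complement of
the 3′ terminus, anchored at the ends with up to a 10-bp offset
allowance per end. The reported length maximizes
(matches − 3·mismatches) rather than "longest prefix above an identity
threshold": beyond the true repeat, unrelated sequence still matches at
~25%, so a pure identity-threshold rule systematically overshoots.
ORF finding scans all six frames for ATG…stop spans; the ORF starts at
the first in-frame ATG after the previous stop and downstream in-frame
ATGs are reported as alternate starts. Protein identity is
matches/columns over a global BLOSUM62 alignment (open −11, extend −1);
it is a qualitative anchor, not a blastp emulation.

## Fragment dating

Fragments are collected by exact 13-mer seeds chained along diagonals
(cluster gap ≤ 150 bp, X-drop extension with match +1 / mismatch −2,
drop 10), kept at ≥ 100 bp, and — when the element has annotated TIRs —
required to overlap the TIR-free interior by ≥ 20 bp so that stray
single-TIR hits (which cross-match between the element's two ends) do
not enter the alignment. The chained hits anchored to consensus
coordinates are used directly as a multiple alignment, exactly as a
hit-table-anchored alignment; columns where a fragment has no base are
skipped pairwise. Distances are p-distances over shared columns with
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); pairs at p ≥ 0.75 are
flagged saturated. Neighbor joining (scikit-bio) builds the tree, with
negative branch lengths clamped to zero; NJ is exact on additive
matrices, which the tests verify on hand-constructed 4- and 5-taxon
cases. Undefined pairs (disjoint or saturated) are resolved before NJ
by greedily dropping the fragment with the most undefined pairs — the
minimal practical removal, important because one short fragment
disjoint from several others would otherwise cascade into dropping
every partner.

Ages are L/(μ·g) on terminal branch lengths, with defaults
μ = 1.45×10⁻⁹ substitutions/bp/generation and g = 10 generations/year;
no factor of two is applied, since the terminal branch already measures
divergence accumulated on that lineage alone. Tree search by ML/Bayes
and rate-heterogeneity models are out of scope; a newick import path
(`terminal_branch_lengths` accepts newick strings) serves users who run
an external tree program.

## Expression ANOVA

The model is fitted by OLS with Type-I (sequential) sums of squares in
the fixed order treatment, age, barcode, treatment×age (statsmodels
`anova_lm`, typ=1); each term is tested against the residual mean
square and p-values come from the F upper tail. Lanes enter as
replicate observations with no lane term. Terms with zero sum of
squares report F = 0, p = 1, which makes the degenerate
constant-response case well-defined. On balanced designs the
sequential sums of squares equal the marginal-means closed forms, which
is the test oracle.

The barcode (library index) factor is coded with a configurable number
of levels, default 3 — the published table structure this module
reproduces carries 2 barcode df and 10 residual df over 16
observations — assigned cyclically across the 8 libraries; a fully
balanced 2-level coding is available and used in the closed-form
oracle tests. The exact real-world coding behind a 2-df index factor
from two index libraries per sample is not recoverable and is treated
as a design-matrix configuration, not an inference.

## Synthetic data

The generators define the study conditions for every test:

* **Mutation model** — single-pass independent per-site substitution
  with probability equal to the divergence parameter, uniform among
  the 3 alternative bases; no indels. Under this model the expected
  observed p-distance equals the parameter exactly, keeping the
  heterogeneity statistic and distance recovery analytically checkable.
  (Per-site divergence parameters therefore map to Jukes–Cantor
  distances via the usual correction when dated.)
* **Genomes** — a shared random background; degraded copies are placed
  at identical positions in both strains, active copies per strain;
  insertions displace background sequence at distinct offsets so they
  can never overlap, and a truth table records realized intervals.
  Degraded copies are truncated from a uniformly chosen end.
* **Reads** — single-end, round(coverage·G/L) reads, uniform starts,
  random strand, substitution errors at a per-base rate, constant
  Phred+33 quality with an optional low-quality 3′ tail for exercising
  the QC trimmer. Paired-end simulation is out of scope (the analyses
  use single ends).
* **Expression** — 16 observations (2 treatment × 2 age × 2 index
  libraries × 2 lanes), cell mean + optional barcode effect + Gaussian
  noise; noise 0 is allowed (the exact-null case), negative noise is
  rejected.

Problem sizes were chosen so the whole test-bed runs in well under a
minute of simulation time: the two-strain preset uses a 200-kb
background, a 20-copy active burst at 1% divergence, 8 relics at 14–24%
divergence retaining 40–90% of their length, and 8× coverage of 100-bp
reads at 0.5% error; the copy-ratio preset plants k-fold excesses over
a base of 3 copies in a 200-kb background at 6× coverage (enough family
reads in the low strain to keep the Poisson error of the ratio small). No per-strain copy numbers are
published for the real element, so these presets are illustrative study
conditions, not calibrated estimates.

## What the synthetic tests do and do not show

Passing tests demonstrate that the statistics recover planted truth
under the stated generative model: substitution-only divergence,
uniform read sampling, no reference bias, no repeat families other than
those simulated. They do not demonstrate robustness to indels,
sequencing-quality structure, GC bias, nested/mosaic insertions, or
mapper-specific multi-mapping behavior in real data — for real reads
the SAM import path and an external mapper are the recommended route.
The published-arithmetic anchors (coverage folds, the 0.10-subs/bp
clock age, the F statistics from published sum-of-squares tables) check
the package's arithmetic against printed values and involve no
simulation.

## Known limitations

* The assigner counts each read once for its best family; paralogous
  families closer than the identity margin can exchange reads.
* Fold ratios with a zero denominator are reported as missing/infinite
  rather than stabilized; a pseudocount option exists but defaults off.
* Core-consensus building anchors on the first copy's coordinates; a
  heavily rearranged first copy would shrink the core.
* NJ with Jukes–Cantor distances is a deliberate desk-scale stand-in
  for likelihood tree search; terminal branch lengths, not topology,
  carry the dating signal.
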
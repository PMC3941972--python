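# te-strain-scan

Strain-comparative screening for recently activated transposable
elements (TEs) from short-read data, with downstream characterization:
element annotation, insertion-age dating and germline-expression ANOVA.

## The problem

Hybrid dysgenesis — sterility in crosses between strains of the same
species — arises when paternally inherited TEs meet no maternal pool of
silencing piRNAs. Finding which element families drive a dysgenic
syndrome means finding families that are (a) strongly over-represented
in the inducer strain and (b) represented there by a young, homogeneous
copy population rather than ancient relics. This package implements
that comparative screen and the follow-up characterization as a tested,
reusable pipeline, exercised end-to-end on seeded synthetic data that
emulates an active low-divergence TE clade against degraded ancient
copies.

## What it computes

* **Enrichment screen** — reads from each strain are assigned to a
  consensus repeat library (k-mer seeded, gapless diagonal extension,
  best-identity family wins); per-family counts are normalized to reads
  per million mapped, `n_{c,s} = 10^6 r_{c,s} / M_s`, and each family's
  between-strain ratio `R_c = n_{c,1}/n_{c,2}` is tested with a Pearson
  chi-squared on the 2×2 family-vs-rest table.
* **Site profiles** — per-position depth `d_i`, coverage per million
  `c_i = 10^6 d_i / M`, and the major-variant frequency
  `h_i = max_b count_{i,b} / Σ_b count_{i,b}`; mean h near 1 marks a
  recently amplified single lineage.
* **Element annotation** — genomic copies extracted with flanks, a
  shared high-identity core consensus, terminal inverted repeats (TIRs)
  by anchored terminal alignment, six-frame ORFs with in-frame
  alternate start codons, and global-alignment protein identity.
* **Fragment dating** — genomic fragments (≥ 100 bp, TIR-only hits
  excluded) anchored to the consensus form a multiple alignment;
  Jukes–Cantor distances feed a neighbor-joining tree and each terminal
  branch length L converts to an age `L / (μ·g)` with
  μ = 1.45×10⁻⁹ subs/bp/generation and g = 10 generations/year.
* **Expression ANOVA** — sequential (Type-I) fixed-effect model
  `rpm ~ treatment + age + barcode + treatment:age` on the
  16-observation reciprocal-cross design, each term tested against the
  residual mean square.
* **Synthetic data** — seeded generators for TE family histories, host
  genomes with a truth table, single-end reads with substitution
  errors, and the factorial expression design.

## Worked example

```python
import te_strain_scan as ts
from te_strain_scan import presets

ds = presets.strain_contrast_dataset(seed=1)
result = ts.run_screen(
    ds.library, {s: r.to_fastq() for s, r in ds.readsets.items()},
    ("160", "9"), denominators=ds.denominators)
print(result.enrichment)
print(result.candidates)
```

prints

```
family_id  rpm_160    rpm_9  fold_ratio     chi2  p_value
     POLY 1.78e+05 7.89e+03        22.6 2.72e+03        0
     UBIQ 3.74e+04 3.82e+04       0.978    0.152    0.696

candidates: ['POLY']
```

POLY — the family simulated with a 20-copy active burst private to
strain 160 plus degraded relics shared by both strains — is enriched
22.6-fold in strain 160 and is the sole screen candidate; UBIQ, equally
active in both strains, sits at ratio ~1. Characterizing the candidate
(`ts.run_characterize`) then recovers a 1707-bp core consensus with a
234-bp TIR (truth: 1708/235 bp) and a bimodal age distribution: 20
fragments with median age 0.6 My (the recent burst) against 7 relics
with median age 12 My. The `examples/` directory has one short script
per capability (simulation, screen, profiles, annotation, dating,
ANOVA), each printing the numbers above with a note on what they mean.
A thin CLI (`te-strain-scan simulate|qc|enrich|annotate|age|anova`)
wraps the same functions for shell use.

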
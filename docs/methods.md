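# Methods

## The census

Transmembrane transcription regulators (TTRs) are one-component
signal-transduction proteins that regulate transcription from the
cytoplasmic membrane: a single polypeptide combining a DNA-binding
domain with at least one membrane-spanning helix.  `ttrcensus`
implements a reproducible census of these proteins across bacterial and
archaeal genome cohorts.  A protein is classified a **TTR** when it
carries (i) at least one DNA-binding domain hit and (ii) at least one
transmembrane (TM) region; a **hybrid TTR** additionally carries one or
more two-component core domains (receiver/Response_reg, HisKA
dimerization, or HATPase_c catalytic domain).  TTRs are categorised by
pass count — single-pass (1 TM), two-pass (2), multi-pass (≥3) — and by
sensory-domain count, defined as the number of resolved non-DNA-binding
domain hits.

Signal-transduction (ST) membership is registry-driven: a protein is ST
iff it carries at least one model from the registry's `st_membership`
set *or* is itself a TTR.  This guarantees TTR ⊆ ST, so the per-genome
count partition (TTR, ST−TTR, CDS−ST) is always well formed.

## Inputs and the domain registry

The pipeline consumes plain-text artifacts: amino-acid FASTA, domain
hits (HMMER3 `domtblout` or a 7-column TSV), TM segments in TMHMM long
format, and genome metadata with GTDB-style taxonomy strings.  All
residue coordinates are 1-based inclusive.  Domain hits are filtered on
the independent E-value at a configurable cutoff (default `1e-5`;
annotation practice varies and no single value is canonical), then
overlap-resolved greedily by descending bit score, keeping a candidate
only if it overlaps every kept hit by ≤ `max_overlap` residues (default
15 — enough to tolerate envelope fuzziness without double-counting
nested hits).

The shipped registry (`data/registry.yaml`) is an editable stand-in
seeded with common helix-turn-helix-family DNA-binding models and
widespread sensory/ST models; users annotating against the full Pfam
vocabulary should extend it.  The two-component core trio
(Response_reg, HATPase_c, HisKA) is the default and is disjoint from
the DNA-binding set by construction.

## TM detection and geometry

Supplied TM segments always take precedence: a protein present in the
TM file (even with zero helices) is never passed to the predictor.  For
proteins without supplied segments, a sliding-window Kyte–Doolittle
hydropathy detector is used: window 19, threshold 1.6 (mean hydropathy
per window), candidate runs expanded to full window extent, runs
separated by ≤ 3 residues merged, regions shorter than 15 residues
dropped.  These are standard hydropathy-plot constants; the detector is
deliberately simple and transparent, not a topology model (no
inside/outside assignment, no signal-peptide discrimination).  Because
the hydropathy scale is expressed in tenths, window sums are compared
against the threshold in integer arithmetic, making boundary windows
(mean exactly equal to the threshold) deterministic.

TM surface area per residue (Å²/residue) is the pooled mean of
per-residue surface-area constants over *all* TM residues of a protein
(residue-weighted, not a mean of per-region means; the two differ for
unequal-length regions and pooling is the natural per-residue
statistic).  The raft-propensity flag is inclusive: a protein is
flagged when its pooled TM surface area is **≤ 172 Å²/residue**, the
threshold below which TM helices partition preferentially into
liquid-ordered (lipid-raft) membrane domains.

### Area-table calibration

No single published per-residue surface-area scheme is canonical for
this threshold.  The base table is the theoretical maximum accessible
surface area scale of Tien et al. (2013), and the shipped table is that
scale multiplied by one global calibration factor chosen so that a
designated anchor TM interval scores exactly 172 Å²/residue.  The
bundled anchor (`data/anchor_tm_synthetic.fasta`) is a **synthetic**
single-pass membrane-regulator sequence with a fixed 23-residue TM
interval (residues 172–194); its calibration factor is 0.959728 and is
recorded in every output's provenance block.  The `calibrate`
subcommand applies the same procedure to any user-supplied sequence and
interval, so the synthetic anchor can be replaced by a real reference
protein without code changes.

## Genome, taxon and cohort statistics

Per genome: counts (ST, TTR, hybrid TTR, any-DNA-binding) and three
ratios — TTR/CDS, TTR/ST, ST/CDS — with zero-denominator cases reported
absent, never zero-filled.  Per taxon (`phylum;class`, the grouping the
census reports): unweighted means and sample SDs across genomes; taxa
with fewer than `min_genomes` genomes (default 10) are excluded from
statistical output but retained, flagged, in the census table; genomes
with an empty phylum go to an `unclassified` bucket.

Cohort-level association between TTR counts and the rest of the genome
is measured on the count partition: x = TTR, y = ST − TTR,
z = CDS − ST, testing (x, y) and (x, z).  Subtracting first removes the
spurious correlation of a count with a superset containing itself.
Count data of this kind are not normal (Shapiro–Wilk W and p are
reported per vector), so the tests are nonparametric: Spearman with
average ranks for ties and tie-corrected Kendall tau-b.  Correlations
are computed per superkingdom as well as cohort-wide.  Which variant of
each test to use is not dictated by the method itself; average-rank
Spearman and tau-b are the standard tie-handling choices.

The raft-stratified comparison tests whether TTRs in the low-surface-
area stratum (raft flag true) carry fewer sensory domains than the
high-stratum TTRs, using the classic pooled-variance two-sample t test,
two-tailed (Welch's form available via `equal_var=False` for
sensitivity analysis).  Domain-composition tables report, per model,
the fraction of TTRs carrying it, plus a cumulative union-coverage
column (fraction of TTRs carrying at least one of the top-k models).

## The synthetic cohort generator

Real cohorts require a database harvest this package deliberately does
not perform, so the generator produces fully self-contained cohorts
with known ground truth.  Its defaults are the study conditions the
census describes:

| parameter | default | meaning |
|---|---|---|
| `st_fraction` | 0.09 / 0.06 | ST share of CDS, bacteria / archaea |
| `ttr_fraction` | 0.0015 / 0.0013 | TTR share of CDS, bacteria / archaea |
| `hybrid_fraction` | 0.082 | hybrid share of TTRs |
| `tm_class_probs` | 0.56 / 0.17 / 0.27 | 1 / 2 / ≥3 TM regions per TTR |
| TM count, multi-pass | 3 + truncated geometric (p = 0.5), cap 22 | right tail of the pass distribution |
| `sa_low_fraction` | 0.43 | TTRs at/below the 172 Å²/residue threshold |
| `sensory_mean_low_sa` / `high_sa` | 0.7 / 1.5 | Poisson means of sensory-domain counts per raft stratum |
| CDS totals | log-normal, median 3000 (σ=0.40) / 2000 (σ=0.35) | typical bacterial / archaeal proteome sizes |
| taxon layout | 10 bacterial + 3 archaeal `phylum;class` groups, 96% / 4% | cohort composition |

CDS medians and dispersions, the multi-pass tail, the per-stratum
sensory means and the taxon layout are not dictated by the census
figures; they were fixed once at values typical of sequenced
prokaryotic genomes (≈3–4 Mb bacterial, ≈2–2.5 Mb archaeal proteomes;
raft-stratum TTRs carrying visibly fewer sensory domains).  Per-genome
TTR and ST counts are binomial draws from the CDS total, so pooled
cohort fractions are exactly binomial and recovery tests can use
binomial standard errors.

Each generated TTR is realised as a sequence whose TM segments are
composed from a two-residue hydrophobic palette (Ala/Phe: both strongly
hydrophobic on the Kyte–Doolittle scale, with well-separated
surface-area constants), with the Ala:Phe ratio solved so the pooled
surface area lands on the intended side of the threshold under the
shipped calibrated table; domain hits are laid out in disjoint
70-residue slots so overlap resolution keeps them all.  Non-TTR ST
proteins carry a single ST-only model; two decoys per genome (a soluble
DNA-binding protein and a membrane protein without recognised domains)
exercise the classifier's negative space.  Every protein's intended
labels are written to `ground_truth.tsv`, so recovery tests compare
pipeline output against an oracle rather than against the pipeline
itself.  A single seed drives a per-genome seed sequence; regeneration
with the same parameters is byte-identical.

What the generator does *not* emulate: real genome composition, domain
architectures beyond the registry vocabulary, realistic bit-score/
E-value distributions, taxon-specific TTR enrichment, or archaea-
specific hybrid depletion.  Passing recovery tests therefore shows the
pipeline is correct and unbiased under the stated sampling model — not
that any biological claim holds on real data.

## Numerical and reproducibility choices

- Threshold comparisons at the raft boundary are inclusive (≤ 172).
- Hydropathy window sums use integer tenths; exact threshold ties are
  classified as hot.
- Overlap-resolution ties on bit score break by envelope start, then
  model name, so output never depends on input order.
- All outputs are plain TSV/JSON with fixed float formatting; a rerun
  of an identical configuration is byte-identical, and every output
  embeds the analysis-settings hash, registry hash, area-table hash,
  calibration factor and seed.
- The `report` subcommand recomputes the statistics JSON from a
  per-protein table alone and reproduces the original bundle's file
  exactly (the per-protein table stores floats at 10 significant
  digits, above the 4-decimal rounding of the statistics block).
- Division-by-zero cases (no ST proteins, no TTRs) are reported as
  absent values; constant vectors make a correlation "undefined" with
  an explicit flag rather than NaN.

## Problem sizes

The bundled verification suite runs the full pipeline on a 500-genome
cohort at default conditions (~130k proteins, ~2.4k TTRs), which is
ample for 3-standard-error recovery of every generator fraction while
keeping a complete run in tens of seconds on one CPU.  The predictor
oracle check samples 10,000 short sequences over a 3-letter alphabet;
the permutation null for the independence contract uses 200 genomes and
499 permutations.

## Known limitations

- The TM predictor is a hydropathy heuristic, not an HMM topology
  model; on real proteomes supply TMHMM/DeepTMHMM output instead.
- The registry is a seed vocabulary, not an authoritative DNA-binding
  domain list; census results are only as complete as the registry.
- The surface-area scale is calibrated against a synthetic anchor; the
  absolute Å² values carry that convention, though the ≤/> 172
  dichotomy is insensitive to the shared factor for proteins away from
  the boundary.
- Raw p-values are reported without multiple-testing correction, and no
  phylogenetic non-independence correction is applied across genomes.
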
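# Methods

`markerkit` implements a complete analysis stack around a functional marker
gene for cellulolytic bacteria: the GH48 (glycoside hydrolase family 48)
cellulase gene, amplified with a cocktail of partially degenerate primers
(cel48-Mix2: 16 forward, 9 reverse) that targets a conserved ~344 bp region.
Because GH48 is essentially confined to bacteria that degrade crystalline
cellulose, counting and classifying GH48 sequences measures the cellulolytic
fraction of a community directly, which 16S rRNA profiling cannot.

## Degenerate primers and the 2^N mixing rule

A primer is modelled as an ordered list of positions, each a set of 1–4
natural bases or the universal base deoxy-inosine (I). Notation accepted:
inline IUPAC codes (R, Y, D, …) and bracket groups (`[AG]`, `[I]`), which are
equivalent (`[AG]` ≡ `R`).

The mixing volume of each primer is `V = 2^N` µL, where `N` counts positions
whose natural-base set has size ≥ 2. Two deliberate properties of this rule:

* **Inosine contributes 0.** It was introduced precisely to avoid 3–4-fold
  degenerate positions, and it pairs with any template base, so it needs no
  compensation in the mix.
* **Counting is positional, not combinatorial.** A 3-base position (e.g. D)
  counts as one degeneration even though variant expansion enumerates all
  three alternatives. This keeps `V = 2^N` consistent with the published
  recipe while `expand_variants` stays combinatorially exact.

In-silico PCR scans both strands of a template with the full mix, treating a
window as an annealing site when every template base lies in the primer's
position set (inosine = wildcard), allowing up to `max_mismatch` violations
(default 2 — the tolerance during amplicon extraction is not standardized, so
it is a configuration knob). All forward×reverse site pairs in productive
orientation with an inner length within [291, 379] bp (the observed GH48
amplicon range) are reported; amplicons are primer-free by default because
downstream analyses operate on sequences without primers. Coordinates are
0-based half-open in the frame of the reported strand. There is no
thermodynamic model: mismatches are per-position Hamming violations, with no
3'-anchor weighting, because no such model is calibrated for this cocktail.

## Reference database construction

GenBank flat files are parsed with Biopython. A database entry is one CDS
whose product matches a GH48 name pattern (case-insensitive substring; both
"glycosyl" and "glycoside" spellings) or whose protein accession is on an
explicit allow-list (rescuing entries annotated only as "hypothetical
protein" — these are retained but flagged, and excluded from calibration
subsets). "Multispecies" products are excluded. The 16S rRNA gene is the
first feature annotated "16S ribosomal RNA" in file order — a deliberate,
reproducible tie-break for genomes with multiple rRNA operons. Taxonomy is
joined on the txid from the source feature.

Species or strains with several assemblies keep only the best one
(complete > chromosome > scaffold > contig, ties broken by lexicographic
assembly id); the species/strain key is the whitespace-normalized organism
name. Assembly level is metadata of the NCBI Assembly database, not of the
flat file, so `build_database` accepts an external locus → (assembly, level)
mapping and also reads `assembly:<id>; level:<level>` tags from source-feature
notes (the synthetic fixtures embed these); otherwise contig is assumed.
Partial CDS are flagged and skipped by the translation-consistency check;
16S length is not filtered at build time (full-length ≥ 1200 nt is required
only when building calibration subsets).

## Pairwise identity

Identity is computed from a global alignment with free end gaps: terminal
overhangs are excluded and an internal run of gap columns counts as one
difference (the mothur "onegap" convention; per-column counting is available
because the convention used in published distance matrices is ambiguous).

For equal-length sequences down to 50% identity the comparison is ungapped
(column-wise). This is a considered choice, not just an optimization: marker
amplicons of one gene family evolve mostly by substitution, and a
dynamic-programming aligner with affine gap costs will, on substitution-only
pairs beyond ~20% divergence, occasionally find paired-indel alignments that
score a few points higher and inflate identity — alignment noise rather than
homology. The ungapped path keeps identity arithmetic exact, which the
synthetic-data design relies on. Length-mismatched or near-unrelated pairs go
through the aligner.

## Threshold calibration

Two routes convert taxonomy conventions into marker thresholds:

1. **Identity correlation.** For all unordered pairs of reference organisms,
   marker-amplicon identity is regressed on 16S identity (the regression
   direction is fixed this way because thresholds are read off at given 16S
   identities). Models: linear and polynomial (default degree 2; the degree
   used in the published fit is unstated, so 2 and 3 are both reported by the
   CLI). Diagnostics: adjusted R², RMSE with denominator n (a documented
   choice; n−p is equally defensible and the published values cannot
   disambiguate), MAE, and PRESS computed exactly as Σ(e_i/(1−h_ii))² from
   the hat matrix — verified in tests against brute-force leave-one-out
   refitting. Predictions at 95/97/99% 16S identity are rounded half-up to
   integer percent and flagged when they extrapolate beyond the observed 16S
   range.

2. **Clustering agreement.** Sequences are clustered greedily
   (UCLUST-style): processing order is descending length then lexicographic
   id (the de-facto convention; input order must not matter), and a sequence
   joins the first centroid at or above the threshold. Agreement at a
   threshold is the percentage of sequences whose cluster is pure with
   respect to their taxon label. Purity is the primary definition because a
   statement like "all sequences correctly clustered at 100% identity" is
   only consistent with purity (at 100% every unique sequence is its own
   cluster, so completeness-style definitions would not reach 100%); the
   pairwise co-clustering definition is available as a mode. The calibrated
   threshold is the smallest grid point (1% steps) with 100% agreement. With
   outlier exclusion enabled, sequences sitting in impure clusters at the
   best grid point are reported and removed (sequences, not pairs — both are
   reported), and the curve is recomputed; this mirrors the removal of
   putatively misclassified or horizontally transferred reference genes.
   Integer grid thresholds make floor-rounding of identities before
   comparison equivalent to direct comparison, so no separate rounding step
   exists.

## Amplicon profiling

Merged, demultiplexed reads are processed deterministically:

1. trim 10 bp from each end;
2. keep reads with post-trim length in [320, 500] bp and expected-error
   *rate* EE/length ≤ 0.02, where EE = Σ 10^(−Q/10) ("rate" is taken at
   face value; a total-EE mode would be the UPARSE default and is a
   configuration choice);
3. dereplicate exactly, carrying counts;
4. greedy-cluster unique sequences into OTUs at 94% identity (the calibrated
   genus threshold);
5. classify each centroid by best hit against the reference amplicons:
   ≥ 94% → genus of the best hit; 80–94% → "unknown \<family of best hit\>";
   < 80% → "unclassified". The 80% family fallback is this package's
   parameter (no published family cutoff exists); both thresholds are
   configurable. Ties break to the highest identity, then the smallest
   reference id.

Outputs: OTU × sample read counts, per-OTU taxonomy, taxon × sample relative
abundances (percent of kept reads; columns sum to 100), and α-diversity
(richness, Shannon with natural log, Simpson 1 − Σp²). Chimera removal is
not performed, and read pairing/demultiplexing are upstream of this tool.
The "minimum quality for unpaired reads" knob is accepted for configuration
completeness but unused, as the tool only sees merged reads.

## qPCR quantification

The standard curve is an ordinary least-squares fit of Ct against
log10(copies/µL) over a serial dilution (≥ 4 points spanning ≥ 3 decades).
Efficiency is `(10^(−1/slope) − 1)·100`; QC requires efficiency in
[85, 125]% and a y-intercept (Ct at one copy) in [35, 40] — the accepted
bands for trustworthy absolute quantification. Copy numbers of plasmid
standards follow from mass and molecular weight with the per-strand residue
weights A 313.21, T 304.2, C 289.18, G 329.21 and −61.96 per strand (the
Sequence Manipulation Suite convention), doubled for dsDNA.

Sample Cts are inverted through the curve per technical replicate; the mean
and sample SD (ddof 1) are reported, with a flag below the 10³ copies/µL
limit of quantification. The GH48/16S ratio is 100 × marker/16S copies,
presented rounded half-up to one decimal; its SD is propagated to first
order (relative variances add) and reported unrounded. Ratios are flagged
unreliable when either quantification is below the LOQ.

## Synthetic data

The generators make every pipeline stage testable without downloads; their
defaults are fixed study conditions, not tuning knobs.

* **Correlated divergence** (`make_correlated_pairs`): a star phylogeny per
  genus on a 1500 nt 16S gene and a 375 nt marker amplicon. Every branch
  substitutes a *disjoint* set of sites, so pairwise divergences add exactly
  and, with the marker substitution count locked to
  `multiplier × 16S site fraction × marker length`, every pair lies exactly
  on `marker_identity = 100 − m·(100 − rrna_identity)`. The default
  multiplier 6 reproduces the observed regime (97% 16S ↔ ~82% marker
  amplicon; the 94% marker genus threshold ↔ ~99% 16S identity); default
  bands are within-genus 16S (99, 100]%, between-genus [94, 97]%. The 375 nt
  length sits in the observed amplicon range and keeps the substitution
  count scaling integral. Optional Gaussian jitter (in identity percent) on
  the marker branch lengths produces realistic scatter; it is off by
  default so the closed-form arithmetic holds. Substitution-only evolution
  (no indels) is deliberate for the same reason.
* **GenBank genomes** (`make_genbank`): one genome per strain embedding the
  strain's marker between concrete cel48-Mix2 primer-site variants with 0–2
  planted mismatches per site (deterministic cycle), inside a ~1.5 kb
  stop-free CDS; plus complement-strand and joined-location cases, decoy CDS
  (wrong family, "MULTISPECIES", hypothetical-but-allow-listed), 1–2 16S
  copies (the second mutated so the first-copy rule is observable), embedded
  assembly metadata, and a duplicate lower-quality assembly of the first
  strain. All coordinates, sequences and planted mismatch counts are emitted
  as a ground-truth table.
* **Reads** (`make_reads`): reads are drawn from reference amplicons at
  configured taxon proportions with i.i.d. substitution errors (default 1%)
  and a constant quality string at the matching Phred score.

What the fixtures do **not** emulate: indels and alignment ambiguity, rRNA
operon heterogeneity beyond one mutated copy, chimeras, PCR/abundance bias,
quality-score variation along reads, and the taxonomic imbalance of the real
reference snapshot. Passing tests therefore demonstrate correctness of the
machinery (parsing, bookkeeping, clustering, fitting, inversion), not field
performance on real communities; snapshot-scale published statistics (entry
counts, fitted thresholds, community compositions) are data-dependent and
require the real reference snapshot and read archive, which the pipeline
accepts through the same file interfaces.

## Numerical choices and limitations

* Greedy clustering joins at `identity + 1e-9 ≥ threshold` to absorb float
  noise at integer grid points; the clustering is deterministic given the
  input set.
* Fit diagnostics use exact linear algebra (hat matrix); no iterative
  optimization is involved anywhere.
* `fit_standard_curve` rejects non-negative slopes, < 4 points, or < 3
  decades of dilution rather than guessing.
* Ratio presentation rounds half-up via decimal arithmetic (`3.75 → 3.8`),
  avoiding binary-float tie surprises.
* Greedy clustering is O(n·k) alignments (k clusters); the intended scale is
  dereplicated amplicon sets up to a few thousand uniques, not raw read
  archives.
* The profiler holds reads in memory; samples are processed independently.
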
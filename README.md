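# markerkit

Toolkit for analysing bacterial communities through a **functional marker
gene**: the GH48 (glycoside hydrolase family 48) cellulase gene, whose
presence marks truly cellulolytic bacteria — degraders of crystalline
cellulose. Unlike 16S rRNA profiling, which sees every bacterium, GH48
amplicon sequencing and qPCR measure the cellulolytic fraction of a
community (e.g. in biogas fermenters, rumen, soil) directly.

`markerkit` covers the full stack:

* **primers** — model degenerate oligonucleotides (IUPAC codes, bracket
  groups, deoxy-inosine), compute the cocktail mixing recipe by the rule
  *V = 2^N* µL (N = number of two-or-more-base positions, inosine excluded),
  expand variants, and run in-silico PCR / amplicon extraction. The
  published cel48-Mix2 cocktail (16 forward + 9 reverse primers, ~344 bp
  product) ships with the package.
* **refdb** — build a combined reference database from GenBank flat files:
  one entry per GH48 CDS, linked to the assembly's 16S rRNA gene, protein
  sequence and ranked taxonomy; deduplicate assemblies; find identical
  modules/amplicons; summarize database parameters.
* **calibrate** — regress marker-amplicon identity on 16S rRNA identity
  (linear/polynomial, with adjusted R², RMSE, MAE and exact leave-one-out
  PRESS), convert 16S thresholds (95/97/99%) into marker thresholds, and
  calibrate an OTU threshold by clustering agreement with taxonomy across a
  1% identity grid. The calibrated genus threshold for GH48 amplicons
  is **94%** identity.
* **profile** — filter merged amplicon reads (trim, length, expected-error
  rate), dereplicate, cluster OTUs at 94%, classify by best hit against the
  reference (genus / "unknown \<family\>" / "unclassified"), and produce
  abundance and α-diversity tables.
* **qpcr** — fit standard curves (efficiency and y-intercept QC), compute
  plasmid-standard copies from mass and molecular weight, invert sample Cts
  to absolute copies/µL, and report the GH48/16S gene-copy ratio — a proxy
  for the cellulolytic potential of a sample.
* **synth** — deterministic synthetic fixtures (GenBank genomes, correlated
  marker/16S divergence with known slope, labelled read sets) so the whole
  pipeline is testable offline.

## Worked example

```python
from markerkit import load_cel48_mix2, mix_volume, degeneracy_count
from markerkit.qpcr import fit_standard_curve, quantify, marker_ratio
from markerkit.synth import SynthConfig, make_correlated_pairs
from markerkit.calibrate import build_pairset, fit_model, predict_threshold

# 1. degenerate-primer mixing rule
mix = load_cel48_mix2()
f6 = next(p for p in mix.primers if p.id == "F6")
print(f"F6: N={degeneracy_count(f6)}, V={mix_volume(f6)} uL")

# 2. qPCR standard curve, quantification, marker ratio
curve = fit_standard_curve([(10**k, -3.5*k + 37.7) for k in range(3, 10)])
print(curve.summary())
gh48 = quantify([curve.ct_at(c) for c in (5.5e6, 5.8e6, 5.8e6)], curve,
                sample="MS1", target="GH48")
rrna = quantify([curve.ct_at(c) for c in (6.9e8, 7.2e8, 7.2e8)], curve,
                sample="MS1", target="16S")
print(marker_ratio(gh48, rrna))

# 3. identity correlation on synthetic correlated-divergence data
data = make_correlated_pairs(SynthConfig(seed=1, jitter_sd=1.0))
fit = fit_model(build_pairset(data.entries), "linear")
print(fit.summary())
print("marker threshold at 97% 16S identity:", predict_threshold(fit, 97)[0])
```

prints

```
F6: N=3, V=8 uL
standard curve over 7 dilution points
  slope = -3.5000  y-intercept = 37.70 Ct  R2 = 1.0000
  efficiency = 93.1% [QC 85-125%: PASS]
  intercept QC [35-40 Ct]: PASS
MS1: GH48/16S = 0.8%
linear fit (degree 1, n=66)
  coefficients: b0=-497.602, b1=5.98161
  adj. R2 = 0.9901   RMSE = 1.1254   MAE = 0.9088   PRESS = 88.8049
  16S identity range observed: [94.53, 100.00]
marker threshold at 97% 16S identity: 83
```

Reading the output: primer F6 carries three two-base positions, so it enters
the cocktail at 2³ = 8 µL. The simulated qPCR run has 93.1% amplification
efficiency and a 37.7-cycle y-intercept — inside both quality-control bands
— and sample MS1 contains 0.8 GH48 gene copies per 100 16S rRNA gene copies.
The synthetic reference set was generated with marker divergence 6× the 16S
divergence plus 1% identity jitter; the fitted slope (≈ 5.98) recovers that
rate, and reading the fit at the conventional 97% 16S genus boundary places
the equivalent marker-amplicon threshold at 83% identity.

## Command line

Every stage is also a `markerkit` subcommand operating on standard formats
(FASTA, FASTQ, GenBank flat files, TSV):

```bash
markerkit primers mix --out recipe.tsv
markerkit primers ispcr --templates genes.fasta --max-mismatch 2 --out amplicons.fasta
markerkit refdb build --genbank genomes/ --taxonomy tax.tsv --out combined
markerkit calibrate fit --amplicons amp.fasta --rrna 16s.fasta --out fit.tsv
markerkit calibrate agreement --amplicons amp.fasta --labels labels.tsv --grid 60:100 --out curve.tsv
markerkit profile --fastq S1.fastq --reference amp.fasta --lineage lin.tsv --outdir out/
markerkit qpcr --standards std.tsv --runs runs.tsv --out quant.tsv
markerkit synth genbank --seed 1 --out fixtures/
```

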
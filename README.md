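# mybkit

A toolkit for characterizing a plant transcription-factor gene family — built
around the MYB family of *Capsicum* (pepper) — from sequence to expression:

- **MYB repeat detection and classification.** The MYB DNA-binding domain is
  an imperfect ~52-aa repeat with regularly spaced aromatic anchors: three
  tryptophans 20–21 residues apart in the R2 repeat, and a phenylalanine plus
  two tryptophans 19 residues apart in the R3 repeat. Proteins are classed by
  adjacent repeat count: 1R (MYB-related), R2R3, 3R, 4R, or atypical.
- **Duplicate-pair evolution.** Duplicate gene pairs (identity > 75%,
  coverage > 75%) are classed tandem (< 100 kb on one chromosome) or
  segmental, and their synonymous/nonsynonymous divergence is estimated by
  the Nei–Gojobori (1986) method with Jukes–Cantor correction:
  `Ka = -(3/4) ln(1 - (4/3) pN)`, likewise `Ks` from `pS`, with
  ω = Ka/Ks classifying selection (ω < 1 purifying, ω > 1 positive).
  Divergence dates assume a synonymous clock, `T = Ks / (2λ)` with
  λ = 6.96×10⁻⁹ substitutions/site/year.
- **Synteny.** Homolog anchors between two genomes are chained by dynamic
  programming into conserved syntenic segments (forward or reversed gene
  order), with summary statistics per chromosome.
- **Promoter features.** Strand-aware 1.5-kb upstream extraction, perfect
  SSR detection (2–6 nt motifs, ≥ 6 copies, period-minimal, maximal runs),
  and IUPAC cis-element scanning on both strands.
- **Expression.** TMM normalization, FPKM, a negative-binomial
  likelihood-ratio test with the adj *p* < 0.01 & FC > 1.5 significance
  rule, Pearson-distance co-expression clustering, and 2^−ΔΔCt qPCR
  quantification.
- **Synthetic data.** A ground-truthed generator (genomes with planted
  repeats, duplicate pairs evolved to chosen ω and Ks, planted SSRs,
  rearranged partner genomes, NB count matrices with planted fold changes)
  replaces genome downloads, so every stage is tested against known truth.

The audience is genomicists running gene-family surveys who want each
pipeline stage as a tested, scriptable function rather than a chain of web
services.

## Worked example

```python
from mybkit.synthetic_data import SimulationConfig, DuplicationEvent, simulate_family_genome
from mybkit.duplication_evolution import analyze_duplicates

cfg = SimulationConfig(seed=2026, duplication_events=[DuplicationEvent("tandem", 0.2, 0.5)])
pkg = simulate_family_genome(cfg)
for p in analyze_duplicates(pkg.proteins, pkg.cds, pkg.gene_models):
    print(p.gene_a, p.gene_b, p.mode, round(p.omega, 3), round(p.t_mya, 2))
```

The scripted study (`python analysis/01_simulate.py` … `07_expression.py`)
prints, among others:

```
3 duplicate pairs pass the >75% identity/coverage filters (2 tandem)
  G0003-G0003d1: tandem, Ka/Ks 0.203 (planted omega 0.2), T 35.76 MYA
  G0019-G0019d2: tandem, Ka/Ks 0.604 (planted omega 0.6), T 8.52 MYA
EG vs MG: 176 significant genes (recall on planted |log2FC|=2: 85.0%)
recovered 17/17 planted repeats within +/-2 aa
```

i.e. the NG86 estimator recovers the ω each pair was evolved under, the
tandem pair at Ks ≈ 0.5 dates to ~36 million years under the synonymous
clock, and the differential-expression stage finds 85% of genes planted with
a 4-fold change at three replicates per stage. Each driver writes its tables
under `results/`.

A `mybkit` console script exposes the same stages
(`mybkit simulate|identify|protprop|dupevol|synteny|promoter|express|qpcr`).

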
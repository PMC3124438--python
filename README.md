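# fessurvey

Genome-survey analysis of fosmid-end sequences (FES): what can a sparse
sample of ~500-bp clone-end reads say about a large, repeat-rich genome?
`fessurvey` implements the full analysis chain used in survey-sequencing
studies of organisms without a reference genome — originally motivated by
penaeid shrimp, whose ~2.2-Gb genomes are so repetitive that assembly
fails and end-sequencing a fosmid library is the practical way in.

The package covers five stages, each usable on its own:

- **`fessurvey.simulate`** — a synthetic FES generator (reads 100–861 bp,
  mean ≈531 bp, configurable GC) that plants microsatellites and
  interspersed repeat families with full ground truth, so every detector
  can be scored without any real data.
- **`fessurvey.tandem`** — microsatellite detection: a k-mer self-match
  scan proposes candidate periods (1–6 bp), and each candidate is resolved
  by **wraparound dynamic programming** against an unbounded cyclic
  repetition of the unit (match +2, mismatch −3, indel −5; arrays kept at
  score ≥ 50, length ≥ 12 bp, purity > 55%).
- **`fessurvey.motifs`** — canonical motif classes: the class label of a
  unit is the lexicographically smallest string among all rotations of the
  unit and of its reverse complement, so TC/CT/GA/AG are one class (AG)
  and the arthropod telomere unit TTAGG is AACCT.  There are 2 / 4 / 10
  classes of unit 1 / 2 / 3.
- **`fessurvey.landscape`** — the survey report: per-class counts, summed
  bases, length statistics, relative abundance (RA, % of microsatellite
  bp) and relative frequency (RF, % of loci), overall density (kb per
  locus), L1–L11 length-class histograms, and genomic-vs-transcript
  partition comparison.
- **`fessurvey.families`** — de novo interspersed-repeat discovery on
  tandem-masked reads: all-vs-all seeded local alignment, aggregation of
  hit intervals into elements, single-linkage clustering with orientation
  propagation, star-alignment consensus, automated merge/split curation,
  a ≥20-copy retention filter, rRNA-style exclusion screening, and
  genome-fraction/copy-number accounting.
- **`fessurvey.genome_metrics`** — flow-cytometry genome sizing (G1-peak
  ratio × 3.50 pg human-lymphocyte standard) and the survey calculators:
  library coverage `clones × insert / genome`, sampling fraction, and gene
  count `coding_fraction × genome / gene_size`.

## Worked example

Sizing a genome from flow cytometry and extrapolating the survey
(`examples/05_genome_size.py`):

```
standard G1 peak: channel 400.0
sample G1 peak:   channel 289.0
ratio:            0.723
DNA content:      2.53 pg per nucleus
haploid genome:   2.17 Gb

fosmid library coverage: 5.3x haploid equivalents
gene count (7-10 kb genes): 10,405 - 14,864
gene density: one per 146 - 208 kb
```

A nucleus fluorescing at 72.3% of the 3.50-pg standard carries ≈2.53 pg of
DNA, i.e. a ≈2.17-Gb haploid genome; a 288,000-clone, 40-kb-insert fosmid
library then covers it ≈5.3-fold, and a 4.8% coding fraction with 7–10-kb
genes implies roughly 10,000–15,000 genes.

Detecting a compound microsatellite (`examples/02_detect_microsatellites.py`):

```
  29-106  period 2  motif TC  class AG  copies  38.5  score  154  purity 1.00
 118-146  period 2  motif CA  class AC  copies  14.0  score   56  purity 1.00
 179-209  period 3  motif AAT  class AAT  copies  10.0  score   50  purity 0.93
```

The adjacent (CT)₃₈ and (CA)₁₄ arrays are reported as two separate loci of
the AG and AC classes — compound repeats are never merged — and the
diverged (AAT)₁₀ array keeps its full span with purity reflecting its
substitutions.

The other example scripts cover simulation with ground truth (`01`), the
motif landscape report (`03`) and de novo family discovery (`04`); each
prints a short, annotated result.  The same stages are available as a thin
CLI (`fessurvey simulate | scan-ssr | summarize | families | genome-size |
survey | run`).

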
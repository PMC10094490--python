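# castechip

Desk-scale analysis of caste-specific histone-mark chromatin and gene
expression in honey bee larvae.

Genetically identical female honey bee (*Apis mellifera*) larvae develop into
queens or workers depending on diet, and chromatin marks such as H3K4me1 — a
hallmark of primed and active enhancers — are candidates for encoding that
developmental switch. A typical experiment profiles H3K4me1 by ChIP-seq and
expression by RNA-seq in queen (Q) and worker (W) larvae, three replicate
colonies per caste, and asks: which genomic regions carry caste-specific
H3K4me1, where do those regions sit relative to genes (promoter, intron,
exon), which genes are differentially expressed, and do chromatin and
expression changes move together?

`castechip` implements that entire analysis as a tested Python library with a
CLI, together with a synthetic-data generator that plants known truth
(caste-unique peaks, differential peaks with known fold changes,
differentially expressed genes, a target chromatin–expression correlation),
so every stage can be validated end to end without any sequencing data.

## What it computes

* **Caste-unique peaks** — a consensus peak (replicate peak calls merged at
  ≥1 bp overlap) is *unique* to a caste when it is present in **all**
  replicates of that caste and in **none** of the other; this strict
  all-or-nothing rule is evaluated before any statistical test.
* **Differential peaks** — consensus peaks present in both castes are tested
  with Welch's t on log2 library-size-normalized signal; a peak is
  differential when *p* < 0.05 and fold change > 2 (both thresholds
  configurable), with direction Q-over-W.
* **Peak position annotation** — each peak is assigned the feature category
  of its midpoint with precedence promoter > exon > intron > intergenic
  (promoter = TSS − 2000 bp to TSS + 200 bp, strand-aware, configurable),
  and the caste-wise promoter/intron/exon distribution is compared with a
  Pearson χ² test.
* **Differential expression** — a self-contained negative-binomial pipeline:
  median-of-ratios size factors, pooled moment dispersion (NB variance
  μ + αμ²), a Wald test on log2(m̂_Q/m̂_W) with delta-method standard errors,
  Benjamini–Hochberg FDR; genes with adjusted *p* ≤ 0.05 are DEGs. FPKM
  (count·10⁹ / (length·total)) is available for reporting.
* **Integration** — peaks are linked to genes (promoter window or gene body,
  nearest-TSS tie-break) giving differential-peak genes (DPGs); DEG∩DPG
  overlaps, Spearman correlation between per-gene peak and expression log2
  fold changes, a strand-aware TSS coverage metaprofile, and a generic
  hypergeometric over-representation test against user-supplied gene sets
  (GMT).
* **qPCR verification** — 2^−ΔΔCT relative quantification against a
  reference gene and control group, with Welch t-tests on ΔCt.

See `docs/methods.md` for the models, defaults, and their rationale.

## Worked example

Run the full simulate → classify → test → integrate pipeline at the default
study conditions (2 castes × 3 replicates, 500 genes on a 5 Mb chromosome,
60 planted unique peaks per caste, 80 differential peaks, 400 background
peaks, 100 DE genes):

```python
from castechip.pipeline import RunConfig, run_pipeline
from castechip.synth import SimulationConfig

config = RunConfig(sim=SimulationConfig(seed=1))
report = run_pipeline(config, "runs/example")
```

`runs/example/report.txt` then reads (abridged):

```
castechip summary — comparison Q_vs_W (seed 1)

consensus peaks: 600
unique peaks: {'Q': 60, 'W': 60}
differential peaks: {'up_Q': 37, 'up_W': 39}
unique peak feature %: {'Q': {'promoter': 20.0, 'intron': 60.0, 'exon': 20.0},
                        'W': {'promoter': 60.0, 'intron': 20.0, 'exon': 20.0}}
distribution test: {... 'chi_squared': 24.0, 'dof': 2, 'p_value': 6.14e-06}
DEGs: {'total': 120, 'up': 60, 'down': 60} of 500 genes
DPGs: 76
DEG ∩ DPG: {'n1': 120, 'n2': 76, 'intersection': 14, ...}
signal–expression correlation: {'all_linked': {'rho': 0.342, 'n': 76,
                                               'p_value': 0.0025}, ...}
TSS metaprofile argmax offset: -25.0
```

Reading this: all 120 planted caste-unique peaks were recovered exactly (60
per caste, none spurious); 76 of the 80 planted differential peaks passed
the p < 0.05 / fold > 2 rule; worker-unique peaks concentrate in promoters
and queen-unique peaks in introns, and the χ² test rejects equality of the
two distributions (χ² = 24.0, p = 6.1 × 10⁻⁶); the NB test declares 120
DEGs (the 100 planted DE genes plus peak-coupled genes); the measured
Spearman correlation between peak and expression fold changes (ρ = 0.34
over 76 linked genes) matches the planted target of 0.3; and mean H3K4me1
coverage peaks within one 50 bp bin of the TSS.

The same stages are exposed on the command line:

```bash
castechip simulate --outdir sim --seed 1
castechip classify-peaks --manifest manifest.tsv --gff sim/genome.gff3 --out peaks.tsv
castechip diffexpr --counts sim/counts.tsv --samples sim/samples.tsv --out de.tsv
castechip integrate --peaks peaks.tsv --deg de.tsv --gff sim/genome.gff3 --outdir integration
castechip qpcr --ct sim/qpcr_ct.tsv --target gene0042 --control W --out qpcr.tsv
castechip run --outdir runs/example --seed 1
```

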
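# Methods

This note documents the models behind `castechip`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate, and
the numerical decisions a maintainer should know about. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and annotation geometry

All internal coordinates are 0-based half-open (BED convention); GFF3's
1-based closed coordinates are converted in the readers/writers and nowhere
else. The TSS coordinate of a gene is its `start` boundary on the + strand
and its `end` boundary on the − strand, so the TSS is always the half-open
boundary immediately 5′ of the first transcribed base and window arithmetic
is strand-symmetric.

The promoter window defaults to **2000 bp upstream to 200 bp downstream** of
the TSS. There is no universal promoter definition for *Apis mellifera*; this
is a conventional choice and is configurable everywhere it enters (peak
annotation, peak–gene linking, the simulator). A degenerate zero-width
request returns a 1-base window at the TSS rather than erroring, so sweeps
over window sizes stay total.

A genomic position is classified with precedence
**promoter > exon > intron > intergenic**. The three genic categories are
treated as mutually exclusive because the caste-wise distribution test is run
over exactly {promoter, intron, exon}; intergenic peaks are reported but
excluded from that test. Ties between genes within a category resolve by
absolute TSS distance, then gene id, making classification deterministic
under overlapping annotations. All interval logic is tested against an
exhaustive per-base oracle on small chromosomes.

## Peak classification

Replicate peak calls are merged into **consensus peaks** wherever intervals
overlap by ≥ 1 bp (touching intervals do not merge). A replicate is *present*
on a consensus peak when one of its intervals overlaps it by ≥ 1 bp — presence
is deliberately binary and strict, because the uniqueness rule is defined on
detection, not signal strength. A replicate's signal on a consensus peak is
the overlap-weighted mean score of its overlapping intervals, 0 when absent.

Classification order:

1. **Caste-unique**: present in all replicates of one caste and no replicate
   of the other. Evaluated first; peaks absent from a whole caste are never
   fed to the differential test, so the unique and differential sets are
   disjoint by construction.
2. **Differential**: requires ≥ 2 replicates with nonzero signal per caste.
   Signals are library-size normalized (each replicate's total consensus
   signal scaled to the median library), and Welch's two-sided t is computed
   on log2(signal + 1) over all replicates of each caste (an absent replicate
   contributes 0 signal — absence is informative). The fold change is
   (mean_Q + 1)/(mean_W + 1); the pseudo-count keeps ratios finite. A peak is
   differential when p < α (default 0.05, raw — no multiplicity correction,
   matching the stated peak-calling rule; the inflation risk at thousands of
   peaks is real and is why the DEG analysis, which drives gene lists, uses
   FDR control) and max(fc, 1/fc) > 2.
3. Remaining testable peaks are **shared**; peaks with fewer than two
   nonzero-signal replicates in either caste are **unresolved**.

Peaks are annotated by the feature category of their midpoint
(floor((start+end)/2)): midpoint assignment is deterministic and
order-independent, unlike maximal-overlap schemes that need tie-breaking on
equal overlaps.

The caste-wise category distribution is compared with a Pearson χ² test
(no continuity correction, expected counts from margins,
df = (rows−1)(cols−1)); a zero row or column margin is an error naming the
margin rather than a silent NaN.

## Negative-binomial differential expression

Counts are modeled as NB with variance μ + αμ². The stages:

* **Size factors**: median-of-ratios — factor_j = median over genes of
  count_gj / geometric-mean_g, restricted to genes positive in every sample.
  A `pseudo_reference` fallback (geometric mean of counts + 1, all genes)
  exists for sparse matrices.
* **Dispersion**: the per-gene method-of-moments estimate pools
  (s² − μ̄)/μ̄² within each group, weighted by group df. With n = 3 per group
  this estimate has ~4 df and is far too noisy to plug into a
  normal-reference Wald test: in NB simulations the resulting z behaves like
  a t with ~4 df and the test rejects ~12% of nulls at α = 0.05. The default
  (`method="common"`) therefore assigns every gene the across-gene mean of
  the unclipped moment estimates — the small-n regime where borrowing
  strength across genes is essential, and the same reason established NB
  tools moderate their dispersions. Because moments are taken within groups,
  true expression differences do not inflate the pooled value. In NB
  simulations at the study's conditions this restores the nominal level
  (measured type-I ≈ 0.05; see the acceptance suite). The trade-off is that
  genuinely gene-specific dispersions are flattened; `method="per-gene"`
  keeps the raw estimates for such data.
* **Wald test**: log2FC = log2 m̂_Q − log2 m̂_W on normalized group means;
  when a group mean is 0, 0.5 is added to both means (flagged in the output)
  to keep the fold change finite. The SE of each group's log2 mean comes from
  the delta method, SE = sqrt((m̂ + αm̂²)/(n m̂²))/ln 2; z = log2FC/SE_diff and
  p = 2Φ(−|z|). Computing the difference of logs (not the log of the ratio)
  makes a group swap negate every log2FC bit-exactly.
* **BH adjustment**: standard step-up with enforced monotonicity, input order
  preserved; DEG ⇔ p_adj ≤ 0.05. No fold-change filter is applied to DEGs.
* **FPKM**: count · 10⁹ / (length · per-sample total), lengths from summed
  exon widths.

## Integration

A peak links to at most one gene: a midpoint inside a promoter window links
as `promoter`; otherwise a midpoint inside a gene span links as `gene_body`;
intergenic midpoints yield no link; ties resolve by nearest TSS. DPGs are
genes linked to ≥ 1 differential peak.

The signal–expression correlation pairs, per linked gene, the mean log2 fold
change of its differential peaks with its expression log2FC, both oriented
Q-over-W so a positive ρ means co-directional chromatin and expression
change. Two variants are reported: all linked genes, and DEGs only (the
population being correlated is a genuine analysis choice, so both are
given). Spearman's ρ uses average ranks with the large-sample t
approximation, and needs ≥ 3 pairs.

Over-representation uses the upper-tail hypergeometric P(X ≥ k) per gene set
with BH across sets. The universe defaults to all annotated genes and should
be set deliberately — universe choice dominates ORA results. Gene sets come
from user GMT files; no pathway database is fetched.

The TSS metaprofile averages per-base coverage in uniform bins (default
50 bp) over ±2 kb around every TSS, strand-flipped so negative offsets are
always upstream; genes truncated by a chromosome edge contribute only their
covered bins. Reported offsets are bin centers.

## qPCR quantification

Technical replicates are averaged per (sample, gene); ΔCt = Ct_target −
Ct_reference per sample; ΔΔCt subtracts the control group's mean ΔCt; RQ =
2^−ΔΔCt. Group tests are Welch t on ΔCt by default — ΔCt is the
approximately normal scale — with a flag to test on RQ instead. The control
group (i.e., the orientation of the fold change) is always an explicit
argument. Amplification-efficiency correction is out of scope.

## The synthetic-data generator

The simulator emulates the *structure* of a two-caste, three-replicate
larval ChIP-seq + RNA-seq experiment, not its sequencing physics: no reads,
no mappability or GC bias, no chromatin-state model. Defaults (one 5 Mb
chromosome, 500 non-overlapping genes of 2–10 kb with 2–6 exons, 1 kb peaks,
NB dispersion 0.05, peak mean 100, RNA mean 200) are invented but sized so
the analysis exercises the same regimes as a real experiment. Peak width,
replicate concordance, and library depth have no published values for this
design; the chosen values are flagged here as the package's own.

Planted structure, all recorded in a truth manifest:

* **Unique peaks** (60/caste): present in all replicates of their caste with
  ±50 bp boundary jitter, absent from the other caste. Worker-unique peaks
  are placed 60% in promoters (midpoint at the TSS ± 100 bp), the remainder
  split intron/exon; queen-unique peaks 60% in introns — mirroring the
  caste-asymmetric placement the analysis is designed to detect. A `dropout`
  knob removes a peak from one own-caste replicate to exercise the
  strictness of the all-replicates rule; it defaults to 0.
* **Differential peaks** (80): present in both castes, group means split
  geometrically by a planted log2FC of ±2.0 with a lognormal spread
  (σ = 0.15). The spread exists because exactly two-valued fold changes tie
  all ranks and cap the achievable rank correlation with expression; σ was
  set so the 2.5th percentile |log2FC| stays near 1.5 (fold ≈ 2.8), clear of
  the 2-fold detection threshold. Each differential peak is hosted by a
  distinct gene (60% promoter / 20% intron / 20% exon).
* **Background peaks** (400): intergenic, equal means in both castes.
* **Expression**: NB counts with per-sample lognormal depth factors
  (σ = 0.15). 100 DE genes (disjoint from peak hosts) get ±1.5 log2FC.
  Genes hosting differential peaks get expression effects drawn from a
  Gaussian copula on the ranks of their peak log2FCs with Pearson parameter
  r = 2 sin(πρ/6), so the planted Spearman correlation matches the
  `signal_expression_rho` target (0.3 by default); the construction keeps
  every transformation monotone, which is what makes the rank correlation
  land on target, and the acceptance suite verifies the calibration at
  targets 0 and 0.9 by simulation.
* **Coverage**: each peak contributes a triangular profile with its summit at
  the peak midpoint (a fragment-pileup shape). A flat box would leave the
  TSS metaprofile with a plateau whose argmax is arbitrary.
* **qPCR**: Ct = baseline − log2(relative expression) + N(0, σ = 0.2), with a
  constant-expectation reference gene, so the ΔΔCt round trip is exact at
  σ = 0.

Placement keeps every planted peak ≥ 300 bp (including jitter head-room) from
every other, so no two planted classes can merge into one consensus peak and
class exclusivity survives the analysis. Gene placement distributes the free
space after reserving minimum intergenic gaps, which always succeeds when the
genes fit and raises a "genome too dense" error when they cannot — with the
default gene-length range, 500 genes need roughly a 4.1 Mb chromosome, hence
the 5 Mb default.

What passing tests therefore show: the classification rules, tests, and
integration recover *known* structure under NB noise at realistic effect
sizes, and the statistical tests hold their nominal error rates under the
simulator's null. What they do not show: robustness to peak-caller
artifacts, alignment bias, batch effects, or dispersion heterogeneity beyond
the NB model — real-data caveats the simulator does not attempt to emulate.

## Problem sizes used in the checks

The test suite and acceptance script run at the defaults above (500 genes,
600 planted peaks, 6 samples) for end-to-end checks; calibration
measurements use 2000 genes for the NB null and planted-recovery rates,
2000 simulations for the χ² type-I rate, 500 peak–gene pairs × 20 seeds for
the correlation calibration, and 10 seeds for planted-recovery averages.
These sizes give Monte-Carlo standard errors comfortably inside the asserted
bands while keeping a full run to minutes on one CPU.

## Known limitations

* Two-group designs only; no covariates, no multi-factor GLM, no outlier
  refitting or independent filtering in the NB pipeline.
* The differential-peak test uses raw p-values by design (documented above);
  treat differential-peak *counts* as threshold-dependent.
* Peak–gene assignment is midpoint-based and promoter/gene-body only; distal
  enhancer–promoter pairing (e.g., from chromatin contact data) is out of
  scope.
* The common-dispersion default assumes dispersions are exchangeable across
  genes; use `method="per-gene"` (and more replicates) when they are not.
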
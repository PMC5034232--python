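# Methods

`primex` implements an analysis stack for species-specific exome studies in
macaques: a codon site-model scan for positive selection with bespoke
alignment filters and a dual-tree consensus, cohort-wide pseudogene calling
from disruptive variants, and capture-design/capture-performance
evaluation.  Every stage can be exercised on synthetic data generated by
the package itself; this note records the models, the defaults, and the
design choices.

## The selection scan

### Substitution model

Coding sequences evolve over the 61 sense codons of the standard genetic
code under the Goldman–Yang (GY94) model.  The instantaneous rate from
codon *i* to codon *j* is

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

for pairs differing at exactly one nucleotide, and zero otherwise; `kappa`
is the transition/transversion rate ratio, `omega = dN/dS`, and `pi` the
stationary codon frequencies.  The chain is reversible, so transition
matrices come from one symmetric eigendecomposition per distinct
`(kappa, omega)` rather than repeated matrix exponentials.  Within a
site-class mixture all class matrices share a single scale factor — the
mixture-weighted mean substitution rate — so branch lengths are expected
codon substitutions per codon site at the model's mean omega, and the
relative speed of the selected class is preserved.

Codon frequencies default to F3x4 (position-specific nucleotide
frequencies estimated from each gene's alignment, floored at 1e-6 and
renormalized); empirical F61 frequencies are available via
`codon_freq="f61"`.  F3x4 is the default because it spends 9 rather than
60 effective degrees of freedom on frequencies, which matters for genes of
a few hundred codons.

### Site models and the test

* **M0** — a single omega shared by all sites; used only to estimate
  branch lengths per gene.
* **M7** — omega ~ Beta(p, q), discretized into `ncat = 10`
  equal-probability classes whose values are the conditional means of the
  beta over each quantile bin (computed from regularized incomplete-beta
  ratios, exact for Beta(1,1): 0.05, 0.15, …, 0.95).
* **M8** — the M7 classes with total weight `p0` plus one selected class
  at `omega_s >= 1` with weight `1 - p0`.

Positive selection is tested per gene by `D = 2(lnL_M8 - lnL_M7)`, clamped
at zero, against chi-square with 2 degrees of freedom (for which
`p = exp(-D/2)`).  The true null distribution of D places mass at zero and
below chi-square(2) because `omega_s = 1` / `p0 = 1` sit on the boundary of
the parameter space, so the test is conservative at nominal alpha; the
calibration suite measures exactly this.

### Likelihoods

Site likelihoods use Felsenstein pruning over unique site patterns, with
all class/edge transition matrices batched.  Masked or ambiguous codons
(and any codon containing a gap or N) are missing data: the tip sums over
all 61 states, so a fully masked site contributes exactly zero
log-likelihood.  Numerical safeguards: transition probabilities are
clipped at zero after reconstruction; per-node rescaling of partial
likelihoods is engaged automatically if a site's mixture likelihood
underflows (irrelevant for shallow primate trees, active for deep or
long-branch inputs).

### Optimization

All fits are bounded L-BFGS-B on log- (rates, shapes, branch lengths) or
logit- (`p0`) transformed parameters, with `ftol` set so the optimum is
resolved to ~1e-6 log-likelihood units; fits are deterministic given
identical inputs.

* Branch lengths are estimated once per gene by joint ML under M0 (with
  kappa and omega) and then held fixed for M7 and M8.  This halves the
  cost of the expensive mixture fits; re-optimizing lengths under each
  site model (as codeml does) is available via `joint_branch_lengths=True`.
* M7 starts from a small deterministic grid of `(p, q, kappa)` points
  (kappa seeded from the M0 estimate); the best-scoring start is optimized
  fully, all of them under `full_multistart=True`.
* M8 starts from the M7 solution with either a modest
  (`p0 = 0.9, omega_s = 2`) or a substantial (`p0 = 0.5, omega_s = 4`)
  selected class.  Deliberately, no start lies on the nested-M7 ridge
  (`p0 -> 1` or `omega_s -> 1`): such a start scores best initially but
  traps the optimizer on a flat boundary and systematically deflates D.
  After optimization the likelihood is floored at the value of the
  degenerate point `(p7, q7, p0 -> 1, omega_s -> 1)` — which *is* the M7
  optimum — so nesting (`lnL_M8 >= lnL_M7`) holds by construction and
  boundary-MLE genes report `D = 0` rather than small negative noise.

### Multiple testing

q-values follow Storey's method: `pi0` estimated on the grid
`lambda = 0.05 … 0.95` from `mean(p > lambda)/(1 - lambda)`, smoothed with
a cubic spline and read off at `lambda = 0.95`, then applied to the
Benjamini–Hochberg step-up quantities.  With fewer than 100 tests, or a
non-positive `pi0` estimate, the estimator falls back to plain BH
(`pi0 = 1`).  Output is monotone in p and capped at 1.

### The dual-tree consensus

Stage 1 tests every QC-passed gene on the fixed species topology
`((CM,HM),(IR,(CR,(CC,(IC,MC)))))` and computes q-values across all genes.
Stage 2 re-tests only the stage-1 hits (q < 0.1) on each gene's own
neighbor-joining tree — NJ on pairwise Kimura-2-parameter ML nucleotide
distances, negative branch lengths clamped at zero, masked sites excluded
from the distances — with q-values recomputed within the hit set.  A gene
is finally selected only when below the FDR cutoff in both stages.
Requiring the signal to survive under both tree hypotheses guards against
false positives driven by gene-tree/species-tree discordance.  The NJ
gene trees provide the alternative topology cheaply; only the topology
matters downstream because branch lengths are re-estimated under M0
before the stage-2 fits.  Chromosome enrichment of the final gene set is
a one-sided hypergeometric test per chromosome against the background
composition, BH-adjusted.

## Alignment QC

* **Intactness** — per taxon, a premature stop is any in-frame
  TAA/TAG/TGA strictly before the final codon after removing that
  sequence's gaps; a frameshift is any gap run whose length is not a
  multiple of 3, or a gap-stripped length not a multiple of 3 (so 3N gaps
  preserve frame and do not disqualify).  A gene is retained iff at least
  `min_intact_species = 6` taxa are intact, and non-intact taxa are
  dropped from the retained alignment rather than discarding the gene.
* **Block-substitution masking** — for each sequence, mismatches are
  counted against the column-majority consensus of the other sequences
  (ties broken toward the alphabetically first base; columns where either
  side is undefined are skipped).  Any window of 9 aligned positions with
  >= 6 mismatches is masked in that sequence only, extended to whole
  codons so the codon model never sees partial codons.  Masked positions
  are missing data downstream.  Masking only adds to the mask, hence is
  idempotent and monotone in the trigger.  The window slides in alignment
  coordinates; the comparison baseline is swappable to a designated
  reference taxon.

## Pseudogene calling

Variant effects are classified from first principles against the spliced
sense-strand CDS (strand-aware; indels by `|length| mod 3`; an SNV
creating a stop before the final codon is `stop_gain`, in the final codon
`other`).  A gene is called pseudogenized when **every** individual of the
cohort carries at least one homozygous stop-gain or frameshift variant in
it; the site need not be shared (`same_site=True` gives the strict shared-
site mode).  Start-loss, stop-loss, and splice variants are classified
`other` and never disrupt — only stop-gains and frameshifts are actioned.
The indel reading-frame spectrum reports the histogram of |length|, the
3N fraction, and a two-sided exact binomial test against lengths uniform
on 1..L.

## Capture design and evaluation

* **Design** — equal-length, gap-free aligned CDS region pairs from the
  two genomes merge into one probe target when they mismatch at fewer
  than 3 bases (`merge_max_mismatch = 2`), the first genome's sequence
  serving as representative; merged targets are extended by
  `flank = 100 bp` on both sides, clipped at chromosome bounds, and
  overlapping extensions merged.  Theoretical coverage is the fraction of
  input exonic bases inside the final intervals.
* **Gene coverage** — fraction of a gene's coding bases at depth
  >= `depth_threshold = 20`; a gene is *failed* below 20% coverage,
  *successful* above 80%, intermediate otherwise (boundaries strict).
* **Saturation** — per effort fraction f, every base's depth is thinned
  Binomial(depth, f) — the depth law induced by uniform random read
  subsampling — and exome-wide coverage at >= 1x and >= 20x recomputed;
  f = 1 bypasses thinning and reproduces the full-depth coverage exactly.
* **Reproducibility** — pairwise Pearson r between replicate per-gene
  coverage vectors on the raw fractions (no transform), with
  zero-variance replicates reported as missing.

## Synthetic data

The generators produce inputs with the statistical structure the pipeline
assumes, with these defaults as the reference study conditions:

* **Tree** — the seven-taxon primate topology above with branch lengths
  (codon substitutions per codon) of 0.06 for the CM/HM tips, 0.24 across
  the ape–macaque split after unrooting, and 0.008–0.03 within macaques:
  a primate-realistic depth where the human–macaque path is ~0.33.
* **Null genes** — M7 with `p = 0.5, q = 1.5` (mean omega 0.25, mass
  piled toward strong constraint); **selected genes** — M8 with the same
  beta, `p0 = 0.9`, `omega_s = 4`.  `kappa = 2`; root states drawn from
  the stationary codon frequencies (uniform by default).
* **Disruptions** — premature stops or 1–2 bp gaps injected into 1–4
  random taxa of a configurable fraction of genes, to exercise the
  intactness filter; 3N gaps injectable for the frame-spectrum tests.
* **Capture** — per-base depth is negative-binomial (dispersion 8) with
  mean `mean_depth * eff(d)`; efficiency is 1 for the species-specific
  platform and logistic, `1/(1 + exp(s (d - d0)))`, for the cross-species
  platform with midpoint `d0 = 0.05` and steepness `s = 150`, so
  efficiency is ~1 at zero divergence, 1/2 at 5%, and ~0 at 10% — a
  functional form chosen to drop sharply beyond 5% divergence.  The
  functional form and the noise law are modeling choices of this package.
* **Cohort variants** — disruptive records placed per a carrier matrix,
  plus Poisson background synonymous/missense records.

Every generator is a pure function of its spec including the seed.

What the simulations do *not* emulate: alignment error (beyond the block
artifacts injected deliberately), recombination and among-gene tree
discordance, indel realism (placement is uniform), sequencing error and
PCR duplicates, GC-dependent capture bias, and paralogy.  Passing tests
therefore demonstrate correctness of the machinery under its own model,
not performance on real exomes.

## Reference problem sizes

The calibration and power suites run at: 200 null genes x 300 codons for
type-I behavior (LRT rejection at alpha = 0.05 and final dual-tree
discoveries), 20 selected genes x 500 codons for power and omega_s
recovery, and 20 replicate capture panels of 300 genes for the platform
asymmetry.  These sizes give binomial standard errors of ~1% on the
rejection rate and ~11% on the power estimate while keeping a full run on
one core in the tens of minutes; the same computation at larger n only
narrows the intervals.

## Known limitations

* Branch lengths fixed from M0 are an approximation; codeml re-optimizes
  them per site model.  The effect on D is small for shallow trees but
  not zero; `joint_branch_lengths=True` removes the approximation at
  ~5-10x cost.
* The chi-square(2) reference makes the M7–M8 test conservative at the
  boundary (observed null rejection a little under nominal), which is the
  standard behavior of this comparison.
* NJ gene trees replace full ML tree search; adequate here because only
  the stage-2 topology is consumed.
* The block-masking consensus baseline (majority of the other sequences)
  is one of several defensible definitions; the alternative (designated
  reference) is exposed as an option in spirit via the per-sequence
  implementation.
* F61 frequencies on very short genes lean on the 1e-6 frequency floor.
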
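# Methods

`mtspike` estimates, for each subset of sorted single cells, the proportion
of cells whose mitochondrial mutation load (heteroplasmy) is *near zero* —
the cells that have effectively cleared a pathogenic variant such as
m.3243A>G — and compares that proportion between cell subsets. This note
describes the statistical model, the sampler and its independent oracle,
the upstream read-level and QC procedures, the synthetic-data generator
used for validation, and known limitations.

## The spike-and-slab mixture

Per-cell variant allele fractions Y ∈ (0,1) within one subject × cell-type
subset are modelled as

    Y ~ π · N01(μ, σ²) + (1 − π) · U(0, 1)
    π ~ π0 · δ0 + (1 − π0) · U(0, 1)

where N01 is a normal truncated to (0,1) (the "spike" of near-zero cells),
U(0,1) the "slab" of cells spread over the whole range, and δ0 a point mass
at zero: with probability π0 there is no spike at all. Priors:
μ ~ U(0, 0.2), σ ~ Exp(5), π0 ~ U(0, 1). The estimand is π, the near-zero
proportion.

π0 enters the posterior only through its prior mean, so it is integrated
out analytically: the marginal prior probability of "no spike" is
E[π0] = 1/2. This is exact and removes one dimension from the sampler.

### MCMC sampler (`fit_mcmc`)

Each iteration applies, in order:

1. **Allocations.** When the spike is present (s = 1), each cell's latent
   component indicator is drawn from its exact conditional,
   z_i ~ Bernoulli(π f(y_i) / (π f(y_i) + 1 − π)).
2. **Spike weight.** π | z ~ Beta(n_spike + 1, n_slab + 1) (conjugate
   under the uniform prior).
3. **Spike parameters.** Metropolis updates: μ with a reflected
   random-walk proposal on [0, 0.2] (step 0.02), σ with a log-scale
   random walk (step 0.4, Jacobian included, Exp(5) prior). When no cell
   is currently allocated to the spike the conditional is the prior, and
   (μ, σ) are drawn from it exactly — this makes the trans-model moves mix
   well from the empty state.
4. **Trans-model move.** A flip between {s = 0} and {s = 1} is attempted
   with probability 1/2 per iteration. Moving up proposes π* from its
   U(0,1) prior; the acceptance ratio is the *marginal* (allocation-summed)
   likelihood ratio L(π*, μ, σ) / L0 with the slab-only likelihood L0 ≡ 1,
   so the move is valid from any state without reversible-jump dimension
   matching. The 1/2 attempt probability keeps the chain aperiodic in the
   data-free limit, where the flip would otherwise be accepted every
   iteration.

Defaults: 4 chains × 30,000 iterations, 10,000 burn-in, thinning 4 →
20,000 retained draws. Chain seeds are spawned deterministically from one
master seed. Convergence is screened by a split-chain R-hat on π; values
above 1.05 raise a warning and are stored in the fit metadata, never
silently dropped. In every retained draw s = 0 ⇔ π = 0 exactly, so the
point mass survives into all downstream summaries.

**Boundary values.** Finite read counts can give VAFs of exactly 0 or 1,
which have zero density under both components. Such values are nudged into
the open interval by half a read, 0 → 1/(2·depth) and 1 → 1 − 1/(2·depth),
and the number of nudged cells is reported. Loads given in percent must be
divided by 100 before fitting; the model lives on (0,1).

### Quadrature oracle (`grid_posterior`)

An independent deterministic route to the same posterior, used to validate
the sampler (and directly usable for subsets up to a few hundred cells).
Each prior coordinate is discretised at mid-quantiles of its own prior
(uniform for π and μ, Exp(5) for σ), giving equal-weight nodes whose
average is a prior expectation. Then

    P(s = 0 | Y) = ½ / (½ + ½ · E_prior[L(π, μ, σ)])

and the continuous marginal of π is the (μ, σ)-averaged likelihood,
normalised. Default grid 160 × 60 × 60; all sums run in log space. A
refinement self-check (doubling all resolutions) raises an error if
P(s = 0) moves by more than the tolerance. The oracle is itself
cross-checked in the tests against brute-force Monte-Carlo prior
integration.

Validation: on seeded datasets with n ∈ {10, 30, 90}, sampler and oracle
agree to |ΔE[π]| < 0.005, |ΔP(s=0)| < 0.005, and decile CDF gaps < 0.02 —
an order of magnitude inside the tolerances the test suite enforces
(0.02 / 0.03 / 0.03).

## Posterior summaries and comparisons

**Peak estimates.** The posterior of π is summarised by its mode(s): the
point mass at 0 is reported as a mode when P(s = 0 | Y) exceeds a
threshold (default 0.25), and continuous modes are local maxima of a
Gaussian KDE with reflection at both boundaries (Silverman plug-in
bandwidth, overridable) whose prominence exceeds 10% of the density
maximum. Multiple modes are reported when the posterior is bi/multimodal.
The height assigned to the zero mode for primary-mode selection treats the
point mass as if smeared over ~0.02 — a presentation convention only.

**Credible intervals** are equal-tailed sample quantiles (linear
interpolation). HPD intervals would be attractive given the point mass but
equal-tailed matches the plain reading of a "95% credible interval"; the
choice is confined to one function.

**Pairwise comparison.** Two subsets differ when zero lies outside the
equal-tailed 95% interval of the posterior difference of their π draws.
Because the two chains are independent, pairing of draws is arbitrary;
iteration-order pairing is used and recorded, with a seeded permutation
option for sensitivity. No multiple-testing correction is applied across
pairs; the report counts comparisons so users can adjust. `gradient_report`
assembles per-subject peak estimates along a declared maturity order
(naive → CM → EM → TEMRA) and runs all within-group pairs.

## Read-level pipeline

Reads carry a well barcode at the 5′ end followed by the amplicon body.
Demultiplexing matches the prefix exactly against the barcode table, trying
the read as given and its reverse complement; matched reads are re-oriented
to the template strand and the barcode stripped. Exact matching (no
mismatch rescue) is safe because barcodes are generated at pairwise Hamming
distance ≥ 3. At the single target position (0-based offset within the
template; the genomic label m.3243 is metadata), bases are counted as
reference (A) or variant (G) only when their Phred quality is ≥ 28; other
bases, sub-threshold bases and too-short reads are tallied as discarded.
The per-base cutoff is the conservative re-reading of an aligner-pipeline
"minimum average quality of 28" for a single-position counter.
VAF = alt / (ref + alt); zero-depth wells are an explicit error and must be
excluded by QC. A streaming demultiplex-and-count path handles
multi-million-read files in one pass at constant memory.

## Quality control

Three filters, applied per sequencing batch to cell wells:

* **Contaminated plates.** Each plate has exactly one cell-free
  negative-control well; a control depth above `negative_control_max_depth`
  (default 10 reads — the source analysis states no numeric criterion)
  drops the whole plate.
* **Lower depth.** Fixed threshold, or "auto": the smallest observed depth
  at or above a floor (default 200). The original per-batch choice was by
  visual inspection and is not reproducible; the floor-based stand-in is
  deterministic and errs conservative.
* **Upper depth (doublets).** Default rule excludes depth > 1.5 × Q3 — the
  literal reading of "1.5 times the upper boundary of the interquartile
  range" — with the classic Tukey fence Q3 + 1.5·(Q3 − Q1) available as a
  configured variant. Quartiles use linear interpolation between order
  statistics (R type-7), named in the config because conventions differ
  near ties.

Thresholds are resolved once per batch from the input distribution and
recorded in the QC report; re-applying a report's resolved thresholds is
idempotent (naively re-estimating Q3 on a filtered set would keep
shrinking it). The report books every exclusion per plate (sums are exact)
and summarises retained depths as median / IQR / range.

## qPCR copy number

Ct is linear in log10 template copies. The standard curve (six 10-fold
plasmid dilutions) is fitted by least squares; curves with slope outside
[−3.449, −3.264] or r² < 0.9992 (assay-validated ranges) are flagged.
Copies per reaction = 10^((Ct − intercept)/slope); copies per cell divide
by n_cells × volume_factor, where volume_factor is the fraction of the
lysate loaded into the reaction (default 1/25 = 5 µl of a 1:5 dilution of
a 25 µl lysate; the exact bookkeeping is assay-specific and configurable).
Plate effects are removed by (absolute / on-plate control) × mean control.
Replicate QC excludes samples with triplicate Ct SD > 0.3 or mean Ct > 30;
one replicate may first be dropped as a within-triplicate outlier when the
remaining pair is tight (SD ≤ 0.3) and the dropped value deviates from the
pair mean by more than 3× the pair's spread ("within-sample outlier" is
otherwise undefined; this rule is recorded per sample).

## Synthetic-data generator

The generator emulates the structure the analysis assumes, with every
planted value exported so downstream filters and estimates have exact
expected outcomes:

* per-cell VAFs from the same spike-and-slab family as the model
  (truncated-normal spike by default; a hard-zero option plants exact
  clearance, deliberately off-model; uniform or beta slab);
* log-normal read depths, median 1,146 with log-SD 0.70 so the central
  99% spans ≈ 190–7,000, truncated at 1 — calibrated to the assay's
  reported retained-depth distribution;
* 96-well plates of a single subset each, one negative-control well per
  plate; subsets default to 91 cells (the assay's median subset size);
* artefacts with planted flags: doublets (two cells' depth- and count-sums;
  default rate 0.02), failed wells (trickle depth ≤ 50), contaminated
  plates (cell-like control depth; default rate 0.05), stray
  negative-control reads (Poisson, mean 2);
* per-base miscall rate 0.005 applied symmetrically (variant fraction
  h(1−e) + (1−h)e) — the real assay's error and doublet rates are not
  published; these are plausible, configurable placeholders;
* optional FASTQ emission realising the planted counts read-by-read
  (barcode + template with A/G at the marked offset, either orientation,
  Phred+33 qualities), so demultiplex → count reproduces planted counts
  *exactly* when the error rate is zero and qualities sit above the
  counting cutoff.

What the generator does **not** emulate: lineage dynamics over age,
PCR-cycle amplification bias, chimeric or partial-barcode reads,
paired-end chemistry, batch effects in depth. Passing tests therefore
demonstrate correctness of the pipeline's logic and calibration of the
inference under the model's own assumptions — not robustness to every
failure mode of real sequencing data.

## Validation sizes

The test suite and the acceptance script regenerate everything from seeds:
oracle-vs-sampler agreement on five datasets (n ∈ {10, 30, 90}; full
20,000-draw fits); credible-interval coverage and RMSE over 20 subsets of
91 cells with π ∈ {0, 0.2, 0.5, 0.8} (compact 2-chain fits, 4,000 draws);
null and separated comparison calibration over 20 pairs each (3,500-draw
fits); a 3-plate FASTQ identity check (~400k reads) plus a 20-plate
planted-QC cohort; a 10-subject, 4-cell-type gradient panel; and the
copy-number fixtures. These sizes keep a full run in a few minutes while
leaving Monte-Carlo error well inside every asserted tolerance.

## Known limitations

* **Slab-mimicry ridge.** Under σ ~ Exp(5), large-σ truncated normals are
  nearly uniform on (0,1), so the spike can imitate the slab. For subsets
  with few near-zero cells the posterior of π acquires a long upper tail
  (and sometimes a second mode), inflating E[π] and widening credible
  intervals — the quadrature oracle confirms this is the model's true
  posterior, not a sampler artefact. Consequences: posterior means of π
  are upward-biased at small true π, and the power of the
  posterior-difference test against such subsets is materially below what
  point estimates alone would suggest (≈ 0.8 per pair at planted 0.1 vs
  0.6, n = 91). Practitioners wanting sharper inference should tighten the
  σ prior on substantive grounds; the package keeps the published priors.
* The equal-tailed difference interval with iteration pairing is one of
  several defensible conventions; the permutation option quantifies the
  (small) sensitivity.
* "Auto" depth thresholds and the negative-control cutoff are stand-ins
  for judgements the original analysis made by inspection; both are
  explicit config values so a re-analysis can match a lab's practice.
* The oracle's μ and σ marginals are reported conditional on spike
  presence; mix with the prior using P(s = 0 | Y) if the unconditional
  marginal is needed.
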
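# mtspike

Single-cell mitochondrial heteroplasmy analysis: from barcoded amplicon
reads to per-cell variant allele fractions, through plate-level quality
control, to a Bayesian estimate of the proportion of cells that have
(nearly) cleared a pathogenic mtDNA variant — with credible-interval
comparisons between cell subsets and a qPCR copy-number module.

**Who it is for.** Groups running plate-based single-cell genotyping of a
heteroplasmic point variant (e.g. m.3243A>G in MT-TL1): cells FACS-sorted
into 96-well plates (one negative-control well per plate), amplified with
well-specific barcoded primers, sequenced as a pooled amplicon library. The
question is not just the mean mutation load of a cell population but what
fraction of its cells sit in the near-zero "cleared" spike — the signature
of ongoing selection against the variant, e.g. along the naïve → memory
T-cell axis.

## The model

Per-cell variant allele fractions Y ∈ (0,1) in one subject × cell-type
subset follow a spike-and-slab mixture with a point mass on "no spike":

    Y ~ π · N01(μ, σ²) + (1 − π) · U(0, 1)
    π ~ π0 · δ0 + (1 − π0) · U(0, 1)

with priors μ ~ U(0, 0.2), σ ~ Exp(5), π0 ~ U(0, 1). N01 denotes a normal
truncated to (0,1) — the near-zero spike — and δ0 the Dirac mass at zero,
so π0 is the probability that no spike exists at all. The near-zero
proportion π is the estimand. Inference is by a purpose-built MCMC sampler
(allocation Gibbs + Metropolis + a marginal-likelihood trans-model move
for the point mass), validated draw-distribution-for-draw-distribution
against an independent dense-quadrature oracle. Two subsets are called
different when zero lies outside the 95% equal-tailed credible interval of
the posterior difference of their π draws.

A synthetic-data module generates plates, barcodes, per-well counts and
optional FASTQ with fully known ground truth, so the entire pipeline is
testable without any patient data. See `docs/methods.md` for the complete
methodological account.

## Worked example

Simulate one subject with a naïve subset (planted near-zero proportion
0.10) and an effector-memory subset (0.80), 91 cells each, run QC, fit the
mixture, and compare:

```python
import numpy as np
from mtspike import (SubsetTruth, SequencingSpec, build_plates,
                     apply_qc, QCConfig)
from mtspike.spike_mixture import fit_mcmc, nudge_boundary
from mtspike.summary_compare import (credible_interval, peak_estimates,
                                     compare_pair)

rng = np.random.default_rng(3)
cohort = [SubsetTruth("P1", "naive", n_cells=91, pi_true=0.10),
          SubsetTruth("P1", "EM", n_cells=91, pi_true=0.80)]
plates, truth = build_plates(cohort, SequencingSpec(), rng)
retained, report = apply_qc(truth, QCConfig())
print("retained", len(retained), "cells;", report.retained_depth_summary)

fits = {}
for ct in ("naive", "EM"):
    sub = retained[retained.cell_type == ct]
    y, _ = nudge_boundary(sub.alt_count.to_numpy() / sub.depth.to_numpy(),
                          sub.depth.to_numpy())
    fits[ct] = fit_mcmc(y, seed=1)
    pk = peak_estimates(fits[ct])
    lo, hi = credible_interval(fits[ct])
    print(f"{ct}: E[pi]={fits[ct].mean_pi:.3f} "
          f"P(no spike)={fits[ct].p_no_spike:.3f} "
          f"peak={pk.primary_mode:.3f} 95% CI=({lo:.3f}, {hi:.3f})")

pc = compare_pair(fits["EM"], fits["naive"], label_a="EM", label_b="naive")
print(f"EM - naive: mean diff={pc.mean_diff:.3f} "
      f"95% CI=({pc.ci_low:.3f}, {pc.ci_high:.3f}) "
      f"significant={pc.significant}")
```

Output:

```
retained 166 cells; {'n': 166, 'median': 1173.5, 'iqr': [698.25, 1732.75], 'range': [223.0, 3016.0]}
naive: E[pi]=0.042 P(no spike)=0.680 peak=0.000 95% CI=(0.000, 0.251)
EM: E[pi]=0.853 P(no spike)=0.000 peak=0.865 95% CI=(0.758, 0.928)
EM - naive: mean diff=0.811 95% CI=(0.585, 0.923) significant=True
```

Reading this: QC kept 166 of 182 sorted cells (the rest were planted
doublets/failed wells) and summarises their read depths. For the naïve
subset the posterior finds little or no spike (68% probability of *no*
spike; peak estimate at π = 0), for the memory subset a large one
(peak 0.865), and the posterior difference between the proportions
excludes zero — the memory subset has a significantly larger cleared
fraction, recovering the planted gradient.

The same flow is available from the shell:

```
mtspike simulate --out run/ --seed 3 --fastq
mtspike demux --fastq run/reads.fastq --barcodes run/barcodes.tsv --out run/counts.tsv
mtspike qc --counts run/truth.tsv --out run/qc
mtspike fit --cells run/qc/retained_cells.tsv --out run/fits --seed 1
mtspike compare --fits run/fits --order naive,CM,EM,TEMRA --out run/cmp
mtspike run --config config.yaml --out run/   # everything, one manifest
```

`mtspike cn` handles qPCR copy-number plates (standard-curve fit,
absolute quantification, plate normalisation, replicate exclusions), and
`mtspike oracle` computes the deterministic quadrature posterior for small
subsets.

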
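# burstlnc

Transcriptional burst kinetics and *cis*-regulation of long noncoding RNAs
(lncRNAs) from allele-resolved single-cell RNA-seq — a tested, reusable
re-implementation of the full analysis pipeline, exercisable end to end on
synthetic data with known ground truth.

## The problem

lncRNAs are expressed at far lower levels and far more heterogeneously
across cells than mRNAs. In F1 hybrid cells (CAST/EiJ × C57BL/6J), SNPs let
every transcript be assigned to its parental allele, so transcription can be
read out *per allele per cell*. That resolution makes two questions
tractable:

1. **How do lncRNA promoters burst?** Under the two-state (telegraph) model
   a promoter switches ON/OFF with rates `k_on`/`k_off` and transcribes at
   `k_syn` while ON; steady-state counts follow a Beta-Poisson mixture
   `x ~ Poisson(k_syn·p), p ~ Beta(k_on, k_off)`. Burst frequency is
   `k_on` (per mRNA lifetime), burst size `k_syn/k_off`. Fitting this model
   per gene×allele by maximum likelihood, with bootstrap CIs and a
   likelihood-ratio test for kinetic changes, quantifies *how* lncRNA
   transcription differs: chiefly through rarer bursts, secondarily through
   smaller ones. RNA half-lives from an actinomycin-D time course convert
   burst frequencies into hours between bursts
   (`duration = t_half / (k_on · ln 2)`).
2. **Which lncRNAs act in *cis*?** A lncRNA that regulates a neighbour on
   its own chromosome leaves an allelic signature: both genes skewed toward
   the same parental allele (allelic-score permutation test against random
   gene relocations) and co-detected on the same allele across single cells
   (per-allele Fisher's exact test against the same relocation background).

Around these sit the supporting analyses: QC presets, promoter-architecture
classification (divergent / convergent / intergenic / separated units), the
expression-matched CV² permutation machinery, and cell-state association
(principal-curve cell-cycle staging, phase-specific ANOVA, apoptosis-cluster
discovery, guilt-by-association).

The pipeline is written for method validation and reuse: every statistical
structure it assumes can be simulated by `burstlnc.synth` with recorded
truth, and every stage is tested against that truth.

## Worked example

```python
import numpy as np
from burstlnc import TwoStateKinetics
from burstlnc.synth import sample_beta_poisson
from burstlnc.kinetics import bootstrap_ci, lrt_kinetics, burst_duration_hours

truth = TwoStateKinetics(k_on=0.5, k_off=5.0, k_syn=50.0)   # burst size 10
counts = sample_beta_poisson(truth, n_cells=1000, seed=2)
fit = bootstrap_ci(counts, n_boot=100, seed=3)
k = fit.kinetics
print(f"k_on {k.k_on:.2f}  CI [{fit.ci_low['k_on']:.2f}, {fit.ci_high['k_on']:.2f}]")
print(f"burst size {k.burst_size:.1f}  CI [{fit.ci_low['burst_size']:.1f}, "
      f"{fit.ci_high['burst_size']:.1f}]")

other = sample_beta_poisson(TwoStateKinetics(1.0, 5.0, 50.0), 1000, seed=4)
res = lrt_kinetics(counts, other, "frequency")
print(f"lambda_LR {res.lambda_lr:.1f}  log2 ratio {res.theta_hat:.2f}  "
      f"significant: {res.significant_one_sided}")
print(f"time between bursts at t_half = 4 h: "
      f"{burst_duration_hours(k.k_on, 4.0):.1f} h")
```

prints

```
k_on 0.54  CI [0.47, 0.61]
burst size 10.0  CI [8.5, 12.5]
lambda_LR 49.6  log2 ratio 1.00  significant: True
time between bursts at t_half = 4 h: 10.7 h
```

The fitted `k_on` of 0.54 per mRNA lifetime (truth 0.5) with a tight CI, the
burst size of 10 molecules, the decisive likelihood-ratio statistic for the
planted twofold frequency change (log2 ratio 1.00, threshold 3.84), and the
~11 h between bursts for a 4-hour half-life are exactly the kinds of numbers
the pipeline produces per gene and allele on real data.

The `analysis/` directory holds numbered drivers that run the whole study on
simulated data (`01_simulate.py` … `07_state.py`), each printing what it
found and writing its tables under `results/run/`. The same stages are
available as a CLI: `burstlnc simulate --seed 1 --out results/run`, then
`burstlnc qc …`, etc.

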
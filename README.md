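# atacploidy

Ploidy inference, proliferation (S-phase) scoring, and copy-number
variation detection from single-cell / single-nucleus ATAC-seq fragment
data — no extra assay required, just a standard 10x-style
`fragments.tsv(.gz)` file.

## The statistical idea

At any autosomal site of a *p*-ploid nucleus, the number of sequenced
fragments covering the site is binomial(*p*, *s*), where *s* is the
per-chromosome-copy capture probability (PCR duplicates collapse to one
fragment, so the trial count is the copy number). Observing all genomic
sites is impractical, so the observation points are restricted to the
distinct 5′ ends (positive strand) of each cell's fragments; the depth
there is then zero-truncated binomial. Tallying, per cell, the number
of 5′-end sites covered by exactly *x* fragments gives the
**fragment-end depth count statistics** (FEDECS) *f₁, f₂, …, f₆*.

With T₁ = Σ x·f_x and T₂ = Σ x²·f_x, the ratio statistic

    U = T₂ / T₁ − 1

satisfies E[T₂]/E[T₁] − 1 = (p − 1)·s, with the unknown number of sites
cancelling. Everything in the package builds on U:

* **Method of moments** (`MomentPloidyModel`): across a cell mixture,
  log U clusters at log(p − 1) + log s — ratio (2−1):(4−1):(8−1) for a
  diploid/tetraploid/octoploid mix. A winsorized 1-D cluster fit
  estimates the shared ŝ and assigns each cell the nearest candidate
  ploidy (and a fractional ploidy U/ŝ + 1).
* **EM mixture** (`EMPloidyModel`): the counts (f₂, f₃, f₄) are modelled
  as a mixture of unconstrained categorical distributions, one per
  candidate ploidy — robust when the uniform-capture assumption fails.
  Components map to ploidies by their mass on the last category.
* **Polyploidy excess** (`PolyploidyExcessModel`): a binomial GLM with
  organ–cell-type and experiment covariates tests each group for more
  polyploid nuclei than the first-quartile background, with Bonferroni
  control.
* **S-phase score** (`SPhaseModel`): U computed separately near
  replication origins and termini; the residual of U_ori regressed on
  U_ter flags cells replicating their DNA.
* **CNV calling** (`CnvModel`): U per 20 Mb window, corrected for
  chromatin accessibility by a Huber regression on diploid cells;
  p̃ = 2(U′_cw + 1)/(U′_cell + 1) flags gains (≥ 3) and losses (≤ 1);
  runs of ≥ 2 windows concentrated in a cell subset are selected
  greedily by the drop in BIC of a two-block Bernoulli model.

A simulator (`atacploidy.simulate`) generates fragment files with
exactly this structure — including in-silico tetraploids/octoploids made
by merging diploid nuclei — so every stage is testable end to end.

## Worked example

Simulate a 300-nucleus mixture (100 each of diploid, tetraploid,
octoploid; s = 0.02; 20,000 sites per cell), compute FEDECS, and run
both inference routes:

```sh
atacploidy simulate fragments --ploidies 2,4,8 --n-cells-per 100 \
    --n-sites 20000 --s 0.02 --seed 11 --outdir demo
atacploidy fedecs demo/sim_fragments.tsv.gz --min-frag 1 \
    --max-frag 1000000 --outdir demo
atacploidy ploidy-moment demo/fedecs.tsv --outdir demo
atacploidy ploidy-em demo/fedecs.tsv --truth demo/sim_truth.tsv --outdir demo
```

prints

```
Moment-method ploidy inference
  cells:            300
  candidate set P:  {2, 4, 8}
  s_hat:            0.0199717
  calls:            2n: 100, 4n: 100, 8n: 100
EM categorical-mixture ploidy inference
  cells fitted:     300 (excluded: 0)
  candidate set P:  {2, 4, 8}
  used categories:  f2, f3, f4
  converged:        True (12 iterations, loglik -28605.6286)
  calls:            2n: 100, 4n: 99, 8n: 101
```

The moment method recovers ŝ ≈ 0.0200 (truth 0.02) and labels every
cell correctly; the EM route misassigns one tetraploid, and the
confusion report written next to the calls shows a diploid negative
predictive value of 1.0 — among cells flagged non-diploid, all are
truly polyploid. Per-cell output (`demo/ploidy_moment.tsv`) carries
U, T₁, T₂, the winsorized V, the assigned and the fractional ploidy:

```
barcode     U        T1       T2       V        ploidy  fractional_ploidy
cell0000    0.01833  20185.0  20555.0  -3.9992  2       1.9178
```

`atlas-test`, `sphase` and `cnv` subcommands continue the pipeline from
these TSVs; see `atacploidy --help`.

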
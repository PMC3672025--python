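# nextpeak

A strand-aware ChIP-seq peak caller built on the **normal-exponential two-peak
model**: a generative description of where sequencing tags land around a
transcription-factor binding site, fitted by per-region Poisson maximum
likelihood with censoring of unmappable genomic positions.

## Who this is for

Anyone calling transcription-factor binding sites from mapped ChIP-seq tags
(BED, SAM, or Bowtie text output) who wants, per peak: a continuous
binding-site location estimate **with a standard error**, an estimated
binding strength that **compensates for unmappable positions**, a
likelihood-ratio p-value for binding, and a goodness-of-fit p-value that
flags PCR spikes and multiple-binding regions.

## The model

A transcription factor bound at site center μ is cross-linked to DNA at a
latent coordinate ξ ~ N(μ, σ²). Sonication breaks the DNA an exponential
distance E ~ Exp(β) from the cross-link, so the 5′ end of a reverse-strand
("right") tag falls at x = ξ + E, with the exponentially modified Gaussian
marginal density

```
f_R(x | μ, σ, β) = Φ((x−μ)/σ − σ/β) · (1/β) · exp(−(x−μ)/β + σ²/(2β²))
```

Forward-strand ("left") tags mirror it: f_L(μ−z) = f_R(μ+z). Observed
per-position tag counts on each strand are independent Poisson with intensity

```
λ_j = ν·f(j | μ, σ, β) + ρ
```

where ν is the expected tag count per strand from one binding event (2ν̂ is
the peak rank statistic) and ρ a locally uniform background rate. Positions
whose tag sequence is not unique in the genome cannot receive tags and are
censored from the likelihood, so ν̂ estimates the *true* binding strength,
not just the visible tag count. (σ, β) are genome-wide and can be trained
from motif-anchored regions; (μ, ν, ρ) are per-region. Binding is tested by
the likelihood ratio against ν = 0 (χ², 1 df); model adequacy by the Poisson
deviance against a saturated model. As a by-product, the average sonication
fragment length is 2β̂ + d − 1 for tag length d.

## Worked example

```
nextpeak simulate --out-prefix sim --n-peaks 5 --chrom-length 200000 --seed 3
nextpeak call --tags sim.tags.bed --sigma 40 --beta 60 --out-prefix calls
nextpeak evaluate --peaks-tsv calls.tsv --sites-tsv sim.truth.tsv
```

which prints

```
{
  "n_true_positive": 5,
  "mean_distance": 1.38,
  "mean_bias": 0.98,
  "precision_at_last_rank": 1.0
}
```

All five planted sites are recovered (a call within 250 bp of a true site is
a true positive); the mean absolute location error is 1.38 bp and the mean
signed error +0.98 bp (positive = downstream). The first rows of `calls.tsv`
show the per-peak detail — e.g. the top-ranked call sits at site 94657.8
± 2.9 bp with binding intensity 2ν̂ = 456.8, LR p ≈ 8×10⁻¹⁴¹, and a
goodness-of-fit p of 1.0 (the single-event model fully explains the counts).

The same workflow runs on real data: `--format sam|bowtie` for other tag
dialects, `--mappability unmappable.bed` for censoring, and
`--motif-pfm motif.pfm --genome-fasta genome.fa` to train (σ, β) on
motif-anchored regions and to get screening cut-off recommendations (without
a motif, defaults σ = 30, β = 50 apply).

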
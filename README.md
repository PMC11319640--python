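# mosaicstr

Detection of somatic mosaicism at short tandem repeats (STRs) from
standard short-read sequencing of a single sample — no matched control
required — together with stutter-aware simulators for validating the
statistics end to end.

## The problem

A post-zygotic mutation at an STR leaves a fraction *f* of an
individual's chromosome copies carrying an extra allele *C* alongside
the germline diploid genotype ⟨A, B⟩ (alleles in repeat-unit copy
numbers). Mosaic STR alleles are hard to call because PCR/sequencing
stutter creates reads at non-germline repeat lengths that mimic exactly
this signal. `mosaicstr` is for researchers who already have STR
genotypes from a caller such as HipSTR (VCF with a per-allele read
support field, `MALLREADS`) and want per-locus, per-sample mosaicism
calls with calibrated p-values and FDR control.

## The model

Each read's observed repeat count *r* given a true allele *G* follows
the stutter error model with parameters Θ = {u, d, ρ}:

    S(r | G; Θ) = 1 − u − d                  r = G
                = u·ρ·(1 − ρ)^(r−G−1)        r > G   (expansion)
                = d·ρ·(1 − ρ)^(G−r−1)        r < G   (contraction)

If the mosaic allele arose on the haplotype carrying B, the read vector
R = {r₁, …, r_n} is modelled as i.i.d. draws from the mixture

    L_B(C, f | R) = ∏_{r∈R} [ ½·S(r|A) + (½−f)·S(r|B) + f·S(r|C) ]

and the log-likelihood is maximised over both haplotype-of-origin
cases, over integer-spaced candidate C in [min R − 3, max R + 3]
(excluding A and B), and over f ∈ [0, 0.5]. The null H₀: f = 0 is
tested with λ_LR = −2·[log L(Ĉ, 0) − log L(Ĉ, f̂)]; because f = 0 sits
on the parameter boundary, λ_LR is referred to a 50:50 mixture of a
point mass at 0 and χ²(2). Candidate calls are then screened with
Benjamini–Hochberg FDR plus hard filters (mosaic support ≥ 3 reads,
depth ≥ 10, f̂ ≤ 0.3, quality ≥ 0.8), cohort recurrence and region
masks.

## Worked example

Estimate detection power for a mosaic allele C = 14 at fraction
f = 0.2 on a heterozygous ⟨10, 12⟩ background, 100× coverage, PCR-free
stutter rates:

```sh
mosaicstr simulate --genotype 10,12 --mosaic 14:0.2 --coverage 100 \
    --stutter-preset pcr_free --reps 200 --seed 7 --out power.tsv
```

prints

```
   A    B mosaic_alleles  true_f_total  coverage     u     d  rho  n_reps  alpha  power  mean_f_hat  mean_C_hat  modal_C_hat
10.0 12.0       14.0:0.2           0.2       100 0.005 0.005  0.9     200   0.05    1.0    0.198635        14.0         14.0
```

i.e. at these settings every one of 200 simulated loci is detected at
p < 0.05 (`power 1.0`), the mean estimated mosaic fraction 0.1986 is
essentially unbiased for the true 0.2, and the mosaic allele is
recovered exactly (modal Ĉ = 14). The same machinery is available as a
library; a single locus:

```python
>>> import numpy as np
>>> from mosaicstr import LocusReadData, PCR_FREE, estimate_mosaicism
>>> from mosaicstr.simulate import SimulationSpec, simulate_read_vector
>>> spec = SimulationSpec(A=10, B=12, coverage=100, theta=PCR_FREE,
...                       mosaic_alleles=[(14, 0.2)], seed=7)
>>> reads = simulate_read_vector(spec, np.random.default_rng(7))
>>> estimate_mosaicism(LocusReadData(A=10, B=12, reads=reads, theta=PCR_FREE))
MosaicEstimate(C_hat=14.0, f_hat=0.176..., lambda_lr=187.04..., pvalue=1.2e-41, ...)
```

Here 16 of the 100 reads support the mosaic allele, f̂ = 0.176, and the
likelihood-ratio statistic 187.0 gives p ≈ 10⁻⁴¹.

Calling from a VCF and filtering:

```sh
mosaicstr call --vcf sample.vcf.gz --stutter model.tsv --out calls.tsv
mosaicstr filter --in calls.tsv --out calls.filtered.tsv --bed hard_to_map.bed
```

Other subcommands: `fit-stutter` (estimate u, d, ρ per repeat-unit
length from confidently homozygous calls) and `simreads` (stutter-aware
FASTQ simulation around a target STR).

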
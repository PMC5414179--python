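# allelics

Analysis toolkit for the computational arc of characterising an
allele-specific regulatory GWAS variant — from statistical fine-mapping of a
multi-SNP risk region, through proteomic identification of
allele-preferential DNA-binding proteins, to the allele-resolved qPCR
arithmetic used in functional follow-up (allelic expression, knockdown,
ChIP, reporter assays and telomere length).

It is written for statistical geneticists and functional-genomics analysts
who need these steps as tested, reusable, scriptable components, together
with synthetic-data generators that provide ground truth for every stage.

## What it computes

**Fine-mapping** (`allelics.finemap`). Case-control association uses the
1-df score test of a log-additive genotype effect: with a logistic null fit
of covariates only (fitted probabilities p̂, weights W = diag(p̂(1−p̂))),

    U = gᵀ(y − p̂),   V = gᵀWg − gᵀWX (XᵀWX)⁻¹ XᵀWg,   U²/V ~ χ²₁.

Conditional analysis appends chosen variants' dosages to the covariates and
re-tests every other variant, exposing both *signal collapse* (proxies of a
single causal variant losing significance) and *masking* (a variant null in
single-SNP analysis becoming significant after conditioning on a correlated
second signal). Variant QC removes MAF < 0.01 and imputation INFO < 0.5.
LD is computed from two-locus haplotype frequencies (counted when phased,
EM-estimated otherwise): D = p_AB − p_A p_B, r² = D²/(p_A q_A p_B q_B),
D′ = |D|/D_max.

**Binder calling** (`allelics.binders`). For paired forward/reverse
label-swap DNA-pulldown runs, per-protein allele-oriented log₂(C/G) ratios
are median-centred and flagged beyond the Tukey fences Q1 − 1.5·IQR /
Q3 + 1.5·IQR; a protein is called C-preferential only when it is an upper
outlier in **both** runs (lower in both for G), so single-run channel
artefacts cancel.

**qPCR arithmetic** (`allelics.qpcr`, `allelics.telomere`). ΔΔCt relative
expression (fold = 2^−ΔΔCt), allelic-discrimination ratios
2^−(Ct_C − Ct_G) with genomic-DNA copy-number adjustment, per-allele
knockdown percentages with paired t-tests, the siRNA-specificity Fisher
exact test, ChIP percent-input enrichment over a nonspecific antibody, dual
luciferase (firefly/renilla) reporter normalisation, and relative telomere
length T/S = 2^−(Ct_T − Ct_S) versus a single-copy gene.

**Synthetic data** (`allelics.simulate`). LD-structured haplotype pools
with exact population-level pairwise r² (tree-factorised, solved in closed
form from D = r·√(p_A q_A p_B q_B)), logistic case-control phenotypes with
retrospective sampling, two-signal masking scenarios, log-normal label-swap
pulldown intensities with planted binders, and Ct tables generated from
latent template amounts.

## Worked example

Simulate a risk region (one causal SNP, OR 1.3, MAF 0.19, three proxies at
r² = 0.7), scan it, then condition on the causal variant:

```python
from allelics import simulate as sim, finemap as fm

ids = ["rs_causal", "rs_proxy1", "rs_proxy2", "rs_proxy3"]
pool = sim.make_haplotype_pool(sim.HaplotypeSpec(
    ids, [0.19, 0.20, 0.22, 0.24],
    [("rs_causal", v, 0.7) for v in ids[1:]], seed=0))
cc = sim.CaseControlSpec({"rs_causal": 1.3}, mode="retrospective",
                         n_cases=2000, n_controls=2000, seed=0)
d = sim.simulate_case_control_study(pool, cc, cohort_multiplier=4)

print(fm.association_scan(d.genotypes, d.phenotype))
print(fm.association_scan(d.genotypes, d.phenotype, condition_on=["rs_causal"]))
```

```
       id     beta       se  score_stat  p_value
rs_causal 0.154990 0.057541    7.269819 0.007012
rs_proxy1 0.115379 0.055906    4.264120 0.038925
rs_proxy2 0.170715 0.054620    9.792381 0.001752
rs_proxy3 0.109167 0.052622    4.307882 0.037936

       id  score_stat  p_value      (conditioned on rs_causal)
rs_causal         NaN      NaN
rs_proxy1    0.126853 0.721717
rs_proxy2    2.553472 0.110052
rs_proxy3    0.042494 0.836682
```

Every variant is associated marginally (the causal SNP's log-OR estimate
0.155 ≈ log 1.17 at this modest sample size), and conditioning on the
causal SNP collapses the proxies' signal (all p > 0.1) — the classic
fingerprint of a single underlying functional variant.

The siRNA-specificity test from published counts (3 of 8 region-targeting
siRNAs inhibiting the target gene versus 0 of 24 pooled control tests):

```python
>>> from allelics.qpcr import sirna_specificity_test
>>> sirna_specificity_test(3, 8, 0, 24)
0.01129032258064516
```

A command-line interface mirrors the library
(`allelics simulate|assoc|ld|binders|qpcr|telomere|run`); see
`allelics --help`.

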
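# hapscan

Fast linear mixed-model association scans for **SNPs, haplotype alleles, and
haplotype blocks** in panels of fully inbred (homozygous) lines, such as maize
or rice diversity panels. Because inbred genotypes *are* haplotypes, blocks
can be built directly from the 0/1 genotype matrix with the Four Gamete Test,
and multi-SNP haplotype alleles can be tested with the same machinery as
single SNPs.

## The model

For a quantitative trait on *n* lines,

```
y = 1·mu + X·beta + a + eps,     a ~ N(0, K·sigma_a^2),   eps ~ N(0, I·sigma_e^2)
```

where `X` is the tested genetic unit — one 0/1 column for a SNP or a
haplotype-allele carrier indicator, or `k-1` indicator columns for a
`k`-allele block (the last allele is dropped for identifiability) — and `K`
is the realized relationship matrix from genome-wide markers. Writing the
polygenic heritability `h2 = sigma_a^2/(sigma_a^2 + sigma_e^2)` and spectrally
decomposing `K = U S U^T` **once**, rotation by `U^T` turns the mixed model
into an independent weighted regression with weights `w_i = h2/(1-h2)·S_i + 1`
(the FaST-LMM transformation). Each unit then costs one weighted
least-squares solve per candidate `h2`, with the profile

```
-2 log L(h2)  ∝  n·log sigma_e^2(h2) + Σ_i log w_i(h2)
```

minimized by a one-dimensional search. Units of any width are tested with the
unified nested-model statistic `F = ((RSS0 − RSS1)/df_beta)/(RSS1/df_eps)`,
`df_eps = n − df_beta − 1`, referred to `F(df_beta, df_eps)`.

Three scan modes trade exactness for speed:

* `exact` — profile `h2` per unit, searching downward from the genomic
  (null-model) heritability;
* `emmax` — fix `h2` at the genomic estimate, one regression per unit;
* `two_pass` (default) — EMMAX screen of all units, then exact re-testing of
  units passing a 5% screen. Total cost stays between one and two genome-wide
  regression scans (`O(imn)` with `1 < i ≤ 2`), which the scan instruments
  and reports.

Haplotype blocks are maximal runs of contiguous markers in which every pair
passes the Four Gamete Test (fewer than four gamete classes at frequency
≥ 1%); haplotype alleles with frequency < 0.02 are pooled into one `_rare`
class per block.

## Worked example

Simulate a 300-line, 1,000-SNP panel with LD blocks, a 40% polygenic
background and one QTL explaining 10% of the phenotypic variance, then scan
SNPs and blocks:

```python
from hapscan import (ScanConfig, SimSpec, build_blocks, compute_rrm,
                     enumerate_all, run_scan, simulate_genotypes,
                     simulate_phenotype, spectral_decompose)

spec = SimSpec(n_samples=300, n_snps=1000, seed=11, h2_poly=0.4,
               qtl=[(250, 0.10)])
G = simulate_genotypes(spec)
y, truth = simulate_phenotype(G, spec)
blocks = enumerate_all(G, build_blocks(G, cutoff=0.01), rare_freq=0.02)
eig = spectral_decompose(compute_rrm(G))
print(f"{len(blocks.blocks)} blocks cover "
      f"{blocks.coverage_pct(G.n_markers):.1f}% of {G.n_markers} SNPs")
for kind in ("snp", "hap_block"):
    res = run_scan(G, y, blocks, ScanConfig(unit_kind=kind, mode="two_pass"), eig)
    top = max(res.results, key=lambda r: r.neg_log10_p)
    print(f"{kind}: {res.n_tests} tests, h2_genomic={res.h2_genomic:.3f}, "
          f"lambda={res.lambda_gc:.3f}, threshold={res.threshold_neg_log10:.3f}")
    print(f"  top hit {top.unit_id}: -log10 p = {top.neg_log10_p:.2f}, "
          f"explains {top.explained_var_pct:.1f}% of variance (df={top.df_beta})")
```

prints

```
235 blocks cover 90.9% of 1000 SNPs
snp: 917 tests, h2_genomic=0.431, lambda=1.043, threshold=4.263
  top hit chr1.s694842: -log10 p = 7.33, explains 7.7% of variance (df=1)
hap_block: 235 tests, h2_genomic=0.431, lambda=0.983, threshold=3.672
  top hit Chr1Block65: -log10 p = 5.64, explains 6.6% of variance (df=2)
```

The top SNP is the planted causal marker (`chr1.s694842`); the block test
flags the block containing it. `h2_genomic` is the null-model heritability
estimate (the planted 0.4 plus the absorbed QTL variance), `lambda` the
genomic-control inflation factor (≈1 means calibrated tests), and the
threshold is the Bonferroni cutoff `-log10(0.05 / n_tests)`. The genomic
control puts every unit, whatever its df, on a common 1-df chi-square scale.

The same scans run from the shell:

```
hapscan simulate --seed 3 -o demo
hapscan blocks --geno demo.geno.tsv --geno-map demo.map.tsv -o demo.blocks.tsv
hapscan scan --geno demo.geno.tsv --geno-map demo.map.tsv \
             --pheno demo.pheno.tsv --trait SIM --units snp \
             --mode two-pass -o demo.scan.tsv
```

Genotypes load from VCF (homozygous or haploid calls only — heterozygous or
missing calls are rejected; impute upstream) or a plain 0/1 tab-separated
table with a 3-column marker map.

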
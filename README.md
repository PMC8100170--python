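# octs — osteocyte transcriptome signature pipeline

Osteocytes are bone-embedded cells that coordinate skeletal remodelling,
yet their transcriptome is hard to measure directly: any bulk bone sample
mixes osteocytes with marrow, blood and muscle. `octs` implements, as a
tested and reusable Python library plus CLI, the computational pipeline
used to distil an *osteocyte transcriptome signature* from bulk RNA-seq
of osteocyte-enriched versus whole-bone samples, and the statistics that
connect that signature to monogenic and polygenic skeletal disease.

The pipeline stages:

1. **Active-expression calling (zFPKM).** Per-sample log2-FPKM
   distributions are bimodal. The active mode is located as the maximum
   of a Gaussian KDE (Scott's bandwidth) of log2(FPKM > 0); a
   half-normal SD is fitted above the mode µ, and each gene is z-scored,
   `zFPKM = (log2 FPKM − µ)/SD`. Genes with zFPKM > −2.6 in **all**
   replicates of a group are *active*, in none *inactive*, otherwise
   *variable*.
2. **Tissue specificity (Tau).** On quantile-normalised per-tissue
   median log2-FPKM, `τ = Σᵢ(1 − x̂ᵢ)/(N_t − 1)` with
   `x̂ᵢ = xᵢ/maxⱼ xⱼ`; τ = 0 means uniform expression, τ = 1 single-tissue,
   binned low (< 0.15) / moderate / high (> 0.85).
3. **Enrichment threshold (Gaussian mixture).** Per-gene log2
   fold-changes between paired osteocyte-enriched and whole-bone samples
   (library-size-normalised counts, per-animal pairing) are fitted with
   a univariate unequal-variance Gaussian mixture: k-means-initialised
   EM, k chosen by BIC. The enrichment threshold is
   `mean₂ + 2·SD₂` of the component with the second-highest mean, and a
   gene is *enriched* when the lower bound of the 95% t-interval of its
   mean LFC exceeds that threshold.
4. **Signature filter.** The signature is the conjunction: active in any
   sample type AND mixture-enriched AND not significantly higher
   (P < 0.05) in blood, bone marrow or skeletal muscle than in bone.
5. **Gene-set statistics.** Over-representation of the signature in
   disease gene sets and among GWAS nearest genes is tested with the
   inclusive upper-tail hypergeometric distribution,
   `P(X ≥ k)` for `(N, K, n, k)` = (population, population successes,
   sample, sample successes), with fold-enrichment `(k/n)/(K/N)` and
   Bonferroni adjustment across groups.

Because the original sequencing data live in external archives, the
package ships seeded generators (`octs.simulate`) that reproduce the
statistical structure each stage assumes — bimodal FPKM distributions,
paired counts with a planted four-component LFC mixture, multi-tissue
panels with planted specific genes, and gene-set universes with planted
over-representation — together with ground-truth labels, so the whole
pipeline is testable end to end.

## Worked example

```python
>>> import octs
>>> counts, samples, truth = octs.simulate_enrichment_experiment(seed=1)
>>> lfc = octs.compute_lfc(octs.libsize_normalize(counts), samples)
>>> model = octs.LfcMixture(seed=1).fit(lfc)
>>> model.k_, round(model.threshold_, 3)
(4, 1.746)
>>> calls = model.predict_table(lfc)
>>> int(calls["enriched"].sum())
507
```

The BIC selects four components (strongly enriched, moderately enriched,
unchanged, marrow-depleted); their fitted means here are 4.59, 1.11,
0.12 and −1.39 LFC. The threshold 1.746 is two SDs above the
second-highest component mean — genes whose 95%-CI lower bound clears it
(507 of 10,000) are called osteocyte-enriched. Against the generator's
truth labels (505 planted) this run attains recall 1.00 and precision
0.996.

The disease-association statistics take the published parameterisations
directly:

```python
>>> res = octs.hypergeom_test(N=15368, K=432, n=1043, k=90)
>>> f"{res.p_raw:.2g}", round(res.fe, 1)
('2.4e-22', 3.1)
```

i.e. of 15,368 expressed ortholog pairs, 432 cause skeletal dysplasia;
finding 90 of them among the 1,043 signature genes is a ~3-fold
enrichment with P ≈ 2.4 × 10⁻²².

Every stage is also a CLI subcommand:

```sh
octs simulate enrichment --seed 1 --out sim/
octs enrich --counts sim/matrix.tsv --samples sim/samples.tsv --seed 1 --out enr/
octs hypergeom --N 15368 --K 432 --n 1043 --k 90
```

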
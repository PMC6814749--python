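# retinet

Single-cell RNA-seq analysis built around multiresolution archetypal cell
networks, for studies of the type that profile a complex tissue (the human
retina being the motivating case) on one or two platforms, annotate cells
against a curated marker panel, dissect heterogeneity within one cell class,
and ask which cell types' expression programs are predictive of genetic risk
for a disease such as age-related macular degeneration.

The pipeline:

1. **QC & normalization** — keep cells detecting ≥ 300 genes and genes
   detected in ≥ 10 cells (iterated to a fixed point), then scale each cell to
   the median depth and log1p.
2. **Batch correction** — mutual-nearest-neighbor (MNN) correction in the
   50-dimensional SVD space.
3. **Archetypal ladder & network** — archetypal analysis `S ≈ S C H`
   (column-stochastic C, H) at depths k = 2…K; concatenated footprints form
   per-cell probability vectors compared with the square root of the base-2
   Jensen–Shannon divergence, `d(p,q) = √JSD(p,q) ∈ [0,1]`, and a k*-adaptive
   nearest-neighbor graph with edge weights `1 − d` links the cells.
4. **Annotation** — marker expression imputed by a restart random walk
   `s = (1−α)(I−αP)⁻¹x`, z-scaled, averaged per type; a frequency-matched
   permutation test assigns significance; cells significant for zero or for
   multiple types (doublet suspects) are filtered, as are cells whose network
   neighborhoods are not enriched for their own label.
5. **Markers** — discriminating-power signatures (per-type metagenes
   back-transformed through the left-singular vectors), one-sided Wilcoxon
   rank-sum selection (adjusted p < 0.001, AUC > 0.5, positive log fold
   change), exclusivity in exactly one type, top-10 ranking, and partial
   Pearson correlation of signatures across platforms controlling for both
   baselines.
6. **Subtypes** — sub-network analysis of one class (e.g. macroglia):
   rod-contamination filtering, re-reduction and re-correction, Leiden
   partitioning of the rebuilt network, subtype markers, and one-sided
   macula/periphery enrichment tests.
7. **GWAS** — per-gene cell-type specificity (−log₁₀ adjusted p, clipped at
   1e-300, significance at 1e-10) and MAGMA-style competitive gene-set
   regression: gene-level Z on set membership plus covariates, one-sided
   positive test, with negative-control traits side by side.

A bundled generator (`retinet.synth`) produces negative-binomial count
matrices with planted exclusive markers, library-size variation, batch and
platform effects, summed-pair doublets, three region-biased macroglia-like
subtypes, and gene-level GWAS statistics with one enriched set — so every
stage is testable end to end without external data.

## Worked example

```
retinet demo --seed 0 --out retinet_demo
```

simulates a 6-type, 1,000-gene, 1,200-cell dataset (5% doublets, 2 batches),
runs QC → MNN → ladder (k = 2…8) → network → annotation → markers → gene-set
regression in a few seconds, and writes TSV artifacts plus a checksum
manifest. The annotation table it produced here:

```
label
amacrine            199
cones               195
rods                187
bipolar             181
horizontal          180
RGC                 173
unassigned_multi     83
unassigned_none       2
```

All six planted types are recovered at close to their planted 200-cell sizes;
the 60 planted doublets plus a margin of ambiguous cells land in
`unassigned_multi`. The gene-set regression output (`gwas_association.tsv`),
where the synthetic trait's association was planted on the RGC marker set:

```
      type      beta        p  neglog10p  significant
       RGC  0.528716 0.019706   1.705397         True
  amacrine -0.059945 0.592266   0.227483        False
   bipolar  0.126185 0.306214   0.513975        False
     cones  0.076559 0.386648   0.412685        False
horizontal -0.151191 0.715306   0.145508        False
      rods -0.324468 0.896801   0.047304        False
```

Only the planted type is significant: its member genes' Z scores exceed the
competitive background by β ≈ 0.53 after adjusting for gene size.

In code, the same machinery is a library:

```python
from retinet import js_distance
js_distance([0.5, 0.5], [1, 0])   # 0.5579230452841438 (√JSD in bits)
```

See `docs/methods.md` for the model, parameter defaults and their rationale,
and what the synthetic benchmarks do and do not demonstrate.

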
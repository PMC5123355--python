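# crrlink

`crrlink` links **candidate regulatory regions** (CRRs) to the transcripts
they control through penalized models of gene expression, and then asks
whether somatic cancer mutations concentrate in the regions the models
select.

It is aimed at regulatory-genomics analysts who have per-cell-type peak
calls (TF ChIP-seq, DNase I hypersensitivity, H3K27ac), normalised DNase
signal tracks, transcript-level RNA-seq quantifications and a
somatic-mutation catalogue, and who want a reduced, expression-backed set of
regulatory elements plus confounder-aware mutation-enrichment statistics.
Everything also runs without any external data: a first-class synthetic-data
generator emulates the whole input stack with known ground truth.

## The model

CRRs are built by merging (≥1 bp overlap) all TF binding sites with the
top-scoring 25% of DNase hypersensitive sites per cell type, the latter
filtered for an H3K27ac mark in at least one cell type. For each transcript
expressed (FPKM ≥ 1) in at least 7 of the 14 cell types, expression is
modelled on the CRRs within 100 kb of its TSS:

```
y = k0 + Σᵢ kᵢ xᵢ ,   y = log(FPKM + 1),  xᵢ = log(signalᵢ + 1)
```

Because the candidates (~42 per transcript) outnumber the 14 cell types, the
fit is L1-penalized (LASSO, objective `(1/2n)‖y − Xk‖² + λ‖k‖₁`) and λ is
chosen so that exactly **two** coefficients survive. Model quality is the
Pearson correlation *r* between observed expression and leave-one-cell-type-out
predictions at the chosen λ; significance comes from an empirical null of
*r* values obtained by permuting expression across cell types (pooled over a
small stratified sample of transcripts, Benjamini–Hochberg adjusted).

CRRs with a non-zero coefficient in ≥1 built model form the **chosen** set;
candidates never selected form the **rejected** set. Deduplicated mutation
counts per CRR are then compared between the sets with proportion tests
(χ², one-sided Fisher), mean tests (Welch *t*, Wilcoxon rank-sum),
confounder-matched resampling (4 equal-count bins on replication timing,
GC, length or TSS distance) and a log-link count GLM with a quasi-Poisson
dispersion fallback, whose chosen/rejected indicator is the headline effect.

## Worked example

```python
import crrlink as cl

result = cl.run_synthetic_analysis(
    cl.SimulationConfig(seed=2, n_transcripts=200), n_perm=100
)
overall = result.reports["all"]
print(f"built models : {sum(m.status == 'built' for m in result.models)}")
print(f"chosen CRRs  : {overall.n_chosen}   rejected: {overall.n_rejected}")
print(f"mean mutations/CRR: {overall.mean_count_chosen:.2f} vs "
      f"{overall.mean_count_rejected:.2f} (factor {overall.enrichment_factor:.2f})")
print(f"t-test p = {overall.t_p:.2e}; GLM chosen effect = "
      f"{result.glm.params['chosen']:.2f} ± {result.glm.bse['chosen']:.2f}")
```

prints (seed 2):

```
built models : 200
chosen CRRs  : 396   rejected: 8015
mean mutations/CRR: 1.62 vs 1.04 (factor 1.57)
t-test p = 1.82e-14; GLM chosen effect = 0.42 ± 0.04
```

The 200 transcripts yield 396 chosen CRRs (~2 per transcript). The planted
functional CRRs carry a 0.46 log-rate mutation boost, and the pipeline
recovers it: chosen CRRs hold ~1.5× more mutations per region, the effect
survives in the count GLM after length, GC, replication-timing and
TSS-distance adjustment.

The same pipeline is available from the shell:

```bash
crrlink simulate --seed 2 --n-transcripts 200 --out-dir sim/
crrlink build-crrs --dhs CT01:sim/dhs_CT01.bed ... --signal CT01:sim/signal_CT01.bedgraph ... \
    --fasta sim/genome.fa --replication-timing sim/replication_timing.bedgraph --out crrs.tsv
crrlink significance --crr-table crrs.tsv --annotation sim/annotation.tsv \
    --expression sim/expression.tsv --n-perm 1000 --seed 0 --out models.tsv
crrlink map-mutations --mutations sim/mutations.tsv --crr-table crrs.tsv \
    --models models.tsv --annotation sim/annotation.tsv --out stats.tsv
crrlink enrich --crr-mutation-stats stats.tsv --models models.tsv --out report.json
```

## Layout

| module | role |
| --- | --- |
| `crrlink.genomic_core` | intervals, BED/bedGraph/FASTA/TSV readers, merge and overlap arithmetic |
| `crrlink.crr_builder` | DHS ranking, H3K27ac filter, peak merging, signal/covariate attachment |
| `crrlink.expression_models` | design matrices, LASSO path, λ selection, LOOCV, chosen/rejected partition |
| `crrlink.significance` | permutation nulls, pooled empirical p-values, BH adjustment |
| `crrlink.mutation_map` | mutation deduplication, per-CRR counts, proximity annotation |
| `crrlink.enrichment` | group tests, matched resampling, quasi-Poisson count GLM |
| `crrlink.synthetic_data` | ground-truth landscape/expression/mutation generator |
| `crrlink.workflow`, `crrlink.cli` | end-to-end driver and `crrlink` command |
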
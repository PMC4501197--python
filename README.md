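# diffenh

Semi-supervised prediction of transcriptional enhancers that are
**differentially active between two cell conditions**, from the relative
enrichment of chromatin ChIP-seq signals — with downstream linking of
enhancers to genes and association with alternative-TSS usage and
exon-skipping (PSI) changes.

## Who this is for

Regulatory genomics groups comparing two conditions (two cell lines, treated
vs. untreated, tumor vs. normal) with a panel of histone-mark / factor
ChIP-seq experiments plus Input and non-specific-antibody controls, who want
condition-specific enhancer calls rather than static enhancer catalogs:
the method only detects elements whose activity *changes* between the
conditions.

## The method

1. **Windows.** The genome is tiled with 1500-bp windows every 500 bp.
   Intergenic windows avoid gene bodies and any TSS by ≥ 500 bp; intragenic
   windows start 500 bp downstream of a gene's first TSS and skip ±1 kb
   around internal alternative TSSs.
2. **Relative enrichment.** Per-window read counts are GC-corrected within
   each sample (full-quantile normalization across equal-occupancy GC
   strata) and full-quantile normalized between samples. For each dataset
   the two conditions are compared on the MA scale,
   M = log2((a+c)/(b+c)), A = ½·log2((a+c)(b+c)), and standardized against
   the replicate-vs-replicate null in equal-occupancy A bins:

       z = (M − μ_bin(A)) / σ_bin(A)

   Positive z means enrichment in condition A. Datasets without replicates
   get pseudo-replicates by binomially splitting pooled counts.
3. **Feature selection.** A shadow-feature wrapper (Boruta-style: permuted
   copies of every attribute as an importance null inside a forest
   regressor, accept/reject by a binomial test on shadow-beating hits at
   α = 0.01) scores attributes against two correlation classes (H3K27ac −
   Input and H3K4me3 − Input), 10 runs on random 5000-window subsets each.
   Attributes accepted consistently and scoring above the Control and
   H4K20me1 negative controls become predictors. The activation-mark preset
   {P300, H3K27ac, H3K9ac, H3K4me1, H3K4me2, H3K4me3, H2A.Z} ships as a
   default.
4. **Mixture classification.** A Gaussian mixture is fitted to a seed of
   15,000 intergenic windows over the selected attribute z-scores; the
   number of components is chosen by BIC (peaks at K = 3: active, silent,
   no-change). The fitted model classifies all windows; predictions with
   posterior > 0.95 are kept, overlapping same-class windows merge into
   enhancer calls, and calls longer than 5 kb are dropped.
5. **Downstream.** Calls link to genes by nearest TSS (2–100 kb band) or by
   ≥ 3 ChIA-PET pairs joining the call to a TSS ± 1 kb zone; consecutive-TSS
   pairs > 20 kb apart define alternative-transcription events with the
   enhancers between them; exon-skipping events are quantified from
   junction reads only, PSI = (n12+n23)/(n12+n23+2·n13) with a ≥ 20-read
   filter, and events are *regulated* (|ΔPSI| > 0.1 in ≥ 1 replicate
   pairing) or *unchanged* (|ΔPSI| < 0.05 in all pairings).

A first-class synthetic-data module (`diffenh.simulate`) generates a genome
with a GC gradient, a multi-TSS/cassette-exon annotation, negative-binomial
ChIP counts with planted enhancer effects, ChIA-PET pairs and junction
counts — with an exported truth table, so the whole pipeline is testable
without downloads.

## Worked example

```python
import numpy as np
from pyfaidx import Fasta
from diffenh import annotation, signal, simulate, windows, pipeline

# synthetic two-condition study: 2 x 10 Mb, 100 genes, 200 active + 200
# silent enhancers planted at an expected enrichment z of +/-3
fasta, gtf, truth = simulate.make_genome_and_annotation(seed=1, out_dir="sim")
ann = annotation.load_annotation(gtf, {"chr1": 10_000_000, "chr2": 10_000_000})
ws = windows.generate_intergenic_windows(ann)
gc, _ = signal.compute_gc(Fasta(str(fasta)), ws)
cm = simulate.plant_chip_counts(truth, ws, gc, seed=2)
z, _ = signal.build_enrichment_matrix(cm, "A", "B", seed=3)

res = pipeline.predict_enhancers(z[list(truth.selected_marks)], ws, seed=4)
print("selected K =", res.k)
print("calls:", len(res.calls))
print(pipeline.reciprocal_overlap_stats(res.calls, truth.enhancers))
```

prints

```
selected K = 3
calls: 400
{'precision': 1.0, 'recall': 1.0, 'n_calls': 400, 'n_truth': 400,
 'matched_calls': 400, 'matched_truth': 400}
```

i.e. the BIC-selected three-class mixture recovers every planted enhancer
interval (at ≥ 50 % reciprocal overlap, class-matched) with no false
positives on this simulation.

The same steps are available from the shell:

```bash
diffenh simulate --seed 1 --out sim/
diffenh windows --gtf sim/annotation.gtf --chrom-sizes sim/chrom.sizes \
    --mode intergenic --out windows.bed
diffenh enrich --counts sim/counts.tsv --samples sim/samples.tsv --out z.tsv
diffenh fit --z z.tsv --out model.json
diffenh classify --z z.tsv --model model.json --windows sim/windows.bed \
    --out classes.tsv --calls-out calls.bed
```

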
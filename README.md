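# deepsata

Chromatin-accessibility sequence modelling with explicit transcription
factor (TF) binding-affinity input layers, for regulatory genomics at the
200 bp bin level: dataset preparation from a genome FASTA and ATAC-seq peak
BEDs, motif scanning with exactly calibrated p-values, a convolutional
multi-task classifier, in-silico mutagenesis of SNPs, cross-species
evaluation, GWAS-trait enrichment of regulatory variants, and a seeded
synthetic-study generator so the whole pipeline is testable without any
external download.

## The model

The genome is cut into 200 bp bins; a bin is open for a chromatin feature
(a tissue/cell-type ATAC-seq track) when more than half of it lies in that
feature's peaks.  Each open chromatin bin (OCB) is represented by its
1000 bp window as a **1000 × 4 × (N+1)** tensor: plane 1 one-hot DNA
(channel order A, T, C, G), planes 2..N+1 the binding configuration of the
N motifs most present in the training windows — each predicted binding
site is filled with the motif's position probability matrix rows, zeros
elsewhere.  A three-layer CNN (kernels 320/480/960 at published scale;
first pool 4 × (N+1) collapses the plane axis) ends in one sigmoid per
feature.  Setting N = 0 recovers a one-hot-only baseline; a flattened
1000 × (4+N) ablation encoding is also provided.

For a SNP, the two alleles of the 1000 bp window centered on it are
encoded (motif sites re-scanned per allele) and scored; alleles on opposite
sides of the per-feature Youden-optimal open/closed threshold mark the SNP
as regulatory.  Regulatory SNPs near GWAS signals are assigned to the
nearest TSS within 1 Mb and tested per trait with a hypergeometric tail
and Benjamini–Hochberg FDR.

See `docs/methods.md` for the full model description, numerical choices
and the synthetic-study design.

## Worked example

```python
import numpy as np
from deepsata import (SimConfig, simulate_study, MotifScanner,
                      prepare_dataset, DeepSATA, ModelConfig)
from deepsata.pipeline import scan_genome, rank_dataset_tfs, encode_dataset

study = simulate_study(SimConfig(seed=1))          # genome + peaks + truth
scanner = MotifScanner(study.motifs)
hits = scan_genome(scanner, study.genome)
ds, split = prepare_dataset(study.genome, study.peaks)
tf_order = rank_dataset_tfs(split.train, hits, study.motifs, n=6).tf_order

X = {p: encode_dataset(getattr(split, p), hits, tf_order, study.motif_map)
     for p in ("train", "validation", "test")}
cfg = ModelConfig.small(n_features=len(ds.features), n_tf_layers=len(tf_order))
fit = DeepSATA(X["train"], split.train.labels,
               X["validation"], split.validation.labels,
               cfg, ds.features, tf_order).fit(seed=100)
print(fit.summary())
```

prints (abridged):

```
DeepSATA fit summary
====================
mode:               3d (6 TF layers)
conv filters:       (32, 48, 64), widths (8, 8, 8)
hidden units:       128
learning rate:      0.1 (momentum 0.9)
epochs run:         52 (best epoch 43)
best val mean AUC:  0.9886
features:           tissue1, tissue2, tissue3
TF layer order:     M10, M09, M05, M04, M02, M11
```

i.e. on the synthetic benchmark — ~1800 open chromatin bins across seven
chromosomes, three tissues each driven by one planted motif — the model
separates open from closed bins nearly perfectly on held-out chromosomes
(mean test AUC 0.988); the one-hot baseline trained identically lands at
0.970, the gap the TF-affinity planes contribute.

The same pipeline is available from the shell:

```
deepsata simulate --outdir study --seed 1
deepsata prepare  --fasta study/genome.fa --peaks tissue1=study/peaks_tissue1.bed ... --out ds.npz
deepsata train    --dataset ds.npz --fasta study/genome.fa --motifs study/motifs.meme --out model.npz
deepsata evaluate --checkpoint model.npz --dataset ds.npz --fasta study/genome.fa \
                  --motifs study/motifs.meme --out aucs.tsv
deepsata score-variants --checkpoint model.npz --fasta study/genome.fa \
                  --vcf study/variants.vcf --motifs study/motifs.meme --out effects.tsv
```

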
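# Methods

## Model

`deepsata` predicts per-tissue chromatin accessibility of 200 bp genomic
bins from the surrounding 1000 bp of sequence.  Its input extends the usual
one-hot DNA encoding to a 1000 × 4 × (N+1) tensor: plane 1 is the one-hot
sequence with channel order A, T, C, G ([1,0,0,0]=A, [0,1,0,0]=T,
[0,0,1,0]=C, [0,0,0,1]=G; N and window padding are all-zero rows), and each
of the N further planes carries one transcription factor's binding
configuration — at every predicted binding site of that TF's motif the
plane holds the motif's position-probability rows (reverse-strand sites are
written with the reverse-complemented PPM so rows always describe
forward-strand base probabilities), and zeros elsewhere.  Overlapping sites
of the same motif combine by element-wise maximum, which is bounded and
order-independent.

The network is a three-layer CNN.  The first convolution (320 kernels at
published scale, width 8) slides along the sequence with a receptive field
spanning the 4 nucleotide channels and shares one filter bank across all
N+1 planes; the first max-pool then takes the maximum over windows of 4
sequence positions × all N+1 planes, collapsing the plane axis — the
network aggregates, for each filter, its strongest response across the
sequence and every TF affinity plane.  Two further convolutions (480, 960
kernels) run along the sequence only, each followed by the activation,
stride-4 max-pooling and dropout (0.2, 0.2, 0.5).  A fully connected layer
feeds one sigmoid output per chromatin feature; the loss is mean binary
cross-entropy across features.  Per-plane first-layer filter banks are
available behind `ModelConfig.per_plane_filters` but shared filters are the
default: sharing is what makes the plane-collapsing pool meaningful.

The activation is a thresholded ReLU: pre-activations ≤ 0 are replaced by a
floor of 1e-6 rather than 0.  Two purely numerical choices depart from a
textbook ReLU backward pass, both motivated by optimization failures we
observed at small sample sizes (hundreds to ~1000 training bins): the
sub-threshold derivative is taken as 0.1 rather than 0 (a leak; with an
exact zero the plane-collapsing max-pool lets entire layers die
irreversibly within the first epochs), and gradients are clipped to a
global norm of 1.0 (convolution-weight gradients aggregate over ~10^3
positions and otherwise dominate the first updates).  The output bias is
initialized to the per-feature log-odds of the training base rates.
Forward semantics are unchanged by all three.

## Motif scanning

Motifs are read from MEME minimal format (A,C,G,T column order, re-ordered
to the internal A,T,C,G at parse time; missing background = uniform).
Scanning scores every window on both strands with the log-odds (base 2) of
the pseudocounted PPM (pseudocount 1e-4, applied before log-odds to avoid
−∞) against an iid background.  Exact p-values come from the classic
dynamic-programming calibration: per-position scores are discretized to
1000 integer levels and the null distribution of the total is the
convolution of the per-position distributions; a window is a hit when
P(score ≥ observed) ≤ 1e-4, the scanning default.  N scores as the level
nearest 0 bits (the background expectation), so N-padded windows never
produce spurious hits.  All overlapping hits are reported; the encoder
resolves overlaps.  TFs are ranked by total hit count over the training
bins' windows (ties broken lexicographically by motif id; an alternative
bins-with-a-hit mode is available) and the top N = 10 by default feed the
encoder.  Desk-scale runs in this repository use N = 6, which keeps every
planted driver motif in the layer set at a third of the compute.

## Dataset preparation

The genome is cut into consecutive 200 bp bins from position 0 (a trailing
remainder is dropped).  A bin is open (label 1) for a feature when strictly
more than 100 bp of it falls inside the feature's merged peaks.  Only open
chromatin bins — open in at least one feature — are retained; their zeros
elsewhere are the negatives (a flag can add genome-wide closed bins).  Each
bin carries its 1000 bp window (bin ± 400 bp, N-padded at chromosome ends).
Chromosome 1 is the validation set, chromosomes 2 and 3 the test set, the
rest training.  The 10-set subsampling of the published pipeline is
implemented as a seeded shuffle dealt round-robin into k sets.

## Variant scoring

A SNP's two alleles are scored on the 1000 bp window covering 500 bp on
either side (SNP at offset 500, coordinates clipped to the chromosome with
N padding).  Motif hits are re-scanned separately per allele — a
substitution can create or destroy a binding site, and that is exactly the
signal the TF planes must carry.  The open/closed probability threshold per
feature maximizes Youden's J (sensitivity + specificity − 1) over midpoints
between consecutive distinct scores on the held-out test split's
predictions (ties take the smaller threshold).  A SNP is regulatory for a
feature when its alleles fall on opposite sides of that threshold; panels
are exported top-k by |Δ probability| with ties broken by genomic position.

## Enrichment

Regulatory SNPs are intersected with 2 Mb windows centered on GWAS signal
midpoints (inclusive bounds), assigned to the nearest transcription start
site within 1 Mb (strand-aware TSS; distance ties to the smaller
coordinate), and the linked gene set is tested per trait with the
hypergeometric tail P(X ≥ k) against all genes in the windows, with
Benjamini–Hochberg FDR across traits.

## Synthetic study

The generator emulates a study in which accessibility is driven by the
local density of tissue-specific TF binding sites observed through a noisy
peak caller.  Defaults (one draw per value; all draws from a single seeded
generator, so outputs are byte-identical per seed):

- genome: 7 chromosomes × 250 kb, iid background at GC 0.41.  Seven
  chromosomes rather than two give the fixed chromosome-based split (chr1
  validation, chr2–3 test) a non-empty multi-chromosome training remainder
  of realistic size (~1000 open bins).
- motif library: 12 PWMs of length 10–12 with a heterogeneous information
  profile — four near-deterministic core positions (consensus probability
  0.93–0.99) among weak ones (0.60–0.80), the shape typical of curated TF
  motifs.  The profile matters for in-silico mutagenesis: substituting the
  most informative core base costs more log-odds than any pair of
  weak-position changes, so a single SNP there pushes the site below the
  p ≤ 1e-4 scanning threshold and the TF planes actually change; uniformly
  sharp long motifs would keep one-base-substituted sites significant and
  leave nothing for variant scoring to detect.
- three tissues, one driver motif per tissue (disjoint via a permutation
  when the library allows).  One driver rather than several reflects what
  the published architecture can learn from ~10^3 training bins; with an
  OR-of-four-motifs rule the one-hot baseline stays near chance at this
  sample size regardless of optimizer, which would make the benchmark
  unable to separate the encoders.  Motifs not assigned to a tissue are
  planted decoys.
- planted sites: 4 instances/kb across the whole library, spaced ≥
  motif-length + 10 bp apart, strand random, realized as the consensus so
  the calibrated scanner recovers every registered site.
- peaks: per tissue, the top 20% of bins by driver-instance count (bins
  with zero driver instances never become peaks by score); 0.5% of bin
  memberships are then flipped in both directions (peak-caller noise) and
  runs of peak bins are merged into intervals.
- variant panel: 500 SNPs, half motif-ablating (most-informative position
  of a planted driver site, substituted with the PPM's least probable
  base, strand-aware) and half neutral (≥ 50 bp from every planted site).
- a second species shares the motif library and tissue-driver assignment
  on an independent background genome (the conserved-TF premise); passing
  no shared study draws a fresh library, removing all transferable signal.

What passing the synthetic benchmark does and does not show: it
demonstrates that the encoder, network, training loop, variant scorer and
transfer harness implement the intended mechanics on data whose regulatory
rule is known exactly.  It does not demonstrate performance on real
chromatin, which has repeats, GC structure, cooperative and degenerate
binding, and far weaker label determinism.

## Desk-scale training configuration

`ModelConfig.small()` — used by the benchmark and acceptance runs — scales
the published architecture to a single CPU: kernels (32, 48, 64), hidden
128, dropout (0.1, 0.1, 0.2), SGD with momentum 0.9, weight decay 1e-6,
learning rate 0.1, batch 16, up to 60 epochs with early stopping (patience
8, never before epoch 45 — depending on the seed the optimizer can sit in
a flat region of the loss for the first 20+ epochs before the motif
detectors form), checkpoint selection by best validation mean AUC.  The published
learning rates (1.0; 0.5 for the pig datasets) are kept as presets in
`LEARNING_RATE_PRESETS`.  Kernel widths are 8 throughout and the published
hidden size is 925; both are configurable.

## Known limitations

- Training is implemented in numpy; it is exact but single-threaded, so
  published-scale filter counts on millions of bins are out of reach.
- The scanner's p-values are discretized (1000 levels); hit decisions at
  the threshold can differ from an infinitely fine calibration by the
  documented discretization tolerance.
- The iid-background generator cannot probe robustness to repeats or
  compositional heterogeneity.
- Multi-allelic sites are skipped, not split; indels are out of scope.
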
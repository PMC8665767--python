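# nasdeconv

Deconvolution of pre-RNA isoform abundances from nascent RNA-sequencing
coverage.

## The problem

Nascent RNA-sequencing protocols (PRO-seq, GRO-seq) sequence RNA still
engaged with polymerase, measuring primary transcription across the full
transcription unit, introns included. The signal at a locus is therefore a
mixture of unspliced **pre-RNA isoforms** — transcription units defined by a
(TSS, PAS) pair — which overlap heavily and differ far less than mature
splice isoforms do. Most analyses either ignore the mixture or assume one
isoform per gene; both choices bias downstream estimates of gene abundance,
dominant-isoform identity, elongation rates and RNA half-lives.

`nasdeconv` models the observed strand-specific read counts as a
non-negative mixture of candidate isoforms. For a cluster of *n*
overlapping same-strand isoforms spanning *m* genomic bins (default 250 bp),
with bin counts **Y** and an *m* × *n* design matrix **X** (x&#8342;&#8345; = 1
where isoform *j* spans unmasked bin *i*), it solves

> &beta;&#770; = argmin&#8320; ‖Y − X&beta;‖² subject to &beta; ≥ 0,

exactly by active-set NNLS, or in log space
(&sum;(log(y&#7522;+1) − log((X&beta;)&#7522;+1))², bounded L-BFGS-B)
under a log-normal noise assumption. Three optional refinements sharpen the
baseline:

- **Masking** of bins at each isoform's 5′ and 3′ ends (defaults 1 and 4),
  excluding the promoter-proximal pause peak and termination deceleration.
- **Active-TSS calling**: a small classifier (1-D convolution → ReLU →
  max-pool → dropout → dense → sigmoid, or a logistic baseline) scores each
  candidate TSS from 42 z-scored features — strand-specific counts in
  21 × 51-bp bins centred on the TSS — exploiting the bidirectional
  transcription signature of active promoters. Only isoforms with an active
  TSS may take non-zero weight; isoforms with an upstream polymerase ratio
  (UPR) ≥ 5 and no active neighbour within 5 kb upstream / 6 kb downstream
  are rescued.
- **Shape-profile correction**: the typical 'U'-shaped read density along a
  transcription unit is fitted from long, isolated, well-expressed reference
  isoforms on a canonical [0, 1] axis (first 3 kb → [0, 0.2], last 3 kb →
  [0.8, 1]), loess-smoothed, median-scaled to 1, and substituted for the
  1-entries of **X**.

Estimates are depth-normalised (per million), summed to gene level, and the
most abundant isoform per gene is flagged as dominant.

The package also ships a non-parametric **simulator** (archetype
resampling with known truth), a read-count baseline (**RCB**,
q = r·10⁶/(f·T) with T = &sum; r&#8342;/f&#8342;), a benchmarking harness with a
72-scheme option grid, and a **Shannon-entropy decomposition** of isoform
diversity into transcriptional H(X) and post-transcriptional
H(Y|X) = H(Y) − H(X) components.

## Worked example

Simulate a 1500-gene dataset, train the TSS classifier on an independent
simulation, and compare the deconvolution and the read-count baseline
against the known truth:

```python
from nasdeconv import ConvTSSModel, generate_archetypes, simulate
from nasdeconv.benchmark import DEFAULT_SCHEME, run_benchmark
from nasdeconv.simulate import make_tss_training_set

archetypes = generate_archetypes(62, seed=1)

train = simulate(archetypes, n_genes=300, seed=101)
feats, labels, _ = make_tss_training_set(train, seed=102)
model = ConvTSSModel(seed=1).fit(feats, labels)

dataset = simulate(archetypes, n_genes=1500, seed=1)
res = run_benchmark(dataset, tss_model=model, scheme=DEFAULT_SCHEME)
for key in ("gene_deconv", "gene_rcb", "dominant_deconv", "dominant_rcb"):
    ev = res[key]
    print(f"{key:16s} r = {ev['r']:.3f}   RMSE = {ev['rmse']:8.1f}   n = {ev['n']}")
```

prints

```
gene_deconv      r = 0.980   RMSE =    197.5   n = 1500
gene_rcb         r = 0.818   RMSE =    578.4   n = 1500
dominant_deconv  r = 0.963   RMSE =    240.8   n = 1500
dominant_rcb     r = 0.935   RMSE =    690.6   n = 1500
```

The deconvolution tracks true gene abundances closely (r = 0.98) while the
read-count baseline, which divides reads by the full union length of each
gene's isoforms, under-normalises genes driven by internal TSSs and lands at
r = 0.82 with nearly 3× the error. Per-gene output
(`res["tables"]["iso"]`) shows the deconvolution at work — here a
three-isoform gene where two overlapping isoforms receive weight in
proportion to their true abundances and the third is zeroed by the TSS
filter:

```
pre_rna_isoform_id  length     raw_beta  true_abundance
      SG00000:1-82   21562 18692.489131       81.168277
    SG00000:11-104   24679 39643.091038      161.810685
     SG00000:29-35    2715     0.000000       11.429655
```

`raw_beta` is in counts-per-bin units (≈ true per-base density × 250 bp
bin size), so the estimated 0.47 abundance ratio between the first two
isoforms matches the true 0.50.

## Command line

```bash
nasdeconv simulate  --n-genes 1500 --seed 1 --out-dir sim/      # GTF + bedGraph + truth
nasdeconv tss       --n-genes 500 --seed 1 --out model.npz      # train TSS classifier
nasdeconv quantify  --gtf sim/annotations.gtf \
                    --bg-plus sim/coverage_plus.bedgraph \
                    --bg-minus sim/coverage_minus.bedgraph \
                    --tss-model model.npz --out isoforms.tsv --gene-out genes.tsv
nasdeconv shape     --gtf ... --bg-plus ... --bg-minus ... --out profile.tsv
nasdeconv benchmark --n-genes 1500 --seed 1 --out bench.tsv     # add --grid for all 72 schemes
nasdeconv entropy   --pre pre.tsv --mature mature.tsv --map map.tsv --boot 100
```

bigWig coverage is accepted via `--bw-plus/--bw-minus`; minus-strand files
that store counts as negative values are absolute-valued on read.

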
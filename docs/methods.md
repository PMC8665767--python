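# Methods

## Model

Each strand-specific cluster of overlapping isoform annotations is tiled
with fixed-width bins (default 250 bp) anchored at the cluster's 5′-most
coordinate and ordered 5′→3′ along transcription. Observed sense-strand bin
counts Y are modelled as a non-negative linear mixture of isoform occupancy
columns, Y ≈ Xβ with β ≥ 0. The least-squares objective corresponds to
maximum likelihood under i.i.d. Gaussian noise per bin; the optional
log-space objective, Σ(log(yᵢ+c) − log((Xβ)ᵢ+c))² with pseudocount c = 1,
corresponds to a log-normal noise assumption and is markedly more robust to
the heavy-tailed spikes typical of nascent RNA-seq coverage. Bins spanned by
no isoform after masking are dropped from the objective rather than
zero-filled, so they contribute no residual.

Mature isoforms are reduced to distinguishable pre-RNA isoforms by merging
all transcripts of a gene whose post-mask start and end bins coincide;
nascent data cannot resolve TSS/PAS differences finer than a bin. Merging is
keyed per gene: two genes overlapping on the same strand share a cluster but
never share a pre-RNA isoform, so gene-level aggregation stays exact.

## Optimisation

Linear mode is solved exactly by active-set NNLS (`scipy.optimize.nnls`).
Log mode uses L-BFGS-B with a zero lower bound and an analytic gradient.
Two numerical choices matter:

- **Start point.** The log-mode optimizer starts from the exact linear NNLS
  solution. A per-isoform-mean heuristic (mean of Y over the isoform's bins
  divided by its column's mean weight) was evaluated first but counts every
  overlapping isoform's reads toward every isoform, so in collinear clusters
  it starts at a gross over-assignment; combined with loose tolerances this
  produced visibly unconverged fits. The linear solution is well-scaled and
  usually within a few iterations of the log-space optimum. The heuristic
  start is retained for the linear-mode L-BFGS-B route, which exists as an
  independent cross-check against the NNLS solution (the two routes agree to
  1e-6 on identifiable designs; with linearly dependent columns the optimum
  is not unique and the comparison is not well-posed).
- **Tolerances.** ftol = 1e-14, gtol = 1e-10, max 1000 iterations. With
  counts in the 10⁵–10⁶ range per bin the log objective decreases by tiny
  absolute amounts per iteration and scipy's default relative tolerance
  (factr = 1e7) declares convergence after a single step.

Estimates are normalised by total library depth (β·10⁶/depth). Gene
abundance is the sum over member isoforms; the dominant isoform is the
argmax of β, ties broken by longer isoform then lexicographic id.

## Active-TSS calling

Features: strand-specific read counts in 21 contiguous 51-bp bins (1071 bp)
centred on the candidate TSS, sense then antisense, ordered 5′→3′ along
transcription, jointly z-scored. A constant window yields an all-zero vector
and an automatic "inactive" call, avoiding NaNs. Two classifier backends
satisfy the 42 → [0,1] contract: a logistic-regression baseline
(scikit-learn) and the default small convolutional network (16 filters,
kernel 5, max-pool 2, dropout 0.3, Adam, early stopping on validation
loss), implemented directly in numpy with manual backpropagation — the
network has a few thousand parameters and trains in seconds. The decision
threshold is 0.5, boundary inclusive. Both backends reach ≥ 0.9 held-out
accuracy on simulator-generated labels (active = archetype TSS with
bidirectional pause peak; inactive = gene-body/intergenic background).

Classifier misses are reconsidered via the upstream polymerase ratio:
sense-strand read density over [+0.5 kb, +2 kb) from the TSS divided by
density over [−3 kb, −0.5 kb). Zero denominators map to +∞ when the inside
density is positive and 0 otherwise. An isoform with UPR ≥ 5 and no active
same-strand isoform TSS within 5 kb upstream / 6 kb downstream is rescued.
Windows use sense-strand counts and TSS-to-TSS distances; both are
configurable, since the convention is a genuine design choice. A
user-supplied inactive list always overrides classifier output.

## Shape profile

References are single-isoform clusters at least 10 kb long, at least 5 kb
from any neighbouring cluster on either strand, with mean unmasked-bin
density in the top expression quartile among candidates (all three
thresholds are config keys; they are concrete stand-ins for informally
defined selection heuristics). Each reference's unmasked bin densities are
divided by their own mean — a scale-free normaliser — and placed at the
canonical positions of their bin midpoints: offsets below 3 kb map
proportionally to [0, 0.2], the last 3 kb to [0.8, 1], the remainder to
(0.2, 0.8); isoforms of length l ≤ 6 kb map their first 0.75 l to [0, 0.2]
and last 0.25 l to [0.8, 1], skipping the body segment. Pooled points are
loess-smoothed (span 0.1, statsmodels lowess), evaluated on a 1000-point
grid, rescaled to median 1 and floored at 0.05 to guard against smoothing
artifacts. Fewer than 5 references triggers a flat (all-ones) fallback;
with a flat profile the quantifier's output is bit-identical to running
without the correction, since the adjustment step is skipped entirely.
Fitting uses masked bins only, so pause/termination peaks do not leak into
the profile.

## Simulator

Five steps: (1) template annotations are clustered as in an analysis run;
(2) clusters and inter-cluster gaps are resampled with replacement until
the requested gene count is placed, strands drawn uniformly; (3) each
isoform is replaced by the archetype nearest in genomic length (a warning
fires beyond a 2× mismatch), keeping its TSS position relative to the
cluster start; (4) each isoform draws an abundance from
log-normal(μ = 4, σ = 1.2) on the per-base-density scale — a stand-in for
an empirical isoform-abundance distribution that would require external
expression data; (5) per-base counts are Poisson-resampled from the
archetype's counts scaled by (simulated abundance / archetype native
density), allowing both thinning and amplification, and overlapping
isoforms add. Conservation (track = Σ contributions) holds by construction
and is tested; a fixed seed reproduces byte-identical exports.

Archetypes are themselves synthetic single-isoform templates: log-uniform
lengths (1.5–50 kb), a Gaussian pause peak within the first 500 bp (8–20×
body density), a U-shaped body, a 3′ termination bump, a divergent
antisense peak just upstream of the TSS, and negative-binomial per-base
noise (dispersion 5). The default template (300 genes, fixed internal seed,
regenerated deterministically in code) draws 1–6 isoforms per gene
(probabilities 0.40/0.25/0.15/0.10/0.06/0.04); each non-first isoform takes
an internal TSS (1–20 kb downstream) with probability 0.4, otherwise a
start within 900 bp of the gene's 5′ end. With abundances i.i.d. across
isoforms this yields ≈ 15% of genes whose truly dominant isoform uses an
internal TSS ≥ 1 kb downstream — the regime where read-count baselines
over-normalise.

What the simulator does **not** emulate: mappability gaps, PCR duplicates,
autocorrelated polymerase waves, enhancer RNAs away from promoters,
annotation errors, and abundance distributions with a realistic point mass
near zero (every placed isoform is expressed). Benchmarks on these data
therefore bound performance under clean conditions; they demonstrate
correctness of the estimator and the qualitative failure modes of
read-count baselines, not field accuracy on any particular library.

## Benchmarking conventions

Truth, deconvolution estimates and RCB estimates are all placed on a
per-million density scale before computing Pearson r and RMSE (r is
unaffected; RMSE and residual signs become comparable across methods).
Isoform-level truths stay on the gene-level normaliser so dominant and
longest selections remain sub-distributions of the gene totals. The
dominant isoform is chosen by true abundance, the longest by annotation;
RCB isoform counts exclude 250 bp after the TSS and 1000 bp before the PAS.
Gene-level RCB uses the union of annotated isoform spans and the
T = Σ r/f normaliser over all genes; isoform-level RCB reuses the
gene-level T so both modes share a scale. The option grid enumerates
{TSS} × {shape} × {log} × {mask5 ∈ 0,1,4} × {mask3 ∈ 0,1,4} = 72 schemes;
the default is (on, on, on, 1, 4). Zero-truth genes would be included in
gene-level evaluation, though the default abundance model produces none.

## Entropy decomposition

Per gene, pre-RNA probabilities p(X=j) ∝ estimated isoform abundance and
mature probabilities p(Y=k) ∝ mature-RNA estimates; H is Shannon entropy in
bits with 0·log 0 := 0. Because each mature isoform maps to exactly one
pre-RNA isoform, H(X,Y) = H(Y), and the chain rule gives the
post-transcriptional component H(Y|X) = H(Y) − H(X). Set-level quantities
are sums over genes (independence assumption), reported also per gene; the
transcriptional fraction is computed from summed entropies
Σ H(X) / Σ H(X,Y) rather than a mean of per-gene ratios, which would be
undefined for single-isoform genes. When the two abundance tables come from
different estimators, H(Y) < H(X) is possible for individual genes; such
negative conditional entropies are reported as-is and flagged. Bootstrap
SDs resample genes with replacement (default 100 replicates, seeded).

## Problem sizes

The standard benchmark uses 1500 simulated genes from 62 archetypes, with a
300-gene independent simulation for classifier training; the full pipeline
completes in well under a minute on one CPU, and the test suite runs the
same configuration. Expanded settings (145 archetypes, 10 000 genes) are
supported by the same code paths.

## Known limitations

- Short isoforms (≲ the mask width) keep a single unmasked central bin and
  are prone to capturing coverage spikes; no sparsity penalty is applied.
- The TSS classifier is trained on synthetic labels; applying it to real
  libraries requires retraining on matched cap-analysis evidence.
- Chromosome-name harmonisation between annotation and coverage files is
  the caller's responsibility; unknown chromosomes warn and count as zero.
- The compatibility map for the entropy analysis must be total; mature
  isoforms without a pre-RNA assignment are an error, not silently dropped.
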
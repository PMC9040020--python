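# Methods

## Accessibility scoring

For each replicate of a DNase-seq experiment we count read 5′ ends per
position (plus-strand reads at `start`, minus-strand at `end − 1`) and
define the accessibility score of position `p` as

    S(p) = N(p) / Ñ(p),   Ñ(p) = M(p) / W,

where `N(p)` is the read-start count at `p` and `M(p)` the count inside a
window of `W` positions centered on `p`. `S` is scale-free (doubling
sequencing depth leaves it unchanged) and equals 1 on a uniform track.

Numerical conventions: `W` is forced odd so the window is symmetric
(default `W = 201`; the window size is a free parameter of the assay-noise
trade-off and is exposed everywhere). At chromosome ends the window is
truncated and `W` in `Ñ` is replaced by the truncated length, keeping `S`
a ratio of rates rather than biasing edge positions downward. Where
`M = 0` we define `S = 0`: a position with no reads anywhere nearby is
maximally closed, and this avoids 0/0. Each replicate is scored
separately because the classifier consumes the replicates as channels.

## Data construction

**Negatives.** Candidate negatives are drawn by rejection sampling from
the background genome — the complement of user-supplied exclusion regions
(enhancers, promoters, exons). Each negative inherits the exact length of
its positive; with GC matching enabled the GC content must agree within
`gc_tol = 0.02`. Negatives are drawn without replacement at the interval
level (no two negatives overlap), and when a window length is supplied the
sampler additionally reserves clearance so that every fixed-length window
later generated around a short negative stays inside the background. A
negative that cannot be placed within `max_attempts = 10 000` draws raises
an error naming the offending positive and its GC content.

**Augmentation.** A region of length `ℓ` becomes fixed-length windows of
`target_len = 300` at a fixed stride: every in-region window when
`ℓ ≥ 300`, every window fully containing the region when `ℓ < 300`
(clipped at chromosome bounds). Without clipping the window count is
`⌊|ℓ − 300| / stride⌋ + 1`. 300 bp brackets the typical enhancer length
(median ≈ 275, mean ≈ 288 in large enhancer catalogues). Both positives
and negatives are augmented identically.

**Folds.** Cross-validation folds are assigned to origin regions *before*
augmentation, stratified by label and balanced within one region per
fold. Every window inherits its origin's fold, so no information leaks
between training and test folds through overlapping windows — the
no-signal control below tests this directly.

## Network

Both feature modules share the same stack (counts for the full
configuration): conv(128 kernels × length 8) → conv(64×1) → conv(64×3) →
conv(128×1) → maxpool → conv(64×3) → conv(64×3) → maxpool, all
convolutions ReLU-activated with same padding and stride 1. The DNA module
takes the one-hot 300×4 window; the DNase module takes the 300×1
auto-encoder embedding of the `k` replicate accessibility channels.
Pooling sizes are a free choice of the geometry; we use pool 2 (stride 2)
so the 300-length input stays divisible through both pooling stages
(300 → 150 → 75).

The auto-encoder is batch-norm → position-shared linear map `k → 1` →
batch-norm → map `1 → k`, trained to minimize mean squared reconstruction
error on the training windows and then frozen as the classifier's input
transform. Its encoder output has length 300 and one channel for any `k`,
which is what makes cross-cell-line transfer possible.

The joint module concatenates skip-connection taps — by default the
flattened outputs of both max-pooling layers of each enabled module — and
passes them through dense layers (512, 256, 128 in the full
configuration; ReLU + dropout 0.5) into a 2-unit softmax. The tap set is
configurable; `merge_taps="pools+gmax1"` additionally feeds a global
per-channel maximum of the first convolutional layer, a position-invariant
readout of the motif detectors (see Motif recovery).

Everything is implemented on a small numpy layer framework with
reverse-mode gradients (`cape.nn`): Conv1D via im2col, max-pooling, dense,
batch-norm, inverted dropout, Adam (with optional decoupled weight decay),
and stabilized softmax cross-entropy. Gradients are verified against
central finite differences in the test suite; training arithmetic is
float32, metrics are float64.

### Training

Stage 1 trains all parameters on every positive training window plus an
equal-count random negative subset (fixed per run, not resampled per
epoch). Stage 2 continues on the full imbalanced training set with all
DNA/DNase convolution parameters frozen — enforced by excluding them from
the optimizer and asserted by a SHA-256 digest of their bytes recorded at
every epoch. Loss is cross-entropy, optimizer Adam (lr 1e-3, batch 128),
early stopping on a held-out 10% slice of the training windows with
patience 5, best-validation weights restored. All randomness derives from
one seed; inference is deterministic; bit-exact reproducibility is only
expected for a fixed BLAS configuration.

Per-origin probabilities average the window probabilities of that origin
(`max` is available as an alternative). Cross-cell-line prediction fits a
fresh auto-encoder on the target cell line's windows (one shared fit, so
identical source models give identical output) and averages per-model
origin probabilities without weighting.

### Reduced configuration

Desk-scale experiments use `NetworkConfig.reduced()`: 16/8 kernels in the
same stack shape, dense (32, 16), dropout 0.2. It trains in ~30 s on one
CPU for the default synthetic benchmark.

## Motif visualization

A position `i` of a sequence activates a kernel when the bias-free,
pre-ReLU convolution sum exceeds `α · EAV`, with `EAV = Σ_m max_n w_mn`
the kernel's extreme activation value over one-hot inputs and `α = 0.9`
(strict inequality). The 8-mers at activated positions of the scanned
sequences (training-fold positives by default; windows containing N are
skipped) are pooled into per-column counts, a pseudocount of 0.1 is added
per cell to avoid zero columns, and the rows are normalized. Kernels with
`EAV ≤ 0` or no activations are skipped, not errored. PWMs are written in
MEME minimal format (8 decimal places, so a parse round-trip is accurate
to ~1e-8).

### Motif recovery at small scale

With training sets of a few hundred distinct regions, the deep positional
architecture separates classes by memorizing region fingerprints rather
than abstracting the shared motif — its dense readout sees
position-specific features, so the gradient that would align a first-layer
kernel with a motif occurring at random offsets largely cancels. (At the
full data scale of hundreds of thousands of windows this does not bind.)
The motif-recovery experiment therefore trains the canonical
motif-discovery configuration, `NetworkConfig.motif_scanner()`: the same
first convolutional layer (16 kernels × length 8) read out through a
global max over positions — which makes the kernel gradient coherent — on
a dataset with many distinct implanted sites
(`SyntheticConfig.motif_discovery()`: 800 enhancers, balanced negatives,
sparse windowing). Kernel convergence to the implanted matrix is an
initialization lottery, as in any multi-start motif finder, so six
restarts are trained and all extracted PWMs pooled; recovered motifs
reach per-column Pearson correlation ≈ 1.0 with the implanted PWM.

## Synthetic data

The generator emulates the statistical structure the method assumes: an
i.i.d. background genome with adjustable GC (default 0.41, human-like);
non-overlapping enhancers with lengths uniform on 200–400 bp (bracketing
the 275/288 catalogue statistics); one motif site per enhancer sampled
from an 8×4 PWM (default: an AP-1/CREB-like consensus at 85% per-position
probability, ≈ 9 bits) written into the genome at a uniform internal
offset; and `k` independent replicate read-start tracks with
`counts ~ Poisson(λ_enh)` inside enhancers and `Poisson(λ_bg)` outside —
the simplest law consistent with per-position read-start counts. Default
rates 0.5/0.1 per position give the five-fold elevation used throughout.
Both signal channels can be silenced independently (`motif_prob = 0`;
`λ_enh = λ_bg`), which yields the matched no-signal control.

Default study conditions: 50 enhancers on a 600-kb chromosome, ratio
1:10 with GC matching, stride-10 augmentation, two replicates, 5 folds.
The no-signal control is evaluated by pooling held-out origin scores over
all five folds (550 origins), since a single fold of 110 origins leaves
the null AUROC too dispersed to interpret.

What the generator does **not** emulate: DNase cut bias and fragment-size
structure, replicate batch effects, repeat structure and long-range
composition of real genomes, multiple or degenerate motifs per enhancer,
and any coupling between motif occupancy and accessibility. Passing the
synthetic benchmark therefore demonstrates that the machinery learns and
evaluates correctly under the model's assumptions, not that real-data
accuracy figures transfer.

## Problem sizes and runtime

All shipped experiments run on one CPU: the default benchmark trains the
reduced joint model in ~30 s per fold; the pooled no-signal control
(5 folds) takes ~2 min; the motif-recovery experiment (~4300 windows, six
restarts × 150 epochs) ~4 min. The full-scale configuration (128/64
kernels, dense 512/256/128) is constructed and shape-checked in the tests
but not trained there.

## Known limitations

- At desk scale the sequence-only model barely exceeds chance on held-out
  origins (the joint model's accuracy is carried by the accessibility
  channel); a PWM-scan oracle bounds the sequence channel itself at
  AUROC ≈ 0.85 under the default conditions, so most of the gap is the
  optimization issue described under Motif recovery.
- The fixed-stride augmentation scheme is a reconstruction; published
  per-cell-line augmented sample counts imply a window set roughly 100×
  larger per region than contain/contained windowing can produce, so such
  counts are not comparable.
- The auto-encoder embedding is linear per position; nonlinear replicate
  structure is not captured.
- MEME export covers the motif hand-off only; motif matching (TomTom) and
  database comparison are external.
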
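# Methods

## Problem setting

Finger-vein verification decides whether two near-infrared finger images
belong to the same person by comparing embedding vectors. In a federated
setting, m organizations each hold a private dataset `D_k` of grayscale
vein images with disjoint identity sets and markedly different imaging
conditions (class counts, samples per class, finger orientation,
contrast, illumination, noise) — the classic non-IID obstacle to naive
parameter averaging. The simulator implements a *personalized* scheme:
the embedding encoder is shared and aggregated; each client's classifier
head stays local, and only compact per-class prototypes cross the wire
in addition to encoder parameters.

## Preprocessing and quality scores

Each client enhances its images once, before any training round:

1. Gradient image `Ig = |G * I|`, with `G` the 3×3 Sobel stencil
   (vertical-finger form; transposed for horizontally oriented fingers).
   Responses **above** the threshold `T = 100` are set to zero — the
   convention treats very strong responses as artifacts, so every
   gradient pixel lies in `[0, T]`. Borders are replicate-padded so the
   gradient has the input's shape.
2. Enhanced image `I' = clip(I + Ig, 0, 255)` — edges are brightened,
   nothing is darkened.
3. Edge intensity `b = Σ Ig`, averaged over each class's samples,
   min-max normalized within the client to `b' ∈ [0,1]`, and mapped to a
   quality score `Q = 100 / (1 + exp(−u(b'−0.5)))` with steepness
   `u = 10`.

During training, the `Q` values of a batch are standardized with the
batch's population standard deviation, scaled by `1/h` with `h = 0.33`,
and clipped to `[−1, 1]`, giving the per-sample indicator `Q̂`.

Degenerate-input conventions (all chosen so the adaptive margin falls
back to the plain fixed margin): if every class has the same edge
intensity, or a client has one class, `b' := 0.5` (so `Q = 50`); if a
batch has one sample or zero spread, `Q̂ := 0`.

## Head, margins, loss

Embeddings are L2-normalized, as are the columns of the local head `W_k`
and all prototypes, so every logit is a cosine. The prototype-expanded
matrix `W'_k` concatenates other clients' prototype blocks around `W_k`
in ascending client order; prototype columns are frozen (their owners'
property) and are never legal targets. The target logit is

    f(θ_y) = s · ( cos(θ_y + g_angle) − g_add ),
    g_angle = −m·Q̂,   g_add = m·Q̂ + m,

with `θ_y + g_angle` clamped to `[0, π]` so the logit stays monotone in
the angle, and `θ` computed as `arccos` of the cosine clipped to
`±(1 − 1e−7)`. Non-target logits are `s·cos θ_j`. The printed form of
the margin expression is parenthesization-ambiguous; the angular margin
is placed inside the cosine (the standard adaptive-margin construction),
and a `literal_form` switch provides the affine reading
`s(cos θ + g_angle − g_add)` for comparison. The per-sample loss is the
softmax cross-entropy over local columns plus all prototype columns;
when label sharing across clients is enabled, prototype columns carrying
the sample's own label are excluded from the denominator. Gradients flow
to embeddings through *all* columns (repulsion from foreign prototypes
shapes the encoder) but to weights only through the local block, chained
through its column normalization. All gradients are analytic and are
checked against central finite differences (relative tolerance 1e−4) in
the tests.

The scale `s` defaults to 64, the convention for normalized-softmax
margin losses tuned on web-scale class counts. The desk-scale reference
configuration uses `s = 16`, appropriate for federations of tens of
classes (larger scales saturate the softmax long before the encoder has
learned anything). Margin `m = 0.4`.

## Federation

Per round, every client: loads the global encoder; rebuilds `W'_k` from
the prototypes received this round; runs its local epochs of mini-batch
SGD (momentum buffers persist across rounds, since the personal head and
its optimizer state never leave the client); then recomputes prototypes
with the *updated* encoder over its full training split and uploads
them. Round 1 bootstraps with no prototype columns — meaningful
prototypes do not exist before any training — so prototypes first
circulate in round 2.

The server averages encoder parameter vectors with weights
`|D_k| / Σ_j |D_j|` (sample-count-proportional; the printed form divides
by the federation's total class count, whose weights do not sum to one —
available behind `literal_class_count_weights`). Prototypes aggregate
per class as `S̄_j = (1/|CS_j|) Σ_{k∈CS_j} (|D_k^j|/N_j) S_k^j`; the
leading `1/|CS_j|` shrinks multi-owner prototypes and is kept as printed
(a `normalized` flag drops it), and with the default disjoint labels the
branch is inert: single-owner prototypes pass through bit-identically.
Prototype count is conserved by construction. Distribution of the global
set defaults to `all` (every client receives every prototype, matching
the download accounting below); `exclude_own` is available.

Communication accounting, in units of 2^20 parameters with prototype
dimension d: a client with `N_k` training classes uploads `N_k·d/2^20`
per round and downloads `(Σ_a N_a)·d/2^20` under `all`. For the
published six-dataset configuration (636/600/492/360/220/1680 classes,
8:2 class split so 508/480/393/288/176/1344 training classes, d = 512)
this gives a mean upload of 0.26 and a download of 1.56 — the quantities
the acceptance script recomputes.

## Encoder

The trainable reference encoder is deliberately tiny: per-image
standardization, a fixed 2×2 average-pool stem, three 3×3 conv + ReLU
blocks (8/16/32 channels, average-pooled after the first two), and a
linear projection of the **flattened** 32×8×16 feature map to d
dimensions (default 64 at desk scale; 512 in the communication
arithmetic). Global average pooling was rejected: vein identity lives in
the spatial layout of the curves, and pooling it away makes classes
indistinguishable. Inputs whose geometry differs from the 64×128 grid
are rotated to the majority orientation and bilinearly rescaled, letting
one encoder serve clients with different sensors. Everything — forward,
im2col convolutions, backward — is plain numpy; there is no autodiff
dependency. Heavier backbones can be plugged in through the encoder
contract (parameters as a flat vector, `embed`, serialization).

Prototypes are re-normalized means of unit embeddings. Normalization is
required for them to act directly as classifier weight columns in
cosine space; a class whose embeddings cancel to zero has no direction
and is rejected explicitly.

## Synthetic data

The generator emulates near-infrared finger imaging: a bright soft
elliptical finger silhouette on a dark background, crossed by 5 smooth
dark curves (Catmull-Rom splines through seeded control points, Gaussian
cross-profile, per-vein depth and width). An identity is a template of
control points; each acquisition re-renders it under small shift /
rotation / brightness jitter, then applies the client's imaging
conditions: contrast `x → 127.5 + c(x − 127.5)` (c = 1 is identity),
illumination offset, and additive Gaussian sensor noise, clipped to
[0, 255] 8-bit. The full federation is a pure function of its spec and
master seed (verified bit-for-bit in tests).

The default desk-scale federation has 4 clients — 12/10/8/6 classes,
6 samples per class, 64×128 px — with one low-contrast noisy client,
one vertically-oriented client, and illumination offsets, mirroring in
miniature the heterogeneity of multi-organization collections (the
published experiments use six public datasets of 636/600/492/360/220/
1680 classes, far beyond desk scale). What the generator does **not**
model: real vein topology statistics, sensor optics (blur, vignetting,
specularities), finger misplacement and occlusion, or within-class
appearance drift over sessions. Passing tests therefore demonstrate the
*algorithmic* claims — prototype sharing and quality-adaptive margins
improve open-set generalization under heterogeneity, losses converge,
all the arithmetic is right — not absolute error rates on real
biometric data.

## Training and evaluation protocol

Open-set split: `floor(0.8·n_classes)` training classes per client by
seeded shuffle; held-out classes keep all their samples. A client needs
at least 2 test classes or the split is rejected (no impostor pairs
otherwise). Scoring embeds every test sample and takes cosine
similarities of all unordered pairs ("combinations" — ordered pairs
would double both counts and change no rate). Acceptance rule is
`score ≥ threshold`, ties accept. EER is found by sweeping the sorted
score union (±∞ sentinels) and linearly interpolating FAR and FRR
between the bracketing thresholds; TAR@FAR interpolates TAR in FAR at
the target operating point, except across the ±∞ sentinels (the
degenerate all-ties case must yield TAR = 0, not a point on the
diagonal). Both metrics are validated against brute-force dense-grid
sweeps in the tests.

Desk-scale study conditions (fixed up front, reported by the acceptance
script): 15 rounds, 3 local epochs per round (with ~2 minibatches per
epoch, fewer steps cannot converge in 15 rounds), batch 32, SGD with
learning rate 0.05 and momentum 0.9, `s = 16`, `m = 0.4`, d = 64. The
local-only baseline trains each client independently with the identical
total budget (45 epochs) and the plain margin loss. Across 5 seeds the
federated encoder's held-out mean EER beats local-only training in all
5, and every client's round-15 training loss is below its round-1 value
(the round-2 loss *jump*, when prototype columns first widen every
denominator, is expected and visible in the histories).

## Known limitations

- The optimizer is plain SGD with momentum; the source experiments name
  no optimizer, and no adaptive method is provided.
- The reference encoder is a toy; absolute EER/TAR values at desk scale
  are not comparable to published GPU-scale results and are not meant
  to be.
- The threshold convention of the gradient enhancement (suppressing
  *strong* responses) is implemented exactly as specified; on synthetic
  images most vein-edge responses exceed T = 100 only at sharp borders,
  so the practical effect is mild smoothing of the quality signal.
- Client sampling, dropout, secure aggregation, differential privacy
  and asynchronous rounds are out of scope; all clients participate in
  every round, in-process.
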
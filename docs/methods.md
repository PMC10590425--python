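# Methods

This note documents the models, the synthetic study design, the numerical
choices and the known limitations of `esdflow`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Recognition model

**Spatial encoder.** The default backbone (`"small-conv"`) is four strided
convolution blocks (5×5 stride 4, then three 3×3 stride 2, ReLU) with global
average pooling to `d` dimensions (default 64); `"tiny-conv"` (three blocks)
serves very small fixtures. Backbones are registered by name, so heavier
architectures can be plugged in without touching the training code. Frames
are scaled to `[0,1]` and centered; the encoder demands a fixed `input_hw`
and rejects other shapes. All layers, gradients and the SGD-with-momentum
optimizer are implemented directly over NumPy arrays; every backward pass is
validated against central finite differences in the test suite.

**Stage-1 objective.** Two linear projection heads (ReLU between, output
L2-normalized) feed the supervised contrastive loss; a linear classifier on
the backbone embedding adds cross-entropy. Two readings of the contrastive
denominator exist in the literature and both are implemented behind
`EncoderConfig.contrastive_denominator`:

* `paper_literal` (default): the denominator sums over different-phase
  frames `N(i)` only. Because the positive-pair similarity then appears only
  in the numerator, the loss is *unbounded below* — with normalized
  embeddings it is bounded by `±1/τ` per pair, so optimization is still
  well-posed; training curves simply go negative.
* `all_others`: the standard supervised-contrastive denominator over all
  non-anchor frames; nonnegative with one positive per anchor.

Anchors lacking a positive or a negative are skipped; a batch in which every
anchor is skipped raises. Embeddings entering the dot products are always
unit-normalized (bounding the exponents; the formula itself does not fix a
normalization). The training objective combines the *per-anchor mean* of the
contrastive term with the *mean* cross-entropy so the loss scale is
batch-size independent.

**Temporal fusion.** Each residual layer computes
`D + conv1x1(ReLU(causal_dilated_conv(D)))`; the convolution is applied to
the same tensor the residual adds (the standard residual form — a mixed
layer indexing would leave the first layer undefined). Causality is realized
by left zero-padding of `(k−1)·dilation`; the contract is the causality
property itself (outputs at ≤ t never depend on inputs > t, asserted
bit-exactly), not the padding mechanism. Kernel size 2 with dilations
doubling over 9 layers is chosen because it gives receptive field
`1 + Σ 2^l = 512` exactly; `d'` defaults to 64 and the input projection
`d → d'` is a 1×1 convolution. A single stage (one hierarchy of dilated
layers) is used.

**Attention head.** One head, one layer. The window `n` (default 30 frames,
capped at `t+1` early in a stream) bounds how far the query attends back
over temporal embeddings. The attention output passes through an explicit
4-way linear classifier before the outer softmax — the attention equation's
output dimension is not inherently 4, so the classifier is a documented
component rather than an implicit assumption. Argmax decisions break ties
toward the lowest canonical phase code; Youden-threshold decisions pick the
largest margin `p_k − threshold_k` among passing phases and fall back to
argmax when none passes.

**Schedules.** The full-scale schedule (`"full"` preset, sized for real
surgical video corpora) is stage 1: 8000 iterations, batch
128, lr 5e-4 (÷10 at 6000); stage 2: 4000 iterations, lr 5e-3 (÷10 at 1500
and 2500); SGD momentum 0.9; the final-iteration model is the released model
(no early stopping). The desk preset — the package's own choice for
one-CPU-minutes turnaround — is stage 1: 320 iterations, batch 32, lr 5e-3
(÷10 at 240); stage 2: 160 iterations, lr 1e-3 (÷10 at 100 and 140).
Stage-1 batches sample frames uniformly over (case, frame) pairs; stage-2
iterations consume one whole video's embedding sequence, with all spatial
embeddings precomputed once from the pruned, frozen encoder (per-frame
cross-entropy on `p_t` is the stage-2 loss).

**Numerical safeguards.** The residual branch's 1×1 convolution is
initialized at 0.1× He scale so the 9-layer stack starts near the identity;
a global gradient-norm ceiling (default 5.0, `StageSchedule.clip_grad_norm`)
prevents the dead-ReLU collapse that a single oversized momentum step can
trigger in small networks. Both are standard deep-learning practice and
documented here because they were load-bearing: without them some seeds
diverge or die at desk-scale learning rates.

## Streaming engine

The stream state holds (a) the FIFO queue of at most R = 512 spatial
embeddings — when `e_i` falls out of the receptive field it graduates from
the queue — and (b) the last `n` temporal embeddings `m_i`, each computed at
the moment its frame arrived. Point (b) matters for exactness: `m_t`
computed from the queue is exact because the queue spans position t's whole
receptive field, but *recomputing* `m_{t−j}` (j ≥ 1) from a truncated queue
would not reproduce its offline value. Caching the head's window of past
`m_i` keeps streaming ≡ offline while state stays O(R + n), independent of
stream length. The equivalence tolerance is 1e-5 to allow for summation-
order differences; in practice the implementation reproduces offline
probabilities to machine epsilon because the per-position arithmetic is
identical. Per-stage wall-clock latencies (encoder / fusion / head) are
recorded on every push and summarized as median + IQR; they are
hardware-dependent facts and never test assertions.

## Evaluation statistics

Overall accuracy is multi-class frame accuracy (trace of the 4×4 confusion
matrix over total frames); the one-vs-rest `(TP+TN)/(TP+TN+FP+FN)` form is
reserved for per-phase metrics, where the two readings coincide. Precision
and recall are macro-averaged over phases present in the truth (micro
behind a flag); a phase with zero predicted positives contributes precision
0. ROC curves sweep all unique scores; AUROC is trapezoidal and must agree
with the Mann-Whitney rank formulation (ties ½-credited) to 1e-9 — a tested
equivalence. The Youden threshold maximizes J = sensitivity + specificity −
1 with ties broken toward the higher threshold (more conservative positive
calls); a 1e-12 tolerance absorbs one-ulp differences between algebraically
tied J values. Per-phase metrics for a phase absent from (or universal in)
the truth are marked unavailable rather than raised. Group aggregates are
per-case means with Student-t 95% CIs — the case, not the frame, is the
replication unit — and arms are compared with a two-sided paired t-test
(identical pairs are a degenerate-variance error, not p = 1).

## Synthetic study design

The generator emulates the *structure* of annotated ESD video, not its
appearance: a semi-Markov grammar (Marking first; Injection/Dissection
alternation interleaved with Idle; no return to Marking) with gamma dwell
times (shape 4; means Marking 20 s, Injection 10 s, Dissection 60 s, Idle
8 s — fixture choices that make Dissection dominate total time, as it does
clinically). Skill has two mechanisms, both scaled by
`idle_rate_multiplier`: transition weights *into* Idle, and an exponential
hesitation hazard (mean 150 s at multiplier 1) that interrupts working
phases into Idle mid-dwell. The hazard is what separates the arms in
transitions-per-minute; weight scaling alone barely changes the cycle
length because the Dissection dwell dominates it. Rendering gives each
phase a distinct base color and texture frequency, a moving tool-like
highlight and Gaussian pixel noise; a nearest-centroid classifier on mean
frame color recovers ≥95% of labels at low noise — the intended difficulty:
the *spatial* problem is easy, so end-to-end tests probe the temporal
machinery. The simulated second rater jitters segment boundaries
(`round(N(0, jitter·fps))` frames, clipped to keep segments nonempty) and
relabels segments to a random *other* phase. Note that exclusive relabeling
structurally biases Pearson agreement negative (−1/3 for uniform labels),
so a full-relabel control lands slightly below zero, not at it.

Default study conditions: 600 s cases at 1 fps, 64×64 frames (tests use
32×32 and embedding width 32 for speed). The 600 s duration is deliberate:
with 300 s videos the default 512-frame receptive field covers entire
training sequences and the TCN memorizes whole-prefix patterns —
cross-validated accuracy collapses while training accuracy stays high.
Desk-scale problem sizes used by the test suite: 10 cases × 600 frames for
the 5-fold chronological cross-validation; 20 random-weight models on
videos of 700–2000 frames for the streaming equivalence sweep; 20 cases per
arm for the skill comparison.

What passing these tests shows — and does not. The synthetic phases are
color-separable, stationary within a phase, and noise is i.i.d. Gaussian;
real endoscopy has intra-phase drift, specularities, tool occlusion and
inter-patient appearance shifts. Green tests therefore certify the
*correctness of the machinery* (losses, causality, streaming equivalence,
metric definitions, fold layout, skill statistics), not clinical-grade
recognition accuracy.

## Fold assignment

Cases are ordered by date and position i goes to fold `i mod k` — the
strided reading of sampling "at equal intervals", and the only one
consistent with fold sizes (10, 10, 9, 9, 9) for 47 cases. Every fold spans
the full date range, so each held-out fold sees the whole equipment/era
distribution. Assignment is deterministic and seed-independent.

## NT-index

The Normalized Transition index is implemented as the cumulative transition
count divided by lesion size (transitions/cm), sampled per frame: a
nondecreasing right-continuous step curve whose final value × lesion size
equals the total transition count exactly. An alternative reading that also
divides by elapsed minutes (a transition *rate*) is available via
`per_minute=True`; the cumulative form is the default because the reported
end-of-procedure scores behave like totals. The report records whether its
phase track came from model predictions or ground-truth annotations.
Trainee ranking sorts ascending by final NT-index (smoother first).

## Known limitations

* A train-time label-shuffle control is *not* chance-level for phases
  locked to stream position: the shuffled-label model's confidence varies
  with position (the zero-padded prefix regime of the causal TCN), and
  Marking always opens a procedure, so its one-vs-rest AUROC reflects
  position rather than leakage (~0.9 observed). The chance-level control in
  the acceptance suite is therefore the standard permutation control —
  scores against permuted truth — which isolates the metric pipeline.
* The `paper_literal` contrastive mode is unbounded below; loss histories
  are comparable within a run but not across denominator modes.
* `resnet50`-class backbones are not bundled; the registry accepts custom
  backbones, and the small default is what the desk-scale guarantees are
  calibrated against.
* HTML reports embed matplotlib figures as base64 PNG; rendering is
  deterministic in content but not byte-identical across matplotlib
  versions (the JSON document, not the HTML, is the lossless artifact).
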
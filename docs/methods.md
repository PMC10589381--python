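# Methods

## The counting problem

A lifespan assay produces one plate image per day for up to 60 days; the
quantity of interest is the number of live worms on each day, from which the
survival curve follows. Deciding *live vs dead* from a single still image is
ill-posed — a live worm can be stationary — so the method treats the whole
assay as one sequence and lets a network infer liveness from displacement
between days. Counting starts on assay day 4 (young adulthood), and the
fixed model sequence length of 57 covers the longest assays (60 days).

## Simplified domain

Real plate photographs vary in illumination, dirt and worm appearance. All
of that is collapsed by a *domain change*: a detector reduces each image to
worm bounding boxes, and boxes above a confidence threshold (default 0.85,
chosen as the precision/recall balance point of the wrapped detector) are
re-rendered as filled discs on a constant background at 256×256. The
counting network only ever sees this blob domain, which a simulator can
reproduce exactly — sidestepping the sim-to-real domain gap without GANs or
photorealistic rendering. Training the detector itself is out of scope; any
model emitting the `DetectionSet` schema plugs in, and a deterministic mock
ships for tests. (For users who retrain a detector externally, the
reference regime for a Faster R-CNN/ResNet-50-FPN on ~1900 labeled plate
images is 20 epochs, SGD momentum 0.9, weight decay 5e-4, lr 0.005 stepped
×0.1 every 3 epochs, vertical-flip augmentation.)

## Survival model and parameter grid

Theoretical cohort survival uses the two-parameter Weibull function S(t) =
exp(−(t/b)ᵃ): b is the scale in days (b ≈ mean lifespan for the shapes
used, since the mean is b·Γ(1+1/a)), a is the slope of the mortality wave.
The training grid crosses worms-per-plate 10–15 (what the assays actually
hold), mean life 5–57 and slope 4–20, inclusive unit steps — 6×53×17 = 5406
curves. Each draw jitters the curve with independent per-day uniform noise
(default ±0.05 of survival fraction), clamps to [0, 1] and re-monotonizes
with a running minimum; the magnitude is a package choice (exposed as
config) since only the existence of "random transformations" is prescribed.
Fractions become integer counts by half-up rounding times the population
size, re-monotonized.

## Blob-world simulator

State per worm is a table row: id, alive flag, last (x, y) position
(column/row, 0-based, disc centers). Per capture day: uniformly chosen
alive blobs die until the count matches the trajectory; dead blobs keep
their last position forever (their discs keep being drawn — a dead worm is
visible but motionless); surviving blobs move to fresh uniform positions in
the plate disc (inscribed circle minus a margin, default 10 px). Nuisances
recreated, all config-exposed because their real magnitudes are unstated:

- **Occlusion** — each blob is skipped for the current day with probability
  0.05 (default); labels still count it if alive, since occlusion hides
  worms, not deaths.
- **Blank days** — no-capture days (default: days ≡ 6, 0 mod 7, i.e.
  weekends) emit a background-only frame; the label carries the previous
  day's count, matching manual bookkeeping.
- **Frame placement jitter** — the composed frame is rotated up to ±3° about
  its center and translated up to ±4 px (nearest-neighbour, background
  fill), emulating plate placement in the rig.
- **Tail padding** — once the population is extinct the last rendered frame
  is replicated to the end of the sequence with label 0: no displacement
  means everyone is dead, which is exactly what the network must learn.

Geometry: blob radius 3 px at 256×256 (a worm projects ≈55×3 px at
1944×1944, ≈7×0.4 px after rescaling; a radius-3 disc has comparable area),
background 255 / blob 0 (backlit bright field). Datasets are generated
online: the stream cycles the 5406-triple grid and re-draws curve jitter and
positions per pass from per-sample seeds split off one master seed, so it is
infinite, non-repeating across passes, and bit-reproducible.

## Counting network

Per frame, three valid (unpadded) 5×5 convolutions with 4/8/16 channels,
each followed by batch norm (eps 1e-5, momentum 0.1), leaky ReLU and
non-overlapping max pooling of 3/4/2 — spatial trace 256 → 252 → 84 → 80 →
20 → 16 → 8, flattened to a 1024-long frame feature. A sequence block mixes
days: LSTM or GRU (hidden 1024, 2 layers) or a pre-norm transformer encoder
(dim 1024, depth 2, heads 8, mlp 2048, head dim 64) with learned positional
embeddings (day order *is* the signal, so position must be explicit; the
choice of learned embeddings is a package decision). The head flattens the
whole sequence block output (57×1024) through 2000 → 2000 → 750 linear
layers with batch norm + leaky ReLU to a 57-long count vector — which fixes
the sequence length per trained model. All three variants share shapes and
training loop.

Training: MSE over all frames in the batch, plain SGD (momentum 0.9, no
weight decay — both unstated upstream and config-exposed), 600 epochs, lr
0.001, batch 16 at full scale. Inputs are frames scaled to [0, 1]; raw
outputs are rounded half-up and clamped at 0 for reporting.

The layers run on an in-package numpy autograd core (reverse-mode, with
fused valid-convolution and argmax-routed max-pool gradients) verified
against central finite differences in the test suite. Checkpoints store
weights, running batch-norm statistics, optimizer momentum, the
architecture spec and the loss history, so interrupted runs resume exactly.

### Scaled-down configuration

CPU-scale work uses a first-class *tiny* spec: 64×64 frames (pools 3/2/2,
trace 64 → 60 → 20 → 16 → 8 → 4 → 2, 64-long features), sequence length 10,
head 256/256/128, hidden 128. The scaled-down training run in the
acceptance checks uses one grid triple (12 worms, mean life 6, slope 5 — so
the full mortality wave fits in 10 days), 50 epochs, lr 0.001, batch 8, two
batches per epoch; it finishes in well under a minute and reliably drives
the per-frame MAE from ≈7 worms (untrained) below 1.

## Detection evaluation

A prediction is correct when IoU with a ground-truth box reaches 0.5.
Matching is one-to-one and greedy in descending score order (the VOC/COCO
convention; the matching rule is a package choice, with IoU ties broken by
truth index for determinism): each prediction takes the unmatched truth of
highest IoU or becomes a false positive; unmatched truths are false
negatives, so TP+FP = detections and TP+FN = targets by construction.
Precision, recall and F1 follow, with score-threshold sweeps filtering
predictions *before* matching. Reported metrics round half-up to 3
decimals.

## Curve assembly and statistics

Plates of one condition are pooled by summing daily counts and initial
populations; percent alive is count×100/n_initial. The two-cycle
post-processing splits at the strain's mean life: days up to the split get
a right-to-left running maximum (early under-counts from occlusion are
raised; capped at the initial population), later days a left-to-right
running minimum seeded by the last early-cycle value (late over-counts from
dirt are lowered; the first late day is thereby also capped by the early
cycle). The result is globally non-increasing and idempotent. The upward
rule is implemented as a running maximum because only that reading produces
a monotone survival curve.

Curve agreement: per-day e(d) = |%manual(d) − %automatic(d)|, summarized
by the mean (MAE) and the population (ddof = 0) standard deviation over
days — per-day, not per-plate, since the error definition sums over days.
The log-rank test expands daily counts into per-subject event times (deaths
between capture days assigned to the later day — daily data carries no
finer resolution; worms alive at the last day right-censored there) and
applies the standard two-group chi-square with 1 df via lifelines; the test
suite checks it against an independently coded risk-table implementation to
1e-9. Identical curves short-circuit to (0, 1). Non-increasing input is
enforced by clipping, as the test is defined on valid survival data.

## What the simulator does and does not show

Passing tests on simulated data demonstrate that the counting architecture
can read survival trajectories out of blob-movement sequences, that the
pipeline is deterministic under seeds, and that every processing step obeys
its contracts. They do not demonstrate real-assay accuracy: the simulator
renders ideal discs with no detector errors (false positives from dirt,
misses from aggregation), no worm morphology, and its occlusion/jitter
magnitudes are assumptions. Published validation on real N2 and daf-2
assays is the benchmark for that; reproducing it requires the real image
dataset and full-scale training, neither of which ships here. Simulating
detector error statistics is a natural extension.

## Numerical and scale choices

- Problem sizes in the shipped checks: tiny-spec training (50 epochs, 800
  samples), 50 held-out sequences, 100 round-trip plates, 1000
  post-processing curves, 100 oracle comparisons — sized for a single CPU.
- Rounding: half-up everywhere a fraction becomes an integer or a printed
  decimal (deterministic, matches common reporting).
- The plate-disc sampler uses rejection sampling (uniform over the disc);
  blob positions are integer pixels.
- Degenerate inputs: empty detection sets render blank frames; zero-denominator
  precision/recall/F1 return 0 by convention; empty segmentation windows
  raise a dedicated error so callers can fall back to manual correction.
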
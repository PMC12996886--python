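# Methods

## The problem

Brain age is the age a model predicts for a person from a structural brain
scan; the brain age gap (BAG = predicted − chronological age) is a compact
biomarker of deviation from typical ageing.  Two things make a BAG model
useful: it must actually track age, and it must not secretly track things
that correlate with age in the training data but are biologically irrelevant
— above all the scanner/site a volume came from and, where it should be
excluded, gender.  `brainacn` implements an adversarial convolution network
(ACN) that learns age-predictive, confound-invariant representations, plus
the downstream molecular-network statistics used to relate BAG-associated
genes to disorder risk genes.

## Model

**Encoder.**  A stack of `conv_blocks` 3D blocks, each 3×3×3 convolution
(stride 2, padding 1) → batch normalisation → ReLU, followed by global
average pooling and a linear + ReLU projection to an `embedding_dim`-wide
"stratified feature" vector.  Channel widths default to 4·2^b per block.
The published network's internal dimensions are not public; depth and width
are configuration here, with a desk-scale default (3 blocks, 16-wide
embedding) small enough to train on one CPU.

**Distributional age labels.**  A scalar age y is encoded as a 90-bin
probability vector over integer ages 5–94: bin c receives
F(c + ½) − F(c − ½), where F is the normal CDF with mean y and standard
deviation σ (default 2.0 years), renormalised over the truncated support
[4.5, 94.5].  The age head is a 90-way softmax; its expectation decode
Σ q_c·c is the predicted age.  μ is read as the individual's label age —
a per-sample Gaussian — with σ a global hyperparameter; this matches the
soft-classification lineage the architecture follows, although the original
wording ("expectation and variance for the age labels") could also be read
as a cohort-level distribution.  Ages outside [5, 94] are clamped with a
warning rather than rejected, since application cohorts fit inside the
support but fine-tuning data might not.

Note one intrinsic limit: near the support edges the truncation itself
biases the expectation decode (0.68 years at age 10 with σ = 4, for any
decoder), so sub-quarter-year round-trip accuracy holds for ages more than
about 2.4σ from the edges.

**Losses.**  The age loss sums, per subject, an L1 term |y − ŷ| and the
KL divergence KL(p‖q) between the soft label p and the predicted
distribution q (probabilities floored at 1e−12 before logs).  Each confound
factor i with C_i classes contributes a mean cross-entropy over the batch;
factors enter with equal unit weights.  The total loss is the plain sum of
the two parts — the adversarial sign lives in the gradient flow, not in the
loss value.

**Gradient reversal and mixed modules.**  Each confound factor (gender,
data site) has a "mixed module": feature standardisation plus a linear
classifier, reached only through a gradient reversal layer — identity
forward, gradient multiplied by −λ backward.  The heads therefore descend
on the confound cross-entropy while the encoder ascends it.  λ follows the
domain-adversarial (DANN) ramp λ(p) = λ_max(2/(1+e^{−10p}) − 1) over
training progress p, with λ_max = 1 by default.

**Why the heads are refit in closed form.**  In early experiments the heads
were trained jointly by SGD, and the minimax stalled: the embedding drifts
each step, a lagging head hovers near chance on the *residual* confound
signal, and whatever linear direction the head has not yet found receives no
adversarial pressure — an after-the-fact linear probe (trained to
convergence) still reads the confound perfectly.  The implementation
therefore solves the inner maximisation exactly for the linear-head family:
before each encoder update, every confound head is refit by ridge
regression of ±1 class indicators on a sliding buffer of recent embeddings
(20 batches, standardised, ridge α = 1e−3).  The encoder then receives the
reversed cross-entropy gradient of a near-optimal adversary.  The reversal
layer, the cross-entropy, and the λ-ramp are unchanged; only how the head's
own parameters reach their minimum differs.

**Optimisation.**  Adam, batch size 12.  Real-scale defaults are learning
rate 1e−4 over 200 epochs; the phantom profile uses 1e−3 over 30 epochs,
appropriate for a 3-block network on a 32×40×32 grid.  Two scale choices
matter and are deliberate: (1) the age term enters the training gradient as
a per-batch mean so that both objectives reach the encoder on the same
scale — with the raw sum, a batch of 12 gives the age gradient a 12×
advantage and the adversary barely registers (the reported value of the age
loss remains the per-subject sum); (2) the learning rate follows a cosine
decay to a 5 % floor, so late epochs settle into the adversarial
equilibrium instead of oscillating around it.  An optional decoupled weight
decay (`weight_decay`, default 0) is exposed but off.  Each epoch ends with
a validation pass; the checkpoint with the lowest validation MAE is
returned.  Training is single-threaded numpy and exactly reproducible from
the seed.

The network and its training run on a small reverse-mode automatic
differentiation engine written for this package (`autodiff.py`: broadcast
arithmetic, matmul, reductions, ReLU/exp/log, softmax, strided 3D
convolution via im2col, the gradient reversal op, Adam).  Every operation is
verified against central finite differences in the test suite.

**Fine-tuning.**  Transfer to a new cohort continues optimisation of all
weights at 0.1× the original learning rate for 100 epochs by default
(`--freeze-encoder` restricts updates to the heads).  This mirrors adapting
a wide-age-range model to an elderly cohort whose age distribution the
pre-training never saw.

**Embedding width (16).**  The embedding is the lever that decides whether
the adversarial contrast is even observable.  At width 32 the encoder has
enough slack that site information survives adversarial pressure in some
direction; at width 8 the bottleneck is so tight that even a *baseline*
model often discards site incidentally, leaving nothing for the adversary
to demonstrably remove.  Width 16 gives both effects reliably: a baseline
leaks site almost perfectly, the adversarially trained model does not.

## Phantom cohorts

The generator renders, per subject, a bright brain ellipsoid (semi-axes
0.40 of the grid) containing a central dark ventricle whose radius grows
linearly with age (`atrophy_rate`, default 0.05 voxels/year from a base of
1.5) — a minimal geometric analogue of ventricular enlargement.  Gender
scales the whole structure by ±`gender_effect`/2 (default 0.05, a few
percent of size dimorphism); data site multiplies all intensities by
1 + s·`site_bias_strength` (default 0.10, a strong scanner-gain analogue);
i.i.d. Gaussian voxel noise (`noise_sd` = 0.05, roughly SNR 20 for tissue
at intensity 1) is added last.  Ages are uniform over [5, 94]; sites and
genders are balanced round-robin, so age and site are independent by
default (`confound_age_site` skews per-site age windows for stress tests).
Cohorts are byte-reproducible from the seed.

The design separates the signals by construction: age is geometric, site is
multiplicative intensity, gender is scale.  That separability is what makes
"remove site, keep age" a solvable task, and is the property the efficacy
evaluation exercises.  What the phantoms do *not* model: registration
error, bias fields, partial-volume effects, anatomical variability,
nonlinear age trajectories.  Passing tests on phantoms demonstrates that
the machinery works where the confound is separable; they say nothing about
how entangled real scanner effects are with real anatomy.

## Evaluation fixtures

The standard fixture trains on n = 600 phantoms (32×40×32 grid, 2 sites,
2 genders, 30 epochs) and evaluates on an independent n = 200 cohort, for
seeds {0, 1, 2}.  Volumes enter training at the generator's raw intensity
scale (the multiplicative site cue is the point of the exercise; per-volume
min–max or z-score normalisation remain available as load options and
z-score would cancel a global gain by construction).  Confound leakage is
measured by a 5-fold cross-validated linear SVM (with feature
standardisation) predicting site from the frozen embedding; age accuracy by
MAE/R²/Pearson r of predicted vs chronological age.  The contrast reported
is median-over-seeds site-probe accuracy of the full model vs the same
backbone trained without mixed modules, alongside the full model's age
correlation.  The transfer fixture fine-tunes the seed-0 model on an
age-restricted cohort (ages 45–85, n = 240) and compares zero-shot vs
fine-tuned MAE there.  Problem sizes were chosen so the full suite trains
six models in minutes on one CPU.

## Network statistics

Given a gene network (directed TRN or undirected PPI/co-expression) and
gene sets, the module computes:

- **Seed subnetwork**: keep edges with at least one endpoint in the seed
  set, then take the largest connected component (direction ignored for
  connectivity; size ties broken by smallest lexicographic node label).
- **Connectivity score** Cs = (C_i/C_o)/(N_i/N_o): the node's in-subset
  connection fraction over the subset's share of the network.  Cs > 1 means
  preferential connection into the subset.  Directed networks use total
  (in + out) degree — "connections" carry no direction here; an isolated
  node scores 0 by convention.  `mean_connectivity` also reports the
  background mean over non-query nodes for the "compared to other genes"
  contrast.
- **Jaccard enrichment** |A∩B|/|A∪B| on node sets, higher = more similar.
  (The source literature calls this a "Jaccard distance index" although it
  is a similarity; the misnomer is noted, the formula is as printed.)
- **Hub TF ranking**: within the seed subnetwork of a directed TRN, seed
  nodes with outgoing edges ranked by out-degree (out-degree, not total,
  because "regulated by" is directional), ties lexicographic.
- **Pleiotropy fraction**: among risk genes (union of the disorder sets)
  sharing an edge with a seed gene, the fraction belonging to ≥ 2 disorder
  sets, with the per-gene membership table.

All four are cross-checked against brute-force enumeration oracles on
seeded random graphs; users supply their own networks (TSV edge lists) and
gene sets (GMT) — the package does not reconstruct TRN/PPI/co-expression
networks from primary data.

## Numerical and degenerate-case choices

- Predicted probabilities are floored at 1e−12 before any logarithm.
- A constant predictor has *undefined* Pearson correlation: reported as NaN
  with a warning, never silently 0.
- Duplicate undirected edges (including reversed pairs) collapse with a
  logged count; self-loops are format errors.
- Volume intensity normalisation at load is min–max to [0, 1] by default,
  z-score or none on request; gene symbols match case-sensitively with an
  opt-in uppercase normalisation.
- Checkpoints store parameters, batch-norm statistics, and the full
  configuration in one versioned `.npz` archive.

## Known limitations

- The phantom is a geometric toy; none of the results here transfer
  quantitatively to real MRI.
- The closed-form adversary is exact only for linear heads on the frozen
  embedding; a nonlinear probe could in principle still read confounds an
  optimal linear adversary cannot see.
- No BAG bias correction (the regression-toward-the-mean adjustment some
  pipelines apply) is implemented, since none is described in the source
  procedure.
- Real-scale (121×145×121) training is supported by the same code paths but
  is far outside desk-scale budgets.
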
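# Methods

`popsphere` learns a 2-D visualization of population structure from diploid
SNP genotypes by self-supervised contrastive training of a small neural
encoder whose outputs live on the unit sphere in 3-D, followed by an
equal-area map projection to the plane. This note records the model, its
assumptions, the numerical choices, and what the synthetic experiments do and
do not demonstrate.

## Model

**Input.** Genotypes are alternate-allele counts in {0, 1, 2} with −1 for
missing calls, one-hot encoded over four channels (one per genotype state
plus a dedicated missing channel), giving the encoder an explicit
representation of missingness rather than an imputed value.

**Encoder.** Two 1-D convolution layers (5 filters, kernel 3, stride 1,
"same" zero padding) run along the marker axis over the 4 input channels,
followed by a flatten, three dense layers of 256 units with batch
normalization, a dense layer with 3 units, and L2 normalization. SiLU
(x·sigmoid(x)) follows every weight layer. The L2 normalization constrains
every embedding to the unit sphere, so each sample has neighbors in all
directions and the embedding has no origin or center of gravity. The network
and its backward pass are implemented directly on numpy arrays; every layer
gradient and every loss gradient is analytic and is verified against central
finite differences in the test suite.

**Contrastive objective.** Each training batch embeds two independently
augmented views of every sample. View 1 is the anchor z, view 2 the positive
z⁺, and the view-1 embeddings of the other samples in the batch are the
negatives {zᵢ⁻}. Three losses are implemented:

* triplet: max(‖z−z⁺‖ − ‖z−z⁻‖ + α, 0), default margin α = 0.2;
* N-pair: log(1 + Σᵢ exp(zᵀzᵢ⁻ − zᵀz⁺)), inner products in the global frame;
* centroid-based N-pair (the default): for each negative, a centroid
  Cᵢ = (z + 2zᵢ⁻ + z⁺)/4 is subtracted from all three points, the shifted
  vectors are divided by the largest of their three magnitudes μᵢ, and the
  N-pair form is applied to the normalized vectors z̃, with exp(−2)
  subtracted inside the sum.

In the best case — anchor and positive coincident — the normalized inner
products are exactly z̃ᵀz̃⁺ = +1 and z̃ᵀz̃⁻ = −1 regardless of where the
points sit, so each term contributes exp(−2) and the subtraction makes the
best-case loss exactly zero. Because only differences of embedding points
enter, the centroid loss is invariant to translations and rotations of the
embedding; the plain N-pair loss is not translation invariant (both facts
are asserted as tests). By Cauchy–Schwarz both normalized inner products lie
in [−1, 1], so every term is non-negative and so is the loss.

The scale μᵢ is the largest plain Euclidean magnitude. A variant that
compares and returns squared magnitudes is kept behind a `squared` flag for
comparison; with it the ±1 best-case identities no longer hold, which is why
the magnitude form is the default.

**Augmentation.** A view is produced by (1) flipping each non-missing call
with per-sample probability p_flip — homozygotes flip to the heterozygote;
heterozygotes flip to either homozygote with equal probability, so a single
application never moves 0↔2 — then (2) masking each call to missing with
probability p_mask, then (3) one-hot encoding. The order matters and is
fixed: a masked marker's earlier flip is unobservable. Per-view rates are
redrawn every batch from U(rate_low, p_max); defaults rate_low = 0.01,
p_flip_max = p_mask_max = 0.99. With both rates zero the two views are
identical and every loss term sits exactly at the best-case zero with zero
gradient, so training is a no-op — the augmentation is what creates the
learning signal, and the ablation experiment measures exactly this.

**Negatives.** Default: all other samples in the batch. An
`inverse_distance` mode draws n_neg negatives per anchor without replacement
with weights 1/(distance + 1e−12), emphasizing hard negatives.

**Optimization.** Adam (lr 0.001, β₁ = 0.9, β₂ = 0.999), learning rate
decayed by 0.99 every 10 epochs, default 5000 epochs, batch size 64. The
decay interval is interpreted in epochs: a 0.99-per-10-steps schedule
underflows to numerically zero learning rates over a long run; a
`lr_decay_unit="step"` switch restores the per-step reading. Batch
normalization uses batch statistics during training and accumulated running
statistics (momentum 0.9) at inference, so inference embeddings are
independent of batch composition. Training is single-threaded deterministic
given the seed.

**Projection.** Embeddings are visualized by converting unit vectors to
longitude/latitude (φ = arcsin x₃, λ = atan2(x₂, x₁)) and applying the Equal
Earth pseudocylindrical projection, implemented from its published
closed-form polynomial (θ = arcsin((√3/2)sin φ); y = A₁θ + A₂θ³ + A₃θ⁷ +
A₄θ⁹; x = (2√3/3)·λ·cos θ / dy/dθ). The projection preserves relative areas
— verified to 0.5 % on a lat/lon grid — at the cost of shape distortion near
the poles. The sphere carries no preferred orientation; an optional proper
rotation (validated orthogonal, det +1) may be applied before projecting.
Rotation changes the 2-D picture but never the 3-D geometry, and all quality
metrics are computed in the 3-D coordinates for exactly that reason (a pair
split across the ±π antimeridian is adjacent on the sphere even though it
lands on opposite edges of the map).

## Evaluation metrics

All label-based scores use a k-nearest-neighbor classifier (majority vote of
the k closest reference samples, Euclidean distance in 3-D). Whenever the
query set is contained in the reference set each sample is excluded from its
own neighbor set, otherwise the local score would be trivially inflated.
Ties are broken deterministically: neighbor ties by stable sort on sample
index, vote ties by smaller mean neighbor distance and then lexicographic
label.

* **Local (L).** 3NN subpopulation accuracy on the training embedding.
* **Global (G).** Mean 3-D coordinates per subpopulation; 3NN superpopulation
  accuracy among those centroids. The metric needs at least 4 subpopulations
  per superpopulation to be able to reach 1.0 — with 2×2 groups every
  centroid's three neighbors are majority other-superpopulation and the
  score is 0 by construction (kept as a test).
* **Generalization (GE).** 3NN accuracy of held-out samples queried against
  the training embedding. The tier defaults to subpopulation; the
  superpopulation tier is available and is what the ablation experiment
  uses.
* **Neighbor overlap.** Mean fraction of shared members between each
  sample's k-NN set under Manhattan distance in genotype space and under
  Euclidean distance in the embedding, for a range of k.
* **Rank-RMSE.** For each sample's n-th closest genotype-space neighbor,
  the root mean square difference between n and that neighbor's rank in the
  embedding, per n. The square root is applied because the quantity is a
  root mean square error.

Genotype-space metrics require complete matrices; missing calls must be
imputed first (per-marker mode, ties toward the smaller genotype value).

## Synthetic data

The generator uses the Balding–Nichols model at two levels: per marker an
ancestral frequency p ~ U(0.1, 0.5); each superpopulation draws its
frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) with F = F_super (so the
drifted frequency has variance F·p(1−p)); each subpopulation drifts the same
way around its superpopulation frequency with F_sub; genotypes are
Binomial(2, subpop frequency). This produces hierarchically structured,
linkage-free data with a closed-form drift variance used directly in tests.
It deliberately does not model linkage disequilibrium, admixture, or
coalescent genealogies — passing tests show the method recovers clean
hierarchical drift structure, not that it handles admixed or LD-structured
real data.

The SNP-chip masking design emulates cohorts genotyped on different chips:
a fraction of samples (default 20 %) is split into groups (default 4), and
every member of a group has the same random subset of markers (default 20 %)
set to missing; different groups' subsets are drawn independently and may
overlap. Masked cells can be left missing or filled with the per-marker mode
of the untouched samples, which emulates imputing new chips against a dense
reference and mirrors how such data would be prepared in practice.

## Desk-scale experiments and problem sizes

The test suite runs three training experiments on simulated data, sized to
complete on one CPU:

* **Parameter recovery:** 3 superpopulations × 3 subpopulations × 15
  samples, 1,000 markers, F_super = 0.25, F_sub = 0.03, 300 epochs, fixed
  seeds, centroid loss with all-negatives.
* **Augmentation ablation** and **chip-masking robustness:** 3 × 3 × 10
  samples, 400 markers, same F values, 150 epochs. The ablation compares
  validation generalization at the superpopulation tier between
  (p_flip_max, p_mask_max) = (0.99, 0.99) and (0, 0) across three seeds;
  the chip experiment trains on the dense 80 %, embeds the chip-masked
  validation samples, and checks that generalization is close to the
  unmasked case and that a 3NN classifier cannot predict the chip group.

A caveat established empirically and worth recording: at the
parameter-recovery scale the contrastive objective converges much more
slowly than a supervised fit of the same architecture. A supervised head
reaches perfect training-set subpopulation accuracy within ~100 epochs,
while the self-supervised centroid training reaches L ≈ 0.5–0.65 at 300
epochs and needs roughly 1,100–1,500 epochs to plateau at L ≈ 0.93–0.96 and
GE ≈ 0.82–0.93. The slow phase is the nonlinear separation of sibling
subpopulations: the first three principal components of these data separate
only the superpopulations (3-D PCA reaches L ≈ 0.54 where 6-D PCA reaches
0.96), so a 3-D embedding must warp nonlinearly to isolate all nine
clusters, and the instance-discrimination signal that drives this is weak
between genetically similar samples. Batch sizes 8–108, inverse-distance
and pooled-both-views negatives, and gentler augmentation were all examined
and none changes this materially; the 300-epoch scores below the plateau are
a property of the training budget, not of the loss, whose converged behavior
matches expectations.

## Known limitations

* No GPU or multi-process training; runtimes target small desk-scale
  problems. Scaling the marker count grows the first dense layer linearly.
* The simulator omits LD and admixture (above).
* Missing-data handling in training assumes missingness is uninformative;
  the chip experiment probes one structured-missingness pattern only.
* The checkpoint format stores raw float64 weights; it is not portable
  across architecture-config changes (by design: marker-set compatibility is
  checked at load).
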
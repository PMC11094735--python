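# Methods

## Free energies from mean-force profiles

The potential of mean force along the surface separation distance (SSD,
the gap between the outermost surface layer and the adsorbate's center of
mass) is obtained by trapezoidal integration of the negative average
force from a far reference distance s₀ where the force has decayed,
enforcing W(s₀) = 0 exactly. The adsorption free energy is the Boltzmann
average of exp(−W/k_BT) over an adsorption layer of thickness δ:

    ΔG_ads = −k_B T ln[ (1/δ) ∫_a^{a+δ} e^{−W(s)/k_B T} ds ]

Defaults: δ = 0.8 nm, T = 300 K (k_BT ≈ 2.494 kJ/mol), k_B from CODATA.
The layer placement `a` is caller-supplied; by default it is the grid
point of minimum W minus δ/2, clipped to the grid, so a well centered in
the layer is captured and a flat PMF yields exactly 0. Whether the layer
should instead start at the surface contact point is not decidable from
the conventions alone; the sliding-window reading is the package's
choice and both are available through `layer_start`.

Numerics: quadrature is trapezoidal on the supplied grid with the layer
endpoints inserted by linear interpolation; exp(−W/k_BT) is evaluated
after factoring out the minimum of W in the layer, so deep wells cannot
overflow. On smooth wells, halving the grid spacing changes ΔG by less
than 10⁻³ kJ/mol at the grids used in the tests (≥1000 points over 2 nm).

Uncertainty: per-window PMFs (one per production-time window of the
underlying simulation) are averaged pointwise; mean ± n_sd standard
deviations define lower/upper PMF envelopes (n_sd = 1 by default — the
multiplier is a free choice and exposed). ΔG is evaluated on all three
profiles after re-zeroing each at s₀, and the reported interval is
[min, max] of the three, since Boltzmann averaging does not preserve the
envelope ordering.

## Synthetic data generator

Each cell of the molecule × material matrix is

    G(i,j) = μ + a_i + b_j + γ[g(i), h(j)] + ε_ij

with molecule/material offsets a, b ~ N(0, 2 kJ/mol), noise
ε ~ N(0, 0.5 kJ/mol), and a 3×3 group-interaction matrix γ whose
defaults plant the empirically observed pattern: a strong block of
−25 kJ/mol (7 aromatic/cyclic molecules × 6 hydrophobic-carbon
materials), a selective block of −20 kJ/mol (3 anionic molecules × 8
charged/polar materials), 0 elsewhere, around a global mean μ = −10
kJ/mol. Group sizes default to 7/22/3 molecules and 6/19/8 materials.

Why these magnitudes: the 0.5 kJ/mol noise matches the typical
statistical uncertainty of metadynamics free energies; the block depths
are on the scale of strong π-stacking / charge–charge adsorption
contrasts and give between-group centroid distances in profile space
(≈ 35–65 kJ/mol) roughly four times the within-group spread from the
2 kJ/mol offsets — clearly separated groups, but with enough per-item
variation that representative selection and split-stability are
non-trivial. The generator emulates only this block-plus-offsets
structure; it does not reproduce heavy-tailed real free-energy
distributions, correlated errors between chemically similar surfaces,
or molecule-specific anomalies (e.g. a bulky anion clustering away from
its charge group). Recovery results on synthetic data therefore
demonstrate algorithmic correctness, not performance guarantees on
measured matrices.

Toy PMFs are Gaussian wells −depth·exp(−(s−c)²/2σ²) plus optional
pointwise noise, pinned to zero at the far grid end.

## Clustering and probe selection

Molecules are points in material space (kJ/mol in every coordinate, so
no standardization). Distances are Euclidean; the optional
root-mean-square variant divides by √n_materials, a global rescaling
that cannot alter merge order. Ward linkage minimizes the increase in
total within-cluster sum of squares (heights = √(2·ΔSSE), i.e. the
Euclidean distance for singleton merges); exact merge-cost ties are
resolved by the nearest-neighbor-chain order of the underlying scipy
implementation and have measure zero for continuous data. K-means uses
k-means++ with 10 restarts, 300 iterations, tol 1e-4; the inertia elbow
is reported as the full curve plus a distance-to-chord knee suggestion
(raw second-difference curvature systematically flags k=2 whenever the
first drop dominates). PCA component count uses Minka's MLE with a 95%
cumulative-variance fallback for degenerate spectra. The probe of each
cluster is the member with minimal Euclidean distance to the cluster
mean, ties broken by input order.

## Regression and validation

Features are the probe molecules' free energies per material; responses
are all remaining molecules. LR (OLS with intercept) and AdaBoost.R2
(50 depth-3 trees, linear loss, weighted-median prediction, seeded
weighted resampling) fit one model per response; the neural network is
a single joint multi-output perceptron (one hidden layer of 10 tanh
units, L2 α = 1e-4, Adam). NN optimizer settings are package choices:
step 1e-2 (at the conventional 1e-3 the 2000-epoch budget leaves
tens-of-kJ/mol unscaled targets far from convergence), max 2000 epochs,
tol 1e-6, non-convergence reported on the fitted model rather than
raised.

Validation uses shuffle-split: 10 independent random 70/30 material
splits (23 train / 10 test for 33 materials). R² and MAE are computed
per response molecule across the materials of each set; a split's
aggregate is the unweighted mean over response molecules, and reported
values are mean ± sd over splits. Pooling order (molecules first, then
splits) is fixed by convention since per-molecule and pooled residual
definitions differ; negative test R² values are retained. R² for a
constant truth vector is undefined and reported as NaN with a warning.
Per-split model seeds derive as seed + split index. The leakage-free
variant re-runs Ward clustering and probe selection on the training
materials' columns only, so held-out materials influence nothing.

## Material grouping

Materials are clustered by the same Ward engine on the transposed
matrix. The predicted-fingerprint matrix keeps probe rows bit-identical
and replaces every response row with model predictions from a model fit
on all materials. Agreement between measured- and predicted-fingerprint
groupings is quantified rather than judged visually: adjusted Rand
index between the k=3 cuts and Pearson correlation of cophenetic
distances.

## Problem sizes and determinism

Default study conditions are 32 molecules × 33 materials, 3 probe
molecules (optionally extended to 5 named extras), 10 splits; analysis
drivers and the acceptance script run these sizes directly and complete
in well under a minute each except the neural-network evaluation
(~20 s). All randomness flows through explicit integer seeds (generator
configs, split schemes, model specs); repeated runs with the same seed
are byte-identical.

## Known limitations

- The deposited 32×33 metadynamics matrix is not redistributable here;
  analyses against its published values require a user-supplied export
  (see `nanofp.datasets`) and the corresponding tests fail with
  instructions until it is present.
- The free-energy layer-placement convention (sliding δ-window at the
  PMF minimum) is one of two defensible readings; results for PMFs with
  a single dominant well are insensitive to it, multi-well profiles are
  not.
- AdaBoost per-response models derive their seeds as spec seed +
  response index; cross-library comparisons must account for this.
- The generator's independence assumptions (iid noise, additive
  offsets) make synthetic recovery easier than real-data recovery at
  equal contrast-to-noise ratio.
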
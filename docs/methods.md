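# Methods

This note records the scientific model implemented by `octaspin`, the
choices made where the design was genuinely open, and what the test suite
does and does not establish.

## Scope and data model

The domain is mononuclear octahedral complexes of Cr, Mn, Fe, Co (each
2+/3+) and Ni (2+), built from one equatorial and one axial ligand type:
four monodentate / two bidentate / one tetradentate ligand fill the
equatorial slot, two monodentate / one bidentate the axial slot, so every
valid complex has exactly six bound donor atoms. High/low spin
multiplicities are fixed per metal and oxidation state (quintet–singlet for
Fe²⁺ and Co³⁺, sextet–doublet for Mn²⁺ and Fe³⁺, quartet–doublet for Co²⁺
and Cr³⁺, quintet–triplet for Cr²⁺ and Mn³⁺, triplet–singlet for Ni²⁺).
The target convention is ΔE_H–L = E(high) − E(low): negative favors high
spin, and raising the exact-exchange fraction a_HF (sampled 0.00–0.30)
lowers ΔE_H–L roughly linearly.

Ligands are pure connectivity graphs — element-labelled atoms (hydrogens
stored but flagged non-heavy), fractional bond orders, metal-binding
"connecting" atoms, formal charge, denticity. No 3D information exists
anywhere in the package; this is a deliberate design constraint of the
descriptor set, not a simplification.

### The bundled ligand library

Fourteen of the sixteen ligands are fixed by the study design: chloride,
S-bound thiocyanate, phenyl isocyanide (pisc), methyl isocyanide (misc),
cyanide, carbonyl, N-bound isothiocyanate, ammonia, water, phenanthroline,
ethylenediamine, porphine (as the dianion), acetylacetonate and oxalate.
The full structures of the remaining two bidentates are only identified in
supplementary material we do not redistribute; they are encoded here as
2,2′-bipyridine and catecholate — common N,N and O,O chelates consistent
with the 9 monodentate / 6 bidentate / 1 tetradentate composition and the
Cl/S/C/N/O connecting-atom palette. This assumption does not affect any
descriptor extreme: the library-wide Kier maximum is set by porphine and
the electronegativity minimum by carbonyl regardless.

Isocyanides are encoded C-bound with a C≡N triple bond; thiocyanate is
S–C≡N when S-bound and N=C=S when N-bound; delocalized chelate backbones
(acac, oxalate, catecholate, aromatic rings) carry bond order 1.5.

## Descriptors

* **Δχ statistics.** For each connecting atom, Δχ = χ(connecting atom) −
  χ(bonded ligand atom) over all intra-ligand neighbours, hydrogens
  included, the metal excluded. The whole-complex max/min/sum pool these
  values over all six coordinated ligand copies (a hexacarbonyl sums six
  copies of the single C→O difference: 6 × (−0.89) = −5.34). Atomic
  ligands contribute empty sets; an all-atomic complex reports (0, 0, 0).
  Pauling electronegativities are shipped to two decimals (H 2.20, C 2.55,
  N 3.04, O 3.44, S 2.58, Cl 3.16, …) and frozen at runtime. The printed
  reference ranges for these descriptors were produced with an unstated
  electronegativity table and pooling convention and differ in the second
  decimal from ours (e.g. −5.30 vs −5.34 for the hexacarbonyl sum); we do
  not force agreement.
* **Truncated Kier index.** ²κ = (A−1)(A−2)²/(²P)², the second-order Kier
  shape index with its linear-alkane normalization, evaluated on the
  heavy-atom subgraph of atoms within three bonds of *any* connecting atom
  (distances measured on the full graph; the union over connecting atoms
  is required — porphine's four-nitrogen union reproduces the reference
  maximum of ≈ 6.96, a per-nitrogen average would not). ²P counts
  unordered length-2 paths; ligands with no such path score 0.
* **Bond order b.** Maximum order of any bond incident to a connecting
  atom; 0 for atomic ligands.
* **Descriptor-set ladder a–g.** Set a uses full ligand identity
  (16 levels per ligand class); b replaces it with connecting-atom element
  plus atom count; c adds max/min/sum Δχ; d drops the redundant min; e adds
  b; f swaps the size metrics for ²κ; g = f + b. Set g is the production
  space: 15 descriptors, 27 one-hot-encoded network inputs.
* **Encoding.** Continuous columns are z-scored by training-set statistics
  (frozen in an `EncodingMeta`; constant columns map to exactly 0);
  categoricals are one-per-level for the network and reference-coded for
  linear models (Co and O are the dropped references). Unseen levels raise
  rather than extrapolate silently.

## Training protocol

Two tanh hidden layers of 50 units, linear output. Loss: mean squared
error plus λ·Σ(‖W‖² + ‖b‖²) — the L2 penalty deliberately includes biases.
Data are shuffled once (seeded); the first 60% trains, the last 40% tests.
λ is selected on the training portion by 10-fold cross-validation over a
log grid 10⁻⁶–10⁻¹, scoring the full regularized loss on held-out folds,
then the network is retrained on the whole training portion. Dropout masks
(hidden layers only) are resampled per mini-batch; inference scales hidden
activations by the keep probability. The bond-length model is one network
with two outputs (min R_LS, min R_HS); two single-output networks can be
configured instead.

Numerical choices: fan-in-scaled uniform initialization; targets z-scored
internally; plain constant-rate SGD with gradient clipping at global norm
10; batch size 20. The reference protocol's learning rates (1.5/1.0) were
tuned inside a framework with its own internal scaling and diverge under
this parameterization; the package default is 0.1 (0.03–0.05 works well on
the synthetic conditions), exposed in `TrainConfig` alongside epochs
(default 2000) and every other protocol constant. Divergence (non-finite
loss) raises with advice to lower the rate.

## Uncertainty quantification

J = 100 dropout realizations at fixed weights give the predictive mean and
variance 1/τ + (second moment − mean²). The precision follows the
dropout-as-GP correspondence τ = p_keep·l²/(2Nλ). With p_drop = 0 the
realizations are degenerate and the variance is exactly 1/τ. The GP
length-scale l is chosen on a seeded 80/20 internal split of the training
portion by maximizing the Gaussian log predictive likelihood of the
held-out fifth; since the dropout spread is l-independent, the scan only
re-weights the baseline term, and the returned curve lets callers check
for grid-edge solutions. Note the reference work quotes a baseline
standard deviation of "approximately 1.5 kcal/mol" for τ = 0.6, whereas
1/√0.6 = 1.29; we implement the variance expression literally and report
the discrepancy rather than matching the rounded prose.

Reliability: Euclidean distance to the nearest training point in the
normalized (encoded) descriptor space, with queries beyond 1.0 flagged;
the uncentered Pearson (cosine-complement) distance is reported alongside.

## Classification tree and baselines

The "spectrochemical tree" is a greedy Gini-impurity binary tree over the
set-g encoding, at most 6 divisions and 10 points per leaf, pruned by
cost-complexity with a 1-SE rule on 10-fold cross-validated accuracy (the
reference analysis cites recursive-partitioning software without stating
its significance test; cost-complexity is the standard interpretation).
Leaves report majority class, purity and population share, and the tree
exports as text or DOT. KRR and SVR baselines use the square-exponential
kernel with grid-searched width and regularization under 10-fold CV and
the same 60/40 split convention as the network; SVR's ε-insensitive loss
has ε on the grid (unstated in the reference). scikit-learn stands behind
the tree, the baselines and the LASSO coordinate descent; independent
closed-form and exhaustive-enumeration oracles for each live in the tests.

## Synthetic data generator

The generator defines the study conditions for every test that needs data:

* per-connecting-atom field strengths (kcal/mol) ordered like the
  spectrochemical series (Cl 0.5 … NH₃ 5 … CN⁻ 15, CO 18), accumulated
  over the six donor atoms;
* sub-additivity via saturation S·tanh(field/S) with S = 95 kcal/mol,
  reproducing the diminishing per-ligand increments seen in chloride →
  isocyanide replacement series (setting S = ∞ recovers an exactly
  additive model, which the tests exploit);
* metal/oxidation baseline offsets (−42 kcal/mol for Mn²⁺ up to
  +15 kcal/mol for Co³⁺) chosen so splittings span roughly −55 to
  +90 kcal/mol;
* a linear a_HF response with slope −sens(metal)·(10 + 1.5·field)
  kcal/mol/HFX, spanning ≈ −13 (weak-field Cr³⁺) to ≈ −175 (hexacarbonyl
  Fe²⁺), sampled at the seven exchange fractions 0.00–0.30;
* bond lengths shrinking linearly with field about spin-state baselines
  (LS 1.98 Å, HS 2.18 Å);
* homoscedastic Gaussian noise, σ = 2 kcal/mol on splittings and 0.01 Å on
  bond lengths.

Complexes are drawn without replacement from the full valid enumeration,
and the ground-truth parameters are returned with the table so recovery
tests compare against the generating process, not against refit values.

What the generator does **not** emulate: heteroscedastic DFT convergence
noise, spin-contamination correlations with ligand charge, interligand
steric and hydrogen-bonding effects, or any systematic deviation from
linear exchange response. Passing the synthetic-recovery tests therefore
demonstrates that the estimators are correct and well-calibrated under the
stated statistical model, not that the real DFT dataset is predicted to a
given accuracy.

## Problem sizes used by the test suite

Oracle and identity checks run on toy problems (≤ 80 rows). Parameter
recovery uses 286 complexes × 7 exchange fractions (≈ 2000 splitting
observations) for the noise-floor check, 1000 rows for UQ calibration and
coverage, and 5005 rows for the generator moment checks; these sizes give
3-SE statistical headroom while keeping the default suite around half a
minute on one CPU.

## Reference (DFT) dataset checks

The desk-scale surface above never touches DFT data. Checks that quote the
published dataset's numbers (extremes +90.7/−54.2 kcal/mol, hexacarbonyl
iron slope ≈ −174 kcal/mol/HFX, test RMSE ≈ 3.1 kcal/mol, ≈ 98%
ground-state accuracy) activate only when `datasets/reference_dft.csv`
exists: a long-format CSV with columns `metal, oxidation, eq_ligand,
ax_ligand, a_hf, delta_e_hl, min_r_ls, min_r_hs, s2_deviation,
geometry_status`, one row per complex per exchange fraction, ligand names
matching the bundled library. The published supplementary archive must be
converted to this schema by hand (its exact layout is not machine-stable);
`octaspin qc` then reproduces the exclusion bookkeeping (spin
contamination > 1, dissociation, non-convergence) before training.

## Known limitations

* Connectivity-only descriptors ignore interligand effects (sterics,
  hydrogen bonds) and distortions; bond-length predictions are least
  reliable where those dominate.
* The exchange-sensitivity model assumes strict linearity in a_HF.
* The ligand-identity encoding of set a and the connecting-atom palette
  (Cl, S, C, N, O) hard-bound the vocabulary; novel donors require
  retraining, and the distance flag only warns — it does not correct.
* Two library ligands are plausible stand-ins for structures identified
  only in non-redistributed supplementary material (see above).
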
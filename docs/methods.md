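# Methods

## The model

`qtst` evaluates canonical gas-phase partition functions in the
rigid-rotor/harmonic-oscillator (RRHO) approximation,

    Q(T) = Q_el(T) · Q_trans(T) · Q_rot(T) · Q_vib(T),

and uses them directly in transition-state-theory (TST) rate constants

    k(T) = (k_B T / h) · (Q_TS / Q_R) · exp(−E_a / k_B T),

for unimolecular reactions, with E_a the ground-state electronic energy gap
between transition state and reactant. On top of the exact evaluator sit
three learned estimators. *Qest* regresses ln Q from a molecule's 3D
descriptor and 1/T; *QesTS* regresses ln Q_TS from the product-minus-reactant
descriptor, ln Q_R, ln Q_P and 1/T; *Double* composes them so that a
transition-state partition function — and hence a TST rate — needs no
transition-state geometry at all, only reactant and product structures plus
an activation energy.

All arithmetic is on the natural-log scale: over 50–2000 K, ln Q spans
several hundred log units (the vibrational zero-point factor dominates at
low T), so linear-scale products would overflow immediately.

### Term conventions

* **Electronic** — the spin multiplicity only; excited electronic states are
  ignored (closed-shell organics).
* **Translational** — `(2π m k_B T / h²)^{3/2} · V` with the ideal-gas
  volume `V = k_B T / p°`, `p° = 1 bar` by default and configurable. The
  volume convention shifts every ln Q by the same constant and cancels in
  the unimolecular ratio Q_TS/Q_R, but learned models inherit whatever
  convention their training data used, so it is recorded prominently here
  and in every saved model bundle.
* **Rotational** — classical rigid rotor: 0 for monatomics,
  `T/(σ θ_rot)` for linear species, `(√π/σ)·√(T³/(θ_A θ_B θ_C))` otherwise,
  with `θ = ħ²/(2 I k_B)` from the principal moments of the center-of-mass
  inertia tensor. The classical form differs from the quantum level sum by
  O(θ/3T); this matters below (oracle design).
* **Vibrational** — per harmonic mode with `x = hcν/k_B T`:
  `−x/2 − ln(1 − e^{−x})`. The zero-point energy lives **inside** Q_vib
  (not in E_a), so ln Q_vib is typically negative; this matches the
  convention that both Q_TS and Q_R "include the zero-point contribution"
  while E_a is a bare electronic energy difference.

### Symmetry numbers

σ counts the proper rotations mapping the molecule onto itself. Candidate
orthogonal operations are generated from the principal inertia axes plus
axes through atoms, atom-pair midpoints and atom-pair difference vectors:
proper rotations C_k and improper rotations S_k of orders 2–6, reflections,
and the inversion. An operation is kept when it permutes the element-labeled,
center-of-mass-centered point set within a matching tolerance (default
0.05 Å); σ is the number of survivors with determinant +1. Matrices are
deduplicated after rounding (with −0.0 collapsed onto 0.0 — omitting that
double-counts reflections).

Linear molecules are decided geometrically rather than by operation
counting: the point group of a linear rotor is continuous, and the
perpendicular C₂ of a centrosymmetric linear molecule is indistinguishable
from an improper reflection when acting on collinear nuclei. A linear
species gets σ = 2 exactly when its atom pattern is symmetric about the
center, else σ = 1. Monatomics get σ = 1.

Tolerance handling is deliberately non-adaptive: σ is computed at the given
tolerance only, so noisy geometries straddling the threshold give a
deterministic (if conservative) answer.

## Dataset assembly

Each reaction contributes its reactant, transition state and product at a
per-reaction set of temperatures drawn uniformly in 1/T over (50, 2000) K
(default 50 per reaction), so every reaction sees a unique temperature grid.
Per-reaction seeds are derived from a master seed by SHA-256, which keeps
the stream stable across platforms and insertion orders.

Hold-out (10%) and 5-fold splitting group reactions by the Bemis–Murcko
scaffold of the reactant. Scaffolds are computed by perceiving bonds from
covalent-radius distance cutoffs (factor 1.2) — geometry is all a transition
state has; bond orders are undefined for it — then deleting hydrogens and
iteratively deleting terminal heavy atoms until only rings and linkers
remain, rendered as canonical SMILES. Acyclic molecules share the empty
scaffold and therefore form a single (large) split group. Whole groups are
assigned largest-first to the hold-out until it reaches the target fraction,
then distributed over folds smallest-fold-first, so no scaffold ever crosses
a split boundary. An optional quantile envelope on ln Q (default
0.05–99.95%) drops extreme rows to limit extrapolation, reporting removals
per role.

## Featurization and scaling

The encoded-bond descriptor is a smoothed interatomic-distance histogram:
one channel per unordered element pair over the vocabulary {H, C, N, O},
each channel a grid of 32 Gaussian kernels (width 0.2 Å) spanning 0–6 Å.
It is invariant to rotation, translation and atom order, and has fixed
length (320) regardless of molecular size. These hyperparameters are
defaults recorded in every model bundle, not tuned constants.

Qest inputs are min–max scaled; QesTS inputs are left unstandardized (the
difference descriptor is already peaked around zero); targets for both are
z-scored and exactly de-standardized at prediction time. One numerical
guard matters: descriptor dimensions whose development-set span is below
10⁻³ of the largest span are treated as constant and mapped to 0. Kernel
tails give spans of order 10⁻²⁰, and dividing unseen scaffolds' values by
them amplified inputs by up to ~10¹⁸, which destroyed any network
downstream.

## Networks

Both estimators are dense feed-forward regressors (scikit-learn fit; saved
bundles carry the raw weight matrices and predictions are a plain forward
pass, so a reloaded bundle is bit-identical). Defaults: two hidden layers of
128 tanh units, L2 strength 10⁻³, Adam at learning rate 10⁻³, up to 600
epochs, batch 128, fixed seed, mean-squared-error loss on the normalized
targets, MAE reported in log-Q units and as percent of the evaluated
targets' standard deviation (so a mean-predicting baseline scores
√(2/π) ≈ 79.8%).

The width/regularization choice is a deliberate fit to the desk-scale
regime this package trains in (hundreds of distinct structures): larger,
weakly regularized networks memorize the development set and fail
whole-scaffold hold-outs outright, while this configuration tracks the
performance of the best linear recovery on the planted tasks. Anyone
training on a dataset of tens of thousands of structures should expect to
re-tune width, regularization and schedule; every knob is exposed in
`NetworkSpec` and recorded in the bundle manifest.

Training enforces the split as a hard contract: any row whose reaction id
belongs to the hold-out aborts fitting with a leakage error.

## Synthetic fixtures and what they do (not) show

The generator produces reactions at the reference-dataset conditions —
C/H/N/O molecules with at most 7 heavy atoms, 3N−6 positive harmonic
wavenumbers in 200–3500 cm⁻¹ (transition states: reactant modes with one
replaced by an imaginary mode of 400–2000i cm⁻¹), activation energies of
0.01–0.12 hartree, 50 temperatures per reaction uniform in 1/T over
(50, 2000) K. Reactants are rings (sizes 3–6, random N/O substitution,
jittered scale, out-of-plane pucker, 0–2 exocyclic heavy atoms) or short
chains; products are coordinate perturbations of the reactant and the
transition state is their midpoint. Two properties are engineered, not
accidental:

* **Descriptor-space overlap across scaffolds.** Every element-pair channel
  is populated by many different scaffold groups (continuous jitter, random
  substitution, chains built with the same bond geometry as rings). Without
  this, a held-out scaffold group is out of distribution by construction
  and no estimator — including an exact linear one — can recover a planted
  map on it.
* **Identifiable planted targets.** Recovery experiments plant
  ln Q = a·z(structure) + m·(1/T) + b with z a smooth per-channel quadratic
  functional of pair distances, i.e. (to kernel accuracy) a low-frequency
  linear map of the descriptor. A raw random per-center weight vector is
  *not* identifiable from desk-scale data under scaffold hold-out — ridge
  regression, the exactly matched model class, fails on it — so failure to
  recover it would measure fixture sparsity, not estimator quality.

What the fixtures do **not** emulate: real potential-energy surfaces,
bond-order chemistry, real vibrational spectra (modes are i.i.d. uniform),
conformational ensembles, or any correlation between geometry and energy.
Passing tests therefore demonstrate that the pipeline's statistics,
plumbing, invariances and learning machinery are correct, not that the
estimators reach any particular accuracy on ab initio data.

## Oracles and numerical choices

* The independent check on the closed forms is a brute-force state sum:
  vibrational levels summed to v_max per mode and rotational levels
  `Σ_J (2J+1) e^{−θJ(J+1)/T}/σ` to j_max for linear species, in log space
  via logsumexp, with a hard error if the last term exceeds 10⁻¹² of its
  sum. The vibrational geometric series matches the closed form exactly, so
  the only physical gap is rotational: classical vs quantum differs by
  ~θ/3T. Toy rotors for these comparisons are drawn long and heavy
  (I ≥ 180 amu Å², θ ≲ 0.14 K) so that at 100 K the physical gap
  (≲ 5×10⁻⁴ in ln Q) sits below the 10⁻³ comparison threshold and the test
  isolates implementation error. Measured worst disagreement: ~4×10⁻⁴.
* Linearity is declared when I_min/I_max < 10⁻⁴; modes with |ν| < 1 cm⁻¹
  are dropped as spurious; both thresholds are configurable and chosen
  conservatively for DFT-quality Hessians (the source data's cutoffs are
  unknown).
* Activation energies require an explicit unit tag (hartree, kJ/mol or J);
  silent unit guessing is refused.
* Atomic masses are standard isotope-averaged weights (natural-abundance
  organics).

## Problem sizes

Default test-time sizes: 200 reactions × 10 temperatures for estimator
recovery (≈6000 rows, ≈600 distinct structures), 500 reactions for split
integrity, 10⁵ draws for temperature-sampling statistics, 20 toy rotors × 3
temperatures for the oracle comparison. These were chosen as the smallest
sets at which the respective statistics are stable.

## Known limitations

* Anharmonicity, hindered rotors, tunneling and variational TST are out of
  scope; Eq. (1)/Eq. (2) conventions only.
* Multi-fragment products are treated as single structures, mirroring the
  source data's convention.
* Only the given local minimum per species is considered; no conformer
  averaging.
* The symmetry detector targets small organics; very high-order axes (>6)
  would need the candidate-order list extended.
* Scaffold keys from geometry use single-bond frameworks, so aromatic and
  saturated rings of the same size and composition share a key — acceptable
  for leakage prevention, not for cheminformatics reporting.
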
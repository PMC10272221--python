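# Methods

## Model

`gdmlreduce` implements a gradient-domain kernel force field: kernel ridge
regression trained directly on forces, so that the predicted force field is
by construction the negative gradient of a latent energy surface. The
descriptor of an N-atom geometry is the vector of inverse interatomic
distances 1/r_ij over all N(N−1)/2 atom pairs (a simplified Coulomb matrix
without nuclear-charge weighting), ordered lexicographically in the 0-based
pair (i, j). No permutational symmetrization is applied, and no cutoff or
switching functions — features are raw 1/r.

The kernel is Matérn ν=5/2 on descriptor-space Euclidean distance,
k(d) = (1 + u + u²/3)e^{−u} with u = √5·d/σ. It is exactly twice
continuously differentiable — the minimum smoothness for a force-force
(Hessian) kernel — while avoiding the pathological smoothness of a Gaussian
kernel at small length scales. Its descriptor-space cross Hessian has the
closed rank-1-plus-identity form

    ∇_x ∇_{x'}ᵀ k = −g1(d)·I − c2(d)·δδᵀ,   δ = x − x',

with g1 = −(5/3σ²)(1+u)e^{−u} and c2 = (25/3σ⁴)e^{−u}, both smooth at
d = 0. All kernel assembly, prediction, and per-feature masking exploit
this structure; nothing ever forms a dense feature-space Hessian outside of
test oracles. Cartesian blocks follow by the chain rule through the
analytic descriptor Jacobian, whose row for pair (i, j) is
∂(1/r_ij)/∂r_i = −(r_i − r_j)/r_ij³ in the atom-i columns and its exact
negative in the atom-j columns.

Training solves the dense regularized system (K + λ s̄ I)α = y by Cholesky
factorization, where y stacks the reference forces and s̄ is the mean
diagonal of K (so λ is dimensionless). This direct solve is intentional:
at desk scale (M·3N ≲ 15 000) it is exact, simple, and fast; iterative or
inducing-point solvers are out of scope. At λ = 0 a singular system falls
back to a minimum-norm least-squares solution and raises a conditioning
error only if the system is inconsistent — this keeps the one-training-point
edge case exact while still diagnosing genuinely unsolvable systems.

Energies enter training only through a single offset constant, fit so the
mean predicted energy over the training set matches the mean reference
energy. The energy predictor shares the kernel-derivative code path with
the force predictor, so F̂ = −∇Ê is an analytic identity, verified by
central differences in the tests to 1e-6 relative.

### Hyperparameters

| parameter | default | units | rationale |
|---|---|---|---|
| σ (length scale) | median pairwise descriptor distance of the training set | Å⁻¹ (descriptor units) | deterministic, scale-adaptive; a validation grid search (`select_sigma`, ties → smaller σ) is available when the budget allows |
| λ (regularization) | 1e-10 | — | middle of the standard tested range 1e-8…1e-12; scaled by the mean kernel diagonal for unit consistency |

After feature reduction σ is re-selected by default (descriptor-space
distances shrink when coordinates are dropped); `sigma="keep"` provides the
strict-ablation alternative, used by the no-op-reduction equivalence test.

## Descriptor reduction

Feature importance is the masking loss: with model coefficients, σ, and λ
frozen, feature n is set to zero for all configurations and the squared
force-prediction change is accumulated over a test set. Masking is applied
to both the descriptor value and the gradient (Jacobian-row) channel by
default; a `value_only` mode masks the kernel distance alone, since which
of the two a "zeroed feature" means is a genuine modeling choice — the
both-channels reading is the default because the reused coefficients
multiply kernel gradients, and a feature absent from the similarity measure
should not retain a gradient channel. The loss is computed on forces only
(the model's native prediction); energies are derived quantities here.

Masked predictions are computed exactly by rank-1 updates of the prediction
formula at O(M·3N) per feature and configuration, rather than re-evaluating
the full kernel sum per masked feature; the test suite checks this against
a literal rebuild-the-masked-descriptor implementation to 1e-10.

Percentile truncation uses the nearest-rank floor convention: exactly
⌊p/100·n⌋ features with the smallest L_n are removed, ties broken by
ascending feature index. This convention reproduces the canonical worked
counts (1062 of 1770 at the 60th percentile; 559 of 861 at the 65th). A
known worked example of 32 removed from 210 at the 15th percentile is
inconsistent with any fixed rounding rule that also reproduces the other
two counts (floor gives 31); the floor convention is fixed and that case is
excluded from the tests.

The local-cutoff baseline mask removes every pair that exceeds the cutoff
(default 5 Å) in *at least one* configuration of the dataset — the strict
reading; the short/long-range decomposition supports both the max-distance
and the mean-distance criterion, since both conventions are in circulation.

## Interaction and feature analyses

Because the predictor is linear in the coefficients, two exact partitions
exist and are asserted to 1e-10 in the tests:

* **by training atom** — restricting the coefficient sum to the three
  Cartesian components of atom k (0-based component indices 3k…3k+2) gives
  F^k, the contribution of atom k to the force on every atom. The
  interaction map averages the per-atom-pair norms over configurations and
  normalizes as t = log(F̄ + ε), ε = 1e-12·max(F̄), mapped min–max to
  [0, 1]; the ε-shift tolerates exact zeros from masked channels. The map
  is not symmetric by construction and is not asserted to be.
* **by query descriptor feature** — the predicted force is J_xᵀw, so
  channel n contributes w_n·J_x[n,:]. The per-feature contribution is the
  configuration-averaged channel norm. This chain-rule definition was an
  open interpretive choice; it is used because it partitions the prediction
  exactly and inherits the 1/r² Jacobian scaling that makes Coulombic-like
  features appear with log–log slope ≈ −2.

Feature classification fits log(contribution) on log(distance) by ordinary
least squares per feature; r² ≥ 0.9 labels a feature "linear", otherwise
"stochastic"; features with fewer than three positive samples are skipped
with a warning. The scaling analysis fits kept-feature counts against atom
counts and reports the coefficient of determination of the same points
against the quadratic n(n−1)/2 for comparison.

The gyration radius supports unit weights (default) and standard atomic
masses, as the appropriate weighting for compactness analyses is
convention-dependent.

## Synthetic data

The toy potential emulates the statistical structure of thermal ab-initio
datasets for flexible molecules: stiff short-range bonded terms and soft
long-range nonbonded interactions with exact analytic forces.

* bonds: harmonic, r0 = 1.5 Å, k = 300 kcal mol⁻¹ Å⁻² (C–C-like);
* angles: harmonic in θ, θ0 = 109.5°, k = 60 kcal mol⁻¹ rad⁻²;
* dihedrals: A(1 + cos 3φ), A = 1.2 kcal mol⁻¹;
* Lennard-Jones: ε = 0.1 kcal mol⁻¹, σ_LJ = 3.4 Å on all pairs beyond the
  1-2 and 1-3 exclusions;
* screened Coulomb: 332.06·q_iq_j·e^{−r/ℓ}/r kcal mol⁻¹, alternating
  partial charges ±0.25 e with a seeded ±20% jitter (so no two beads are
  exactly equivalent), screening length ℓ = 10 Å — long-ranged on the
  molecular scale without being formally infinite-ranged.

Chains are peptide/fatty-acid analogues, rings closed chains, dimers two
covalent fragments bound only by nonbonded terms (base-pair/host–guest
analogues). Beads are carbon-mass particles. These values were chosen once
as a physically reasonable bead-molecule parameterization: bond and angle
stiffness in the range of single-bond force constants, torsion barriers of
a few kT at 300 K so dihedrals actually flip during sampling, and
nonbonded couplings strong enough that long-range features carry signal.

What the generator does *not* emulate: chemical diversity of elements,
anharmonic bond profiles, polarization/many-body dispersion, hydrogen-like
fast degrees of freedom, conical or reactive regions. Passing tests
therefore demonstrate the correctness and internal consistency of the
method — exact oracles, partitions, stability, and the
reduction-preserves-accuracy phenomenology on a redundant global
descriptor — not transferability to real ab-initio data.

Datasets are sampled with BAOAB Langevin dynamics at the target temperature
(default 300 K, friction 0.02 fs⁻¹, dt 0.5 fs), discarding a 2000-step
equilibration segment and keeping every 10th step; labels are evaluated
analytically on the kept frames, so they are noise-free.

## Molecular dynamics

Velocity-Verlet (NVE) and BAOAB-splitting Langevin integrators, canonical
units Å / fs / amu / kcal mol⁻¹ (acceleration bridge: 4.184e-4 Å fs⁻²
per kcal mol⁻¹ Å⁻¹ amu⁻¹). Initial velocities are Maxwell–Boltzmann at the
stated temperature unless zeroed. Steered runs add a constant force of
equal magnitude and opposite sign to two chosen atoms along their
connecting line, re-evaluated every step (a fixed-axis mode is available);
the pN-to-internal conversion is computed from CODATA values
(1 kcal mol⁻¹ Å⁻¹ ≈ 69.477 pN). The magnitude applies per atom; a
`pull_shared` flag halves it. Instability detection flags any nonbonded
pair closer than 0.7 Å (steric clash) and any bond stretched beyond 2.5×
its equilibrium length (fragmentation), time-stamped per sampled frame.

## Problem sizes used in the validation suite

The heavy checks run at desk scale, chosen to exercise the phenomenology
on one CPU: the accuracy-preservation experiment uses a 20-bead chain
(190 features), M = 100 training points, 200 test configurations, and five
seeds; the scaling experiment chains of 10/16/24/32 beads at the 60th
percentile; the stability experiment a 10-bead chain with 100 ps of
Langevin dynamics driven by the p=50-reduced model (dt = 1 fs, five
seeds); the steered comparison 10 ps runs at 300 pN, where the pulled
trajectory's late-window mean gyration radius exceeds its seed-paired
control systematically (+0.014 Å — small because the free chain is already
near-extended at 300 K, but strictly positive in every paired seed). NVE
energy drift on the analytic surface is below 1e-3 kcal mol⁻¹ per ps by a
large margin (measured ≈ 5e-8).

## Known limitations

* Dense kernel algebra bounds training to M·3N of a few thousand;
  evaluation cost grows linearly with M and with the active feature count.
* Masking assumes separability between features; correlated groups of
  features are scored independently (grouped selection is out of scope).
* At a fixed percentile the kept-feature count is a fixed fraction of the
  quadratic global size; the approach to truly linear scaling arises from
  choosing deeper reduction for larger molecules, which the scaling
  experiment only approximates over a narrow size range.
* No periodic boundaries, no uncertainty estimates, no GPU path.
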
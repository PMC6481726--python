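# Methods

This note documents the models, numerical choices and limitations behind
`ecgipoly`: what the synthetic torso–heart simulator does and does not
emulate, how the polynomial inverse network relates to classical linear
inversion, and how training is carried out.

## The inverse problem

Quasi-static volume conduction makes the heart-to-torso forward map linear:
`U_T = F U_A`, with `U_A` the endocardial potentials (mV) on `m` catheter
poles and `U_T` the body-surface potentials on `n` torso leads. `F` is
smooth and strongly smoothing — high-spatial-frequency patterns on the heart
surface are heavily attenuated at the torso — so its inversion is ill posed
and must be regularised. The classical baseline implemented in
`ecgipoly.linear` is zero-order Tikhonov, `(FᵀF + λI)⁻¹Fᵀ U_T`, solved by
Cholesky factorisation of the regularised normal matrix (one factorisation
shared by all time samples); `λ = 0` falls back to a minimum-norm
least-squares solve with a rank-deficiency warning. λ is a configuration
input: no automatic L-curve selection is attempted, because the trainable
model replaces that tuning problem.

## From matrix series to polynomial network

For an invertible `n × n` matrix, Cayley–Hamilton gives the inverse as a
degree-`(n−1)` polynomial in the matrix, with coefficients obtained from the
power sums `s_k = tr(Aᵏ)` through Newton's identities
(`ecgipoly.series`). Two numerical choices:

- Coefficients are computed by the complete-Bell-polynomial recurrence on
  the signed, factorial-scaled power sums (O(n²), no symbolic algebra); an
  independent Faddeev–LeVerrier recursion serves as the test oracle,
  including for the alternating signs.
- A matrix counts as singular when `|det| ≤ 1e-12 · max(|s₁|/n, 1)ⁿ` — the
  floor is relative to the mean-eigenvalue scale so it behaves sensibly for
  matrices far from unit scale. The error raised carries the computed
  determinant.

Truncating the series keeps its `p+1` highest-order terms
(`A^{n−1} … A^{n−p−1}`) with the `(−1)^{n−1}/det` prefactor retained. Note
that the truncation error is *not* monotone in `p`: partial sums of an
alternating series can transiently cancel better than longer ones, and a
brute-force sweep confirms non-monotonicity for generic SPD matrices. The
guarantees are that `p = n−1` is exact and no truncation beats it.

The trainable model (`ecgipoly.polynet`) generalises this truncated series
to non-square maps by absorbing the scalar coefficients and the determinant
into free per-channel weights:

    Û_A[:, t] = Σ_{k=0}^{p} ω_k ⊙ (M U_T[:, t])^{⊙k},

with element-wise (Schur) products and powers, `z^{⊙0} = 1` so `ω_0` is a
per-channel bias, and default degree `p = 3`. Index convention: the linear
map sits at `ω_1 = 1` (all other weights zero) — a degree-0 network is a
constant, which is why `init_linear` rejects `p = 0`. Element-wise powers
are computed by iterated multiplication, which is sign-correct for negative
potentials at the small degrees used. The model is applied independently
per time sample and is therefore time invariant by construction. No
multi-layer composition or cross-channel polynomial terms are provided: the
nonlinearity is strictly element-wise in the transformed input.

## Training

Parameters (`M` and, by default, all `ω_k`) minimise

    E = mean_t ‖Û_A(t) − U_A(t)‖² + λ_S · mean_t Σ_ij |J(t)_ij|^s,

where `J(t) = ∇_{U_T} Û_A` is the input Jacobian. For this model
`J = diag(g) M` with `g_i = Σ_k k ω_k[i] z_i^{k−1}`, so the penalty
factorises as `Σ_i |g_i|^s · Σ_j |M_ij|^s` and costs no more than a forward
pass. The penalty bounds the roughness of the inverse map with respect to
its *input* — a Sobolev-type surrogate for output-side Tikhonov/TV
regularisation — and is applied only during training, never at
reconstruction time.

Choices and defaults, all exposed in `TrainConfig`:

- **Sobolev exponent** `s = 2` (smooth gradients); `s ≥ 1` supported.
- **Penalty weight** `λ_S = 1e-3`, interpreted relative to the data term at
  the starting point (resolved once to an absolute weight, then fixed), so
  the penalty starts subdominant regardless of data scale. Absolute mode
  and sum-over-samples reduction are toggles.
- **Optimiser**: plain gradient descent with a discrete line search. The
  analytic gradient (validated against central finite differences at 1e-5
  relative) is normalised to unit max-abs; candidates
  `θ + γ · scale · direction` are evaluated for
  `γ ∈ {0, ±0.1, ±0.5, ±1}` and the best kept. Since `γ = 0` is always a
  candidate, the objective trace is non-increasing by construction. Ties
  prefer the smallest `|γ|`.
- **Step scale**: starts at 1, halves when `γ = 0` wins twice consecutively
  and doubles when the largest trial magnitude wins. The growth rule is
  essential in practice: with a shrink-only rule a badly scaled start wastes
  hundreds of iterations re-fitting the scale (measured on a 54/64-lead
  linear problem: objective 659 → 201 in 400 iterations without growth
  versus 659 → 2.6 in 10 iterations with it).
- **Stopping**: fixed iteration budget (default 200) plus early stop after
  10 consecutive `γ = 0` wins or a null gradient; NaN objectives abort with
  a diagnostic.
- **Protocol**: train/test sets are disjoint random subsets of time samples
  (default 70/30, seeded); `round(fraction · T)` samples train.

A train-time polynomial degree distinct from the deployment degree is *not*
implemented; one degree serves both phases.

## Synthetic data

`ecgipoly.geometry` emulates a clinical AF mapping session: 54 torso ECG
leads and a 64-pole basket catheter recording simultaneously for 7.4 s at
2035.5 Hz (defaults), referenced to a common-mode average. Components:

- **Geometry**: concentric ellipsoids at anatomical scale (torso semi-axes
  200×150×300 mm, heart 50×50×60 mm), triangulated from subdivided
  icosahedra; electrodes placed by a deterministic Fibonacci lattice mapped
  to each surface.
- **Forward kernel**: infinite-homogeneous-medium point source,
  `F_ij = 1/(4πσ r_ij)` with σ = 0.2 S/m — it preserves the linearity and
  distance decay of the true operator in closed form. No boundary-element
  assembly, no imaging-derived anatomy: patient-specific geometry is out of
  scope.
- **Sources**: per channel, a dominant sinusoid (5 Hz — a literature-typical
  AF dominant rate, not fitted to any dataset) plus 3 harmonics with
  amplitude decaying as `1/(h+1)²`, a 0.15 Hz baseline drift (0.2 mV), a
  seeded ±25% per-channel amplitude jitter around 1 mV, and per-channel
  phases proportional to the electrode's projection on a seeded propagation
  direction (a travelling-wave surrogate for activation spread).
- **Measurement model**: `U_T = ref(sat(F U_A) + ε)`, with element-wise
  saturation `(1−g)x + g·c·tanh(x/c)` (unit slope at the origin; gain
  `g = 0.3` and scale `c = 10 mV` by default; `g = 0` is exactly linear),
  Gaussian sensor noise (sd 0.05 mV), and optional common-mode subtraction
  per time sample. The saturation supplies the forward-model mismatch that
  a nonlinear inverse can exploit; the common-mode reference emulates
  central-terminal referencing.
- **Determinism**: one seed feeds separate source and noise streams;
  identical configurations are bitwise reproducible.

What this generator does *not* capture: realistic cellular
electrophysiology (no reaction–diffusion dynamics), tissue inhomogeneity,
electrode contact artefacts, respiration/motion, or broadband AF
disorganisation — its sources live in a low-dimensional harmonic subspace.
Passing tests therefore demonstrate the correctness and relative behaviour
of the algorithms under a controlled, physically scaled model, not clinical
reconstruction accuracy.

## Evaluation

Errors follow the per-sample convention: `e[k] = |U[k] − Û[k]|` pooled over
all channel–sample pairs, reported as mean ± population standard deviation
(mV); relative errors `|U−Û|/|U|·100` exclude reference samples with
`|U| ≤ 1e-9 mV` ("effectively zero") and report the exclusion count.
Pooled-over-samples averaging (rather than per-channel-then-time) is used
throughout. The normalised variant divides every channel of each recording
by its own max-abs level (RMS optional), measuring waveform-shape fidelity
independent of scale. Note the pooled relative error is heavy-tailed: near
zero crossings of the reference, even small absolute errors produce large
ratios, so relative errors well above the RMS-level error are expected for
zero-mean oscillatory signals.

## Problem sizes used in tests and the acceptance script

Simulation studies run at reduced record lengths chosen to keep the full
loop desk-sized while leaving ample samples per parameter: the
baseline-vs-network comparison uses 54/64 leads, 3 s at 500 Hz (1500
samples, 1050 training) over 5 seeds with 200 training iterations; the
linear recovery experiment uses 12/8 leads, 2 s at 200 Hz, single harmonic;
monotone-descent checks run on the full 7.4 s / 2035.5 Hz default. The
54/64 noiseless linear recovery experiment is also exercised at 2 s /
500 Hz with 2500 iterations; on that instance the source subspace seen
through the smoothing kernel has a Gram condition number of ~7×10⁶, and
first-order descent leaves a residual relative error of ~9% — an instance
of the intrinsic ill-posedness discussed above rather than an
implementation limit; the well-conditioned instance recovers to <0.2%.

## Known limitations

- The optimiser is deliberately first-order; on severely ill-conditioned
  linear subproblems it converges slowly (see above). Momentum or
  second-order steps are out of scope by design.
- `M` is dense; no sparse or structured specialisations.
- The normalised-error convention (per-channel max-abs) is one of several
  in use; comparability with normalised figures computed under other
  conventions is not guaranteed.
- Spectral-accuracy metrics are not implemented; low-amplitude
  high-frequency transients are known to be smoothed by time-invariant
  sample-wise models of this kind.
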
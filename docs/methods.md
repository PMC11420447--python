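# Methods

`leuplat` couples two lattice models of juxtacrine cell decision-making and
the analysis machinery that maps one onto the other: a mechanistic
Notch-Delta-Jagged (NDJ) signaling simulator, a phenomenological
entropy-driven phenotype simulator, microenvironmental-uncertainty
observables, an estimator for the sensitivity parameter β, and pattern
statistics.  This note records the models, the parameter choices, the
numerical decisions, and what the synthetic test conditions do and do not
establish about real tissues.

## Lattice geometry

All dynamics run on a rows × cols square lattice with periodic boundaries.
Interactions use the Moore neighborhood of Chebyshev radius r: the
(2r+1)² − 1 cells within distance r, or (2r+1)² when the focal cell belongs
to its own sample.  The wrap constraint r < min(rows, cols)/2 is enforced
with a hard error so a wrapped neighborhood can never double-count a cell.
Aggregation (mean / sum / population variance) is implemented with a
separable wrapped box filter, which is O(1) in r and agrees with explicit
neighbor enumeration to floating-point rounding.

Two neighborhood conventions coexist deliberately:

* the **entropic-force sample includes the focal cell** (the entropy of a
  cell's microenvironment must depend on its own phenotype for the gradient
  to be nonzero), while
* the **local-variance metric excludes it** (the microenvironment of cell n
  is defined as its neighbors).

Each follows its defining expression; tests pin both against brute-force
enumeration.

## Notch-Delta-Jagged model

Per cell, four species: Notch receptor N, ligands Delta D and Jagged J, and
NICD I (the cleaved intracellular signal, used as the cell's phenotype
readout).  Shifted Hill factors Hs(I) = (1 + λ(I/I0)ⁿ)/(1 + (I/I0)ⁿ)
implement NICD feedback: activation of Notch and Jagged (λN = λJ = 2),
complete shutdown of Delta (λD = 0).  Trans-activation by neighboring
cells' ligands at rate kT releases NICD; cis-inhibition at rate kC removes
receptor-ligand pairs in the same cell without signaling:

    dN/dt = N0 Hs+(I) − kC N (D + J) − kT N (Dext + Jext) − γ N
    dD/dt = D0 Hs−(I) − kC N D − kT D Next − γ D
    dJ/dt = J0 Hs+(I) − kC N J − kT J Next − γ J
    dI/dt = kT N (Dext + Jext) − γI I

Defaults (molecules and hours): N0 = 1400, γ = 0.1, γI = 0.5, kT = 5×10⁻⁵,
kC = 5×10⁻⁴, I0 = 200, (nN, nD, nJ) = (2, 2, 5).  D0 and J0 are the swept
control parameters (plausible ranges D0 ∈ [500, 2000], J0 ∈ [200, 1300]; the
phase-diagram analyses sweep the square [500, 2000]²).  Delta-dominated
parameters produce lateral inhibition (checkerboard NICD patterns, e.g.
(D0, J0) = (1600, 700)); Jagged-dominated parameters produce lateral
induction (a uniform hybrid fate).

**External levels.** Next/Dext/Jext are the neighbor **means** over the
focal-exclusive Moore r = 1 neighborhood — a per-contact share that keeps
the trans terms on the same molecular scale for any radius.  A `sum`
convention is exposed (`NDJParams.ext_stat`); with the default rates it
saturates the NICD feedback and abolishes patterning, so `mean` is the
default.

**Integration.** Explicit forward Euler at dt = 0.01 for 30000 steps
(T = 300), with optional early stopping once the maximum relative change
per step falls below 10⁻⁶.  The ODEs preserve positivity, but an Euler step
can overshoot zero near hard shutdowns; such components are clamped to 0
and the event logged once.  Non-finite values abort with the offending step
named.  Initial conditions draw every species i.i.d. uniform on [0, 2000]
per cell (no distribution is canonical here; uniform over the plausible
molecular range is the least informative choice), seed-controlled.

**Quasi-steady-state NICD.** Because γI ≫ γ, I relaxes onto
I = (kT/γI) N Lext.  The reduced analysis below relies on this; at a
converged lattice the integrated I field matches the manifold to the
convergence tolerance (tested at 10⁻³ relative).

## Entropy-driven phenotype model

Each cell carries a scalar phenotype X ∈ [−1, 1].  With the Gaussian
microenvironment assumption, the entropy of cell n's neighborhood sample is
S_n = ½ ln(2πe σ_n²), and the phenotype follows an overdamped Langevin
equation

    dX_n/dt = −β ∂S_n/∂X_n + ξ_n,   ⟨ξ ξ'⟩ = 2D δ,

whose drift has the closed form (X_n − μ_n)/(N σ_n²) over the
focal-inclusive sample of N = (2r+1)² cells.  β > 0 descends the entropy
gradient (consensus, induction-like), β < 0 ascends it (diversification,
inhibition-like).  A property test pins the closed form to central finite
differences of S_n at 10⁻⁶ relative error.

Choices:

* **Noise default D = 0** — the perfect-sensor, zero-noise limit used for
  all regime analyses; the noise term is fully implemented (D = 0.5
  corresponds to unit-variance ξ) for studying decision stochasticity.
* **Hard clipping at ±1**, not reflection: clipping is what pins the
  multimodal peaks exactly at −1, 0, +1.
* **Variance floor 10⁻¹²** with force → 0, removing the 0/0 of a locally
  uniform neighborhood.
* **Initial condition** i.i.d. uniform on [−1, 1], seed-controlled.
* Euler-Maruyama at dt = 0.01 for 5000 steps (T = 50) by default.

**Stability of the stiff collapse regime.** The drift stiffness is
k = β/(N σ²); the explicit update multiplies deviations from the local mean
by (1 − dt·k), so stability requires dt < 2Nσ²/β
(`leup.stability_bound_dt`).  For strongly positive β the variance collapse
itself drives σ² below the bound and the steady ⟨σ²⟩_L freezes at an
integrator floor ≈ dt·β/(2N) instead of collapsing further.  Runs that must
resolve the collapse (e.g. β = +100 at r = 1) therefore use a step
comfortably below the bound at the target variance (dt = 5×10⁻⁴ for the
10%-collapse analyses); a property test documents that the floor shrinks
with dt.  The β ≤ 0 regimes are not stiff and use the default step.

## Microenvironmental uncertainty observables

⟨σ²⟩_L is the lattice average of each cell's neighbor-sample population
variance (metric radius r = 1 by default, configurable).  It is invariant
under additive shifts and scales as a²; for NDJ runs it is computed on the
min-max normalized NICD field (X − 100)/1300, which leaves the sign of its
time slope unchanged.  The regime observable is the OLS slope of ⟨σ²⟩_L
against time over the recorded series: positive for lateral inhibition,
negative for lateral induction.  The entropy transform
S = ½ ln((2πe)^d σ²) is provided for interpretation; all decisions use the
variance directly.

## Sensitivity-parameter (β) estimator

The NDJ state is reduced to internal X = (N, L) with L = D + J and external
Y = (Next, Lext) (neighbor means).  The intrinsic flow is Taylor-linearized
around the NICD Hill threshold I0 on the quasi-steady-state manifold
I = αNLext (α = kT/γI); the Taylor slope of a shifted Hill at threshold is
n(λ−1)/(4I0), with h = the corresponding Hill coefficient.  Under a
small-noise Gaussian closure,

    β = −( ln|∇_Y G| + S(Y) − c ) / I(X:Y),

with every term computed from one steady-state snapshot:

* |∇_Y G| from the explicit 2×2 Jacobian, giving
  kT·N·L·|nN·N0·α(λN−1)/(4I0) − kT| at the lattice-mean state (a printed
  simplification that drops the γI factor is not used; a finite-difference
  oracle arbitrates at 10⁻⁴ relative error);
* S(Y) = ½ ln((2πe)² det Σ_Y) and I(X:Y) = ½ ln(det Σ_Y / det Σ_{Y|X}) from
  sample covariances over all lattice cells, with the conditional covariance
  by the Schur complement Σ_{Y|X} = Σ_Y − Σ_YX Σ_X⁻¹ Σ_XY (diagonal jitter
  of 10⁻¹² × trace if Σ_X is numerically singular, logged);
* c = ln M + d/2 with d = 2 and the capacity concentration
  M = |(5000, 5000)| = 5000√2 ≈ 7.07×10³, the norm of the maximal internal
  state at ~5000 molecules per species (so c ≈ 9.864);
* |∇_X G| (for the boundary diagnostic) by central finite differences with
  step 10⁻⁴ × variable scale, cross-checked analytically.

The estimate is a limiting bound — a lower bound on |β| for either sign —
and is reported as the β value.  When the mutual information is below
tolerance the estimate is undefined and flagged as the β ≈ 0 regime rather
than dropped.  Two diagnostics accompany it: the boundary quantity
ln|∇_X G / ∇_Y G|, which dips negative only near the β = 0 phase boundary,
and the quadratic correction term ⟨(Y − F̂(Y))ᵀ Σ_Y⁻¹ (Y − F̂(Y))⟩ with
F̂ = neighbor mean of Y.

**On the quadratic diagnostic.** The form is self-normalized: the residuals
Y − F̂(Y) are measured against the covariance of the very fluctuations that
produce them, so at any finite residual amplitude it evaluates to O(1) and
it reaches 0 only at an exactly uniform (or otherwise exactly
neighbor-mean-consistent) state.  It is reported as a diagnostic of how far
a snapshot is from that idealization, not asserted small at simulated
steady states.

**Where the sign correspondence holds.** Over the phase-diagram square
(D0, J0) ∈ [500, 2000]², sign(β) matches sign(modality index) on ≥ 90% of a
4×4 grid × 3 seeds (scaled-down rendering).  Extending the sweep into the
low-Jagged strip J0 ≈ 200 lands in the no-decision band where β ≈ 0 and both
signs are noise; agreement there drops to ~70%, which is the expected
behavior of a boundary band, not a calibration failure.  The sweep grids are
fully configurable.

## Pattern statistics

* **Sarle's bimodality coefficient** SBC = (g1² + 1)/(g2 + 3(n−1)²/((n−2)(n−3)))
  with method-of-moments skewness g1 and excess kurtosis g2.  SBC = 5/9 for
  uniform samples, 1/3 for normal, → 1 for symmetric two-point samples.
  The modality index 5/9 − SBC is positive for unimodal and negative for
  multimodal populations.  SBC is affine-invariant, so raw and normalized
  NICD give identical values.
* **Radial distribution function.** Pairs are binned by exact minimum-image
  distance class (integer squared distances on the torus; unit-width
  rebinning optional) so that e.g. nearest-neighbor (d = 1) and diagonal
  (d = √2) correlations of a checkerboard stay separate.  g(d) = observed
  fraction of selected-selected pairs at distance d over the expectation
  n_s(n_s−1)/(n(n−1)) under random placement; g ≡ 1 under the null.  Default
  classifier: cells above the upper tercile of the field range.
* **Ring-averaged power spectrum.** 2D DFT of the mean-subtracted field;
  amplitudes averaged over rings of equal kx² + ky² (centered integer
  frequency indexing, DC excluded), each ring average squared.  Ring-averaging
  the amplitudes *before* squaring is what rewards coherent structure: a
  checkerboard concentrates all its amplitude in the Nyquist ring while any
  value-shuffle of the same field spreads it (total unaveraged power is
  permutation-invariant by Parseval — a convention test asserts this).
* **Spectral order metric.** AUC = Σ_k p(k), referenced against the mean AUC
  of n = 20 seeded uniform value-shuffles of the same field:
  auc_metric = AUC − AUC_random.  Positive for checkerboard-like order,
  ≈ 0 for exchangeable fields, ≈ 0-or-below for uniform fields.

## Problem sizes and what the tests show

Regime and concordance analyses run on 12×12 lattices for 30000 steps with
3-5 seeds, and phase-diagram grids at 4×4 resolution — a deliberately
scaled-down rendering that reproduces the sign structure (slopes, modality,
spectral order, β) of the full-size phase diagrams; full-scale runs
(24×24, denser grids, up to 3×10⁵ steps) use the same code paths through
the CLI and change no qualitative conclusion we tested.  The synthetic
generators emulate ideal conditions: spatially i.i.d. Gaussian pairs for
the covariance pipeline (no spatial autocorrelation), perfect chessboards,
and i.i.d. random fields.  Passing tests therefore establishes internal
consistency of the estimators and the models' regime structure under the
stated rate constants — not that real tissues realize these parameters, nor
that the Gaussian microenvironment closure holds for strongly non-Gaussian
real ligand distributions.

## Known limitations

* Explicit Euler only; the stiff large-β corner needs the documented step
  bound, and very stiff NDJ parameter corners rely on clamping rather than
  adaptivity.
* The β estimator assumes the Gaussian small-noise closure and a
  steady-state snapshot; mid-transient estimates drift with stopping time.
* Near the β = 0 boundary the β sign (and hence any sign-agreement score)
  is intrinsically noise-dominated.
* Scalar phenotypes only in the Langevin model; no proliferation,
  migration, or off-lattice geometry; periodic boundaries only.
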
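# leuplat

Lattice simulators and estimators for entropy-driven cellular
decision-making and Notch-Delta-Jagged (NDJ) juxtacrine signaling.

## The problem

Notch signaling between neighboring cells patterns tissues: when Delta
ligand dominates, *lateral inhibition* drives adjacent cells to opposite
fates (checkerboard / salt-and-pepper patterns); when Jagged dominates,
*lateral induction* drives them to the same hybrid fate (uniform patterns).
Mechanistic NDJ models capture this but are high-dimensional and hard to
treat analytically.  A low-dimensional alternative describes each cell by a
scalar phenotype X ∈ [−1, 1] that moves along the gradient of its
*microenvironmental entropy* S = ½ ln(2πe σ²) (σ² = local neighborhood
variance), scaled by a single sensitivity parameter β:

    dX_n/dt = −β ∇_X S(Y_n | X_n) + ξ_n

β > 0 reduces local uncertainty (induction-like consensus), β < 0 grows it
(inhibition-like diversification).  This package implements both models on
periodic square lattices, the observables that connect them (the
lattice-averaged local variance ⟨σ²⟩_L and its time slope), an estimator
that computes β directly from NDJ steady states,

    β = −( ln|∇_Y G| + S(Y) − c ) / I(X:Y),      c = ln M + d/2,

built from the drift Jacobian of the Taylor-reduced NDJ flow, lattice
covariances, Gaussian entropy and mutual information — plus pattern
statistics (Sarle bimodality coefficient / modality index, radial
distribution function, ring-averaged power spectrum with a
shuffle-referenced AUC metric) and reproducible phase-diagram sweeps.

It is intended for computational systems biologists studying juxtacrine
patterning, and as a worked example of mapping a mechanistic signaling
model onto an entropy-based decision principle.  See `docs/methods.md` for
the full model descriptions and numerical choices.

## Worked example

Simulate a Delta-dominated (lateral inhibition) lattice and estimate β:

```bash
$ leuplat simulate-ndj --d0 1600 --j0 700 --rows 12 --cols 12 --seed 1
{"params": {"D0": 1600.0, "J0": 700.0, ...}, "grid": [12, 12], "seed": 1,
 "converged_at": null, "sigma2_steady": 0.02742,
 "variance_slope": 4.689e-05, "nicd_mean": 457.1}

$ leuplat estimate-beta --d0 1600 --j0 700 --rows 12 --cols 12 --seed 1
{"D0": 1600.0, "J0": 700.0, "seed": 1, "ln_det_dY": -2.777,
 "ln_det_dX": -0.688, "S_Y": 14.098, "mi": 0.873, "M": 7071.068, "d": 2,
 "c": 9.864, "beta": -1.669, "boundary_q": 2.090, "quad_term": 2.392}
```

The positive `variance_slope` says local NICD variance grows over time —
the lateral-inhibition signature — and the estimator returns `beta < 0`,
the inhibition-like sign.  `c = 9.864` is ln(5000√2) + 1, the capacity
constant of the internal (Notch, ligand) state space.

The phenomenological model shows the matching regime with just (β, r):

```bash
$ leuplat simulate-leup --beta -100 --radius 1 --seed 1
{"params": {"beta": -100.0, "radius": 1, ...}, "grid": [24, 24],
 "sigma2_initial": 0.2833, "sigma2_steady": 0.9160,
 "variance_slope": 7.370e-04, "sbc": 0.9845}
```

Local variance climbs from 0.28 toward its ±1-saturated maximum and the
final phenotype distribution is strongly multimodal (SBC = 0.98 ≫ 5/9, the
uniform-distribution threshold).  Positive β instead collapses ⟨σ²⟩_L and
gives SBC ≪ 5/9.

Phase diagrams (one tidy CSV row per parameter point and seed):

```bash
leuplat sweep-ndj --d0s 500,1000,1500,2000 --j0s 500,1000,1500,2000 \
    --seeds 1,2,3 --rows 12 --cols 12 --out results/ndj
leuplat sweep-leup --betas -100,-10,10,100 --radii 1,2,5 --seeds 1,2,3 \
    --out results/leup
```

The NDJ sweep reports, per run, the β estimate and all of its components,
the modality index of the NICD distribution, the nearest-neighbor NICD
correlation and the spectral AUC metric; across the (D0, J0) square the
signs of β and the modality index agree on ≳ 90% of grid points, with the
disagreements concentrated along the β ≈ 0 no-decision boundary.

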
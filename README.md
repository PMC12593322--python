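# trisurv

Region-of-interest selection from 2D images with irregular boundaries, for
interval-censored survival outcomes.

## The problem

In imaging studies of progressive disease (the motivating case is brain MRI
in Alzheimer's disease), each subject contributes a baseline image plus a
time-to-event outcome that is only known up to a visit interval: the event
is first noticed at a follow-up visit, so the true time T lies in (L, R],
with L = 0 if the event precedes the first visit and R = inf if it never
occurs during follow-up.  The scientific question is *which regions of the
image* are associated with the hazard of the event.  Two obstacles make
this hard: the image domain is irregular (naive smoothers leak information
across the boundary), and standard partial-likelihood machinery does not
apply to interval censoring.

## The model

**Stage 1 — images as splines.**  The domain Omega is triangulated into M
triangles; on each triangle the image is represented in the degree-d
Bernstein–Bézier basis (K = (d+2)(d+1)/2 functions per triangle).  Each
subject's noisy pixels are fitted by penalized least squares

    min_alpha ||Y - D alpha||^2 + varsigma alpha' P alpha   s.t.  H alpha = 0,

with P the thin-plate energy and H cross-edge continuity constraints.  The
fitted surface is reduced to scores xi_i = W alpha_i (W the basis Gram
matrix), so gamma' xi_i is exactly the L2 inner product of a coefficient
surface gamma with subject i's image.

**Stage 2 — transformation model with group selection.**  The conditional
cumulative hazard is

    Lambda(t | X_i, Z_i) = G( Lambda(t) exp(beta'Z_i + gamma'xi_i); rho ),
    G(x; rho) = log(1 + rho x) / rho,

the generalized odds-rate family: rho = 0 is Cox proportional hazards,
rho = 1 proportional odds.  Lambda is a monotone I-spline sieve (cubic,
four interior knots, J = 7).  The penalized log-likelihood

    log L(theta) - lambda sum_l s(K) ||gamma_l||_2

applies a group lasso per triangle, so entire regions are kept or dropped.
Estimation uses a Poisson-augmented EM: writing G through a gamma-frailty
Laplace transform, two latent Poisson counts per subject and basis function
give closed-form E-steps, a closed-form profile update for the sieve
coefficients, a one-step Newton update for beta, and a KKT-screened block
coordinate descent for gamma.  lambda is chosen by AIC with df = number of
nonzero estimates.

## Worked example

`examples/03_region_selection_pipeline.py` generates one replicate of the
simulation design (heart-shaped domain with ~1036 pixels inside a 40x40
grid, 63 triangles, one signal triangle, Cox case, n = 200) and runs the
full pipeline:

```
mesh: 63 triangles; signal set [59]; admin censoring at t=2.69
lambda path (12 values): AIC optimum at lambda=25.12 with 1 selected triangle(s)
selected: [59]  (truth: [59])
true-positive rate 1.000, false-positive rate 0.0000
```

The AIC-selected group-lasso fit isolates exactly the triangle whose
spline coefficients were wired into the hazard.  The other examples cover
surface smoothing on the irregular domain, the interval-censored
transformation model on its own, and selection under a misspecified
(finer) analysis mesh with the centroid-surrogate truth mapping.

A thin CLI wraps the same drivers:

```bash
trisurv simulate --n 200 --seed 1 --out sim/
trisurv fit --images sim/images.csv --records sim/records.csv --mesh sim/mesh.txt --out fit.json
trisurv replicate-table --n 200 --a 0.025 --rho 0 --reps 20 --seed 1
```

## Layout

- `src/trisurv/triangulation.py` — meshes of irregular domains, point location, mesh generation
- `src/trisurv/bernstein.py` — Bernstein–Bézier systems: design, Gram, energy, smoothness matrices
- `src/trisurv/smoothing.py` — stage-1 penalized fits and score construction
- `src/trisurv/survival.py` — transformation model, I-spline sieve, likelihood
- `src/trisurv/em.py` — Poisson-augmented EM with group-lasso selection
- `src/trisurv/simulate.py` — the synthetic-data generator (heart domain study design)
- `src/trisurv/evaluate.py` — TP/FP, surrogate-truth mapping, integrated Brier score
- `src/trisurv/pipeline.py` — two-stage driver and replicated studies
- `docs/methods.md` — modelling and numerical details
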
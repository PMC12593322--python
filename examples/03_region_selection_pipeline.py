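"""Full pipeline: find the image region associated with an event time.

Generates one replicate of the simulation design (heart domain, ~62
triangles, one signal triangle carrying spline coefficients
(0.1, 0.2, 0.3, 0.5, 0.6, 0.4), Cox-case rho = 0, n = 200), runs the
two-stage analysis, and reports which triangles the group lasso selects at
the AIC-optimal penalty.
"""

from trisurv.evaluate import tp_fp
from trisurv.pipeline import analyze
from trisurv.simulate import ScenarioConfig, make_scenario

config = ScenarioConfig(n=200, target_M=62, a=0.025, rho=0.0, seed=1)
sc = make_scenario(config)
print(f"mesh: {sc.mesh.n_triangles} triangles; signal set {sc.signal_set}; "
      f"admin censoring at t={sc.admin_time:.2f}")

result = analyze(sc.images, sc.points, sc.data, sc.mesh, rho=0.0)
best = result.best
print(f"lambda path ({len(result.fits)} values): AIC optimum at "
      f"lambda={best.lam:.2f} with {len(result.selected)} selected triangle(s)")
print(f"selected: {result.selected}  (truth: {sc.signal_set})")

tp, fp = tp_fp(result.selected, sc.signal_set, sc.mesh.n_triangles)
print(f"true-positive rate {tp:.3f}, false-positive rate {fp:.4f}")
print("TP=1/FP=0 means the penalized likelihood isolated exactly the image "
      "region that drives the hazard")
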
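"""The three cross-validation designs for longitudinal genomic prediction.

CV1 predicts unphenotyped lines from all days; CV2 forecasts each line's
future from an early time window (walk-forward); CV3 thins the phenotyping
schedule inside the training window.  Run on a synthetic water-limited
trial whose genetic trajectories are quadratic while the fitted model is
linear, so window length and phenotyping frequency genuinely matter.
"""

import warnings

import numpy as np

from longrr.basis import BasisSpec
from longrr.cv import cv1_run, cv2_run, cv3_run
from longrr.genotypes import compute_grm, impute_mean, qc_filter
from longrr.phenotypes import compute_blues
from longrr.simulate import SimulationConfig, simulate_markers, simulate_trajectories

warnings.filterwarnings("ignore")

Cu = np.array([[1000.0, 800.0, 150.0], [800.0, 700.0, 100.0], [150.0, 100.0, 250.0]])
cfg = SimulationConfig(
    n_accessions=100, n_markers=500, n_replicated=20,
    basis=BasisSpec("legendre", 2), Cu=Cu, Cpe=0.4 * Cu, seed=6,
)
markers = simulate_markers(cfg)
records, _ = simulate_trajectories(markers, cfg)
grm = compute_grm(impute_mean(qc_filter(markers, 0.0, 0.0)))
blues = compute_blues(records, "water-limited")
fit_spec = BasisSpec("legendre", 1)
kw = dict(n_repeats=5, seed=42, fit_kwargs=dict(max_iter=150, tol=1e-5))

res1 = cv1_run(blues, grm, fit_spec, **kw)
print("CV1 (new lines, all days): median accuracy per day quartile:",
      np.round(res1.groupby("day").accuracy.median().iloc[[0, 9, 19]].values, 2))

print("\nCV2 (forecast own future): median accuracy at days 16-20")
for window in (5, 10, 15):
    res = cv2_run(blues, grm, fit_spec, train_through=window, **kw)
    med = res[res.day >= 16].accuracy.median()
    print(f"  trained on days 1..{window:2d}: {med:.2f}")

print("\nCV3 (thinned phenotyping in days 1-15, forecast 16-20):")
for pattern, label in [("A", "odd days"), ("B", "even days"), ("C", "keep 1 of 3")]:
    res = cv3_run(blues, grm, fit_spec, pattern, **kw)
    print(f"  CV3{pattern} ({label:10s}): median accuracy {res.accuracy.median():.2f}")
print("phenotyping every other day costs little accuracy; thinning to every")
print("third day costs more - the basis needs support across the window")
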
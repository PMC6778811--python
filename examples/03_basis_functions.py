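"""Time-covariable bases: normalized Legendre polynomials and B-splines.

Builds the four basis configurations compared throughout the package on the
20-day grid and prints their dimensions and defining properties.
"""

import numpy as np

from longrr.basis import BasisSpec, build_basis, n_coefficients, standardize_time

days = np.arange(1.0, 21.0)
print("standardized time: day 1 ->", standardize_time(1),
      " day 10.5 ->", standardize_time(10.5), " day 20 ->", standardize_time(20))

specs = {
    "linear Legendre": BasisSpec("legendre", degree=1),
    "quadratic Legendre": BasisSpec("legendre", degree=2),
    "linear B-spline, 3 knots": BasisSpec("bspline", degree=1, n_knots=3),
    "linear B-spline, 4 knots": BasisSpec("bspline", degree=1, n_knots=4),
}
for name, spec in specs.items():
    basis = build_basis(spec, days)
    print(f"{name}: K = {n_coefficients(spec)} coefficients; "
          f"Phi is {basis.Phi.shape[0]} x {basis.Phi.shape[1]}")

leg = build_basis(specs["linear Legendre"], days)
print("\nnormalized Legendre at day 1:", np.round(leg.Phi[0], 5),
      "(sqrt(1/2), -sqrt(3/2))")

bsp = build_basis(specs["linear B-spline, 3 knots"], days)
print("B-spline knots:", bsp.spec.knots, "- equidistant on the day range")
print("row sums (partition of unity):", np.unique(np.round(bsp.Phi.sum(axis=1), 12)))
print("each B-spline coefficient only shapes the trajectory near its knot,")
print("whereas every Legendre coefficient acts along the whole trajectory")
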
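"""Cross-validation and forecasting schemes for longitudinal genomic
prediction, with Pearson correlation as the accuracy measure.

Three designs are implemented:

* CV1 - across lines: half the accessions are fitted on all days, genetic
  values of the held-out lines are obtained by projecting training BLUPs
  through the genomic relationship matrix,
  g_tst,t = G_tst,trn G_trn,trn^-1 g_trn,t.
* CV2 - walk-forward in time: a random half of the lines is fitted on days
  1..t and their own future days t+1..T are forecast as g_t' = Phi_t' u_i.
* CV3 - reduced phenotyping frequency: as CV2 with the base window 1..15
  thinned to odd days (A), even days (B) or keep-one-delete-two (C), always
  forecasting days 16..20.

Accuracies are reported per day as the Pearson correlation between predicted
genetic values and the held-out adjusted phenotypes (BLUEs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .basis import BasisSpec, build_basis
from .genotypes import GenomicRelationship
from .mtm import mtm_fit, mtm_predict_newlines
from .phenotypes import BlueTable
from .rrm import assemble, reml_fit

__all__ = [
    "CV3_DAY_SETS",
    "CVPlan",
    "accuracy",
    "cv1_run",
    "cv2_run",
    "cv3_run",
]

CV3_DAY_SETS = {
    "A": tuple(range(1, 16, 2)),  # odd days of the base window
    "B": tuple(range(2, 15, 2)),  # even days
    "C": (1, 4, 7, 10, 13),  # keep one, delete two
}


@dataclass(frozen=True)
class CVPlan:
    scenario: str
    n_repeats: int = 10
    seed: int = 0
    train_days: tuple = ()
    forecast_days: tuple = ()

    def __post_init__(self):
        if set(self.train_days) & set(self.forecast_days):
            raise ValueError("training and forecast day sets must be disjoint")


def accuracy(predicted, observed) -> float:
    """Sample Pearson correlation; NaN (with a warning) if either side is
    constant or fewer than 3 pairs are available."""
    x = np.asarray(predicted, float)
    y = np.asarray(observed, float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        warnings.warn("fewer than 3 pairs; accuracy undefined", stacklevel=2)
        return np.nan
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector; accuracy undefined", stacklevel=2)
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _repeat_rng(seed: int, repeat: int) -> np.random.Generator:
    # fixed offsets from one master seed keep repeats reproducible and
    # splits shared across models compared on the same plan
    return np.random.default_rng(int(seed) * 1009 + repeat)


def _subset_blues(blues: BlueTable, acc_idx=None, days=None) -> BlueTable:
    vals = blues.values
    if acc_idx is not None:
        vals = vals.iloc[np.asarray(acc_idx)]
    if days is not None:
        keep = [c for c in vals.columns if float(c) in {float(d) for d in days}]
        vals = vals[keep]
    return BlueTable(vals, blues.treatment)


def cv1_run(
    blues: BlueTable,
    G: GenomicRelationship,
    spec: BasisSpec,
    n_repeats: int = 10,
    seed: int = 0,
    model: str = "rrm",
    fit_kwargs: dict | None = None,
    diagnostic_training_set: bool = False,
) -> pd.DataFrame:
    """Across-line prediction: fit on ~half the lines over all days, project
    genetic values onto the held-out lines through G.

    ``model`` selects the random regression model ("rrm") or the multi-trait
    baseline ("mtm"); both use the same splits for a paired comparison.
    With ``diagnostic_training_set`` the training lines predict themselves
    (an upper-bound sanity mode, not a validation design).
    """
    fit_kwargs = dict(fit_kwargs or {})
    n = blues.accession_ids.size
    if n < 4:
        raise ValueError("need at least 4 accessions")
    phi = build_basis(spec, blues.days)
    rows = []
    for rep in range(n_repeats):
        rng = _repeat_rng(seed, rep)
        perm = rng.permutation(n)
        n_trn = int(np.ceil(n / 2))
        trn, tst = np.sort(perm[:n_trn]), np.sort(perm[n_trn:])
        if diagnostic_training_set:
            tst = trn
        blues_trn = _subset_blues(blues, trn)
        G_trn = G.subset(trn)
        G_tst_trn = G.G[np.ix_(tst, trn)]

        if model == "rrm":
            fit = reml_fit(assemble(blues_trn, phi, G_trn), **fit_kwargs)
            g_trn = phi.Phi @ fit.u  # day x n_trn
        elif model == "mtm":
            fit = mtm_fit(blues_trn, G_trn, **fit_kwargs)
            g_trn = fit.u_hat.T
        else:
            raise ValueError(f"unknown model {model!r}")

        g_tst = _project(G_tst_trn, G_trn.G, g_trn.T).T  # day x n_tst
        Y_tst = blues.to_array()[tst]
        for j, day in enumerate(blues.days):
            rows.append(
                {
                    "scenario": "CV1",
                    "model": model,
                    "repeat": rep,
                    "day": float(day),
                    "accuracy": accuracy(g_tst[j], Y_tst[:, j]),
                }
            )
    return pd.DataFrame(rows)


def _project(G_tst_trn, G_trn_trn, values_trn):
    try:
        cf = sla.cho_factor(G_trn_trn, lower=True)
    except sla.LinAlgError:
        ridged = G_trn_trn + 1e-6 * np.eye(G_trn_trn.shape[0])
        cf = sla.cho_factor(ridged, lower=True)
    return G_tst_trn @ sla.cho_solve(cf, values_trn)


def _forecast_run(
    scenario: str,
    blues: BlueTable,
    G: GenomicRelationship,
    spec: BasisSpec,
    train_days,
    forecast_days,
    n_repeats: int,
    seed: int,
    fit_kwargs: dict,
) -> pd.DataFrame:
    train_days = sorted(float(d) for d in train_days)
    forecast_days = sorted(float(d) for d in forecast_days)
    if set(train_days) & set(forecast_days):
        raise ValueError("training and forecast days must be disjoint")
    if len(train_days) < spec.K:
        raise ValueError(
            f"{len(train_days)} training days cannot identify K={spec.K} coefficients"
        )
    # Phi spans the full window so rows exist for the forecast days
    phi = build_basis(spec, blues.days)
    phi_fc = build_basis(spec, forecast_days)
    n = blues.accession_ids.size
    full = blues.to_array()
    day_list = [float(d) for d in blues.days]
    fc_cols = [day_list.index(d) for d in forecast_days]
    rows = []
    for rep in range(n_repeats):
        rng = _repeat_rng(seed, rep)
        half = np.sort(rng.permutation(n)[: n // 2])
        blues_half = _subset_blues(blues, half, train_days)
        fit = reml_fit(assemble(blues_half, phi, G.subset(half)), **fit_kwargs)
        g_fc = phi_fc.Phi @ fit.u  # forecast-day x n_half
        for j, day in enumerate(forecast_days):
            rows.append(
                {
                    "scenario": scenario,
                    "model": "rrm",
                    "repeat": rep,
                    "day": day,
                    "accuracy": accuracy(g_fc[j], full[half, fc_cols[j]]),
                }
            )
    return pd.DataFrame(rows)


def cv2_run(
    blues: BlueTable,
    G: GenomicRelationship,
    spec: BasisSpec,
    train_through: int = 15,
    n_repeats: int = 10,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Walk-forward forecasting: train on days 1..train_through for a random
    half of the lines and forecast their remaining days."""
    days = [float(d) for d in blues.days]
    train_days = [d for d in days if d <= train_through]
    forecast_days = [d for d in days if d > train_through]
    if not forecast_days:
        raise ValueError("no days left to forecast")
    return _forecast_run(
        f"CV2-{len(train_days)}/{len(forecast_days)}",
        blues, G, spec, train_days, forecast_days,
        n_repeats, seed, dict(fit_kwargs or {}),
    )


def cv3_run(
    blues: BlueTable,
    G: GenomicRelationship,
    spec: BasisSpec,
    pattern: str,
    n_repeats: int = 10,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Reduced phenotyping frequency within the base window 1..15, always
    forecasting days 16..20.  ``pattern`` is "A" (odd days), "B" (even days)
    or "C" (keep one, delete two)."""
    if pattern not in CV3_DAY_SETS:
        raise ValueError(f"pattern must be one of {sorted(CV3_DAY_SETS)}")
    days = [float(d) for d in blues.days]
    train_days = [d for d in CV3_DAY_SETS[pattern] if d in days]
    forecast_days = [d for d in days if d > 15]
    return _forecast_run(
        f"CV3{pattern}",
        blues, G, spec, train_days, forecast_days,
        n_repeats, seed, dict(fit_kwargs or {}),
    )
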
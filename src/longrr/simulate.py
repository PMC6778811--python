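"""Synthetic genotypes and longitudinal shoot-growth phenotypes.

The generator emulates a rice diversity-panel drought experiment: ~357
accessions genotyped at tens of thousands of biallelic SNPs, imaged daily
for 20 days under a control and a water-limited treatment whose mean growth
curves coincide until a divergence day (default 6) and separate afterwards.
Genetic and permanent-environment variation enter exactly the way the
random regression model assumes - through low-order basis-coefficient
covariances (Cu, Cpe) propagated over time by the basis matrix Phi - and
residual noise is Gaussian with a day-specific variance.  Ground truth
(coefficients and per-day genetic values) is returned for recovery tests.

Conventions: with U the K x n coefficient matrix stacked accession-major
(vec(U) concatenates per-accession K-vectors), Var(vec(U)) = G (x) Cu; U is
drawn as chol(Cu) Z chol(G)' with Z iid standard normal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .basis import BasisSpec, build_basis
from .genotypes import MarkerMatrix, compute_grm, impute_mean, qc_filter, write_plink

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "mean_curve",
    "simulate_markers",
    "simulate_trajectories",
    "make_fixture_suite",
]

TREATMENTS = ("control", "water-limited")


def _default_cu() -> np.ndarray:
    # linear-Legendre coefficient covariance giving small genetic variance
    # early in growth and large late, like an expanding shoot-biomass fan
    return np.array([[1000.0, 800.0], [800.0, 700.0]])


def _default_cpe() -> np.ndarray:
    return 0.4 * _default_cu()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic drought phenotyping experiment.

    Defaults mirror the real design being emulated: 357 accessions, ~35k
    SNPs, 20 daily time points, three experiments with a replicated subset
    of 54 accessions, and treatment mean curves diverging after day 6.
    """

    n_accessions: int = 357
    n_markers: int = 35000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 3  # diversity-panel population structure
    fst: float = 0.3  # Balding-Nichols differentiation among subpopulations
    admixture_alpha: float = 0.3  # Dirichlet concentration; small => near-pure lines
    inbred: bool = True  # selfing crop: homozygous dosages {0, 2}
    missing_rate: float = 0.02
    n_experiments: int = 3
    n_replicated: int = 54  # accessions duplicated within each experiment
    days: tuple = tuple(range(1, 21))
    basis: BasisSpec = field(default_factory=lambda: BasisSpec("legendre", degree=1))
    Cu: np.ndarray = field(default_factory=_default_cu)
    Cpe: np.ndarray = field(default_factory=_default_cpe)
    sigma2_eps: np.ndarray | None = None  # default (2 + 1.4 t)^2
    mean_family: str = "exponential"  # "exponential" | "logistic" | "linear"
    baseline: float = 50.0  # PSA scale at the curve origin
    growth_rate: float = 0.115  # per-day relative growth, control
    linear_slope: float = 20.0  # PSA/day for the linear mean family
    stress_rate_multiplier: float = 0.5  # growth-rate factor after divergence
    divergence_day: float = 6.0
    sigma_experiment: float = 8.0  # SD of experiment effects
    treatments: tuple = TREATMENTS
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        for name in ("Cu", "Cpe"):
            C = np.atleast_2d(np.asarray(getattr(self, name), float))
            if not np.allclose(C, C.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(C).min() < -1e-8 * max(np.abs(C).max(), 1.0):
                raise ValueError(f"{name} must be positive semi-definite")
            object.__setattr__(self, name, C)
        if self.Cu.shape[0] != self.basis.K:
            raise ValueError("Cu order must equal the basis dimension K")
        s2 = self.resolved_sigma2()
        if (s2 <= 0).any():
            raise ValueError("sigma2_eps must be positive")

    def resolved_sigma2(self) -> np.ndarray:
        if self.sigma2_eps is not None:
            return np.atleast_1d(np.asarray(self.sigma2_eps, float))
        t = np.asarray(self.days, float)
        return (2.0 + 1.4 * t) ** 2


@dataclass(frozen=True)
class SimulationTruth:
    u: dict  # treatment -> K x n genetic coefficients
    pe: dict  # treatment -> K x n permanent-environment coefficients
    g: dict  # treatment -> n x t genetic values Phi_t u_i
    mean: dict  # treatment -> length-t mean curve
    experiment_effects: np.ndarray
    config: SimulationConfig


def mean_curve(cfg: SimulationConfig, treatment: str) -> np.ndarray:
    """Population mean PSA trajectory for one treatment.

    The water-limited curve coincides with the control curve up to the
    divergence day and grows at ``stress_rate_multiplier`` times the control
    rate afterwards.  Families: "exponential" (baseline * exp(rate*t)),
    "logistic" (saturating at the control day-t_max level), and "linear"
    (baseline + slope*t).  The linear family lies inside the span of any
    basis of degree >= 1 on the day grid, which makes it the right choice
    for model-exact parameter-recovery experiments; the curved families
    emulate real shoot-growth shapes for qualitative forecasting studies.
    """
    t = np.asarray(cfg.days, float)
    r = cfg.growth_rate
    post = np.maximum(t - cfg.divergence_day, 0.0)
    # effective cumulative "growth exposure": control rate before divergence,
    # reduced rate after (control plants never diverge)
    expo = r * t if treatment == "control" else (
        r * np.minimum(t, cfg.divergence_day) + r * cfg.stress_rate_multiplier * post
    )
    if cfg.mean_family == "exponential":
        return cfg.baseline * np.exp(expo)
    if cfg.mean_family == "logistic":
        A = cfg.baseline * np.exp(r * float(np.max(cfg.days)))
        c = (A - cfg.baseline) / cfg.baseline
        return A / (1.0 + c * np.exp(-2.0 * expo))
    if cfg.mean_family == "linear":
        slope_t = (
            cfg.linear_slope * t
            if treatment == "control"
            else cfg.linear_slope
            * (np.minimum(t, cfg.divergence_day) + cfg.stress_rate_multiplier * post)
        )
        return cfg.baseline + slope_t
    raise ValueError(f"unknown mean_family {cfg.mean_family!r}")


def simulate_markers(cfg: SimulationConfig, rng=None) -> MarkerMatrix:
    """Biallelic dosages emulating a structured crop diversity panel.

    Ancestral allele frequencies are uniform on ``maf_range``; subpopulation
    frequencies drift from them under the Balding-Nichols model with
    differentiation ``fst``, and each accession draws admixture proportions
    from a symmetric Dirichlet(``admixture_alpha``), so most lines are
    near-pure members of one group with a minority of admixed lines - the
    relatedness continuum typical of a rice diversity panel.  Accessions of
    a selfing crop are inbred lines (``inbred=True``): dosages are doubled
    haploid draws, hence homozygous.  Set ``n_subpops=1`` or ``fst=0`` for
    an unstructured panel.  Calls are masked at ``missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    maf = rng.uniform(*cfg.maf_range, size=cfg.n_markers)
    if cfg.n_subpops > 1 and cfg.fst > 0:
        F = cfg.fst
        a = maf * (1 - F) / F
        b = (1 - maf) * (1 - F) / F
        pop_freq = rng.beta(a, b, size=(cfg.n_subpops, cfg.n_markers))
        pop_freq = np.clip(pop_freq, 1e-4, 1 - 1e-4)
        q = rng.dirichlet(
            np.full(cfg.n_subpops, cfg.admixture_alpha), size=cfg.n_accessions
        )
        freq = np.clip(q @ pop_freq, 1e-4, 1 - 1e-4)
    else:
        freq = np.broadcast_to(maf, (cfg.n_accessions, cfg.n_markers))
    if cfg.inbred:
        dos = 2.0 * rng.binomial(1, freq)
    else:
        dos = rng.binomial(2, freq).astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random(dos.shape) < cfg.missing_rate
        dos[mask] = np.nan
    acc = np.array([f"ACC{i:04d}" for i in range(cfg.n_accessions)])
    mrk = np.array([f"SNP{j:05d}" for j in range(cfg.n_markers)])
    return MarkerMatrix(dos, acc, mrk)


def _chol_psd(C: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(C)
        return V @ np.diag(np.sqrt(np.maximum(w, 0.0)))


def simulate_trajectories(
    markers: MarkerMatrix, cfg: SimulationConfig
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Plant-level longitudinal records plus the generating ground truth.

    Per treatment, genetic coefficients are drawn with Var(vec(U)) = G (x) Cu
    (G from the supplied markers) and permanent-environment coefficients
    with Var = I (x) Cpe; each plant record is

        psa(t) = mean_curve(t) + Phi_t u_i + Phi_t pe_i + experiment + eps_t.

    Every experiment contains one plant per accession per treatment and a
    random subset of ``n_replicated`` accessions gets a second plant.
    Treatments receive independent coefficient draws.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    # markers fixed in the sampled panel carry no relationship information
    polymorphic = qc_filter(markers, min_call_rate=0.0, min_maf=0.0)
    G = compute_grm(impute_mean(polymorphic)).G
    n = markers.n_accessions
    if n != cfg.n_accessions:
        cfg = replace(cfg, n_accessions=n)
    K = cfg.basis.K
    phi = build_basis(cfg.basis, np.asarray(cfg.days, float))
    LG = _chol_psd(G)
    Lu = _chol_psd(cfg.Cu)
    Lpe = _chol_psd(cfg.Cpe)
    s2 = cfg.resolved_sigma2()
    sd = np.sqrt(s2)
    exp_eff = rng.normal(0.0, cfg.sigma_experiment, size=cfg.n_experiments)

    u, pe, g, mean = {}, {}, {}, {}
    rows = []
    for trt in cfg.treatments:
        U = Lu @ rng.standard_normal((K, n)) @ LG.T
        P = Lpe @ rng.standard_normal((K, n))
        u[trt], pe[trt] = U, P
        g[trt] = (phi.Phi @ U).T  # n x t
        mean[trt] = mean_curve(cfg, trt)
        traj = mean[trt][None, :] + g[trt] + (phi.Phi @ P).T
        for e in range(cfg.n_experiments):
            reps = rng.choice(n, size=min(cfg.n_replicated, n), replace=False)
            counts = np.ones(n, int)
            counts[reps] = 2
            for i in range(n):
                for r in range(counts[i]):
                    eps = rng.normal(0.0, sd)
                    psa = np.maximum(traj[i] + exp_eff[e] + eps, 0.0)
                    for j, day in enumerate(cfg.days):
                        rows.append(
                            (markers.accession_ids[i], e + 1, r + 1, trt,
                             int(day), psa[j])
                        )
    records = pd.DataFrame(
        rows,
        columns=["accession", "experiment", "replicate", "treatment", "day", "psa"],
    )
    truth = SimulationTruth(u, pe, g, mean, exp_eff, cfg)
    return records, truth


def make_fixture_suite(outdir, seed: int = 0) -> dict:
    """Write a tiny (n=20, p=100, t=10) and a medium (n=300, p=2000, t=20)
    synthetic dataset for test use: phenotype CSV, genotype CSV + PLINK trio
    and truth files.  Regenerates identically for the same seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = {
        "tiny": dict(
            n_accessions=20, n_markers=100, days=tuple(range(1, 11)),
            basis=BasisSpec("legendre", degree=1, t_min=1, t_max=10),
            n_experiments=2, n_replicated=5, seed=seed,
        ),
        "medium": dict(
            n_accessions=300, n_markers=2000, days=tuple(range(1, 21)),
            n_experiments=3, n_replicated=40, seed=seed + 1,
        ),
    }
    paths = {}
    for name, kw in specs.items():
        cfg = SimulationConfig(**kw)
        sub = outdir / name
        sub.mkdir(exist_ok=True)
        markers = simulate_markers(cfg)
        records, truth = simulate_trajectories(markers, cfg)
        markers.to_frame().to_csv(sub / "genotypes.csv", na_rep="NA")
        write_plink(markers, sub / "genotypes")
        records.to_csv(sub / "phenotypes.csv", index=False)
        for trt, g in truth.g.items():
            tag = trt.replace("-", "_")
            pd.DataFrame(
                g, index=markers.accession_ids,
                columns=[f"day{int(d)}" for d in cfg.days],
            ).to_csv(sub / f"truth_genetic_values_{tag}.csv")
        meta = {
            "seed": int(cfg.seed),
            "n_accessions": int(cfg.n_accessions),
            "n_markers": int(cfg.n_markers),
            "days": [int(d) for d in cfg.days],
            "Cu": np.asarray(cfg.Cu).tolist(),
            "Cpe": np.asarray(cfg.Cpe).tolist(),
            "sigma2_eps": cfg.resolved_sigma2().tolist(),
            "experiment_effects": truth.experiment_effects.tolist(),
        }
        (sub / "truth.json").write_text(json.dumps(meta, indent=1))
        paths[name] = sub
    return paths
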
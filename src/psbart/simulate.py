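"""Simulation harness: clustered data with known ground truth, evaluation
metrics, and replication studies.

The data-generating process mirrors a 200-cluster, 6-per-cluster CRT with a
nested-Probit strata model, nonlinear arm-stratum outcome surfaces with a
heterogeneous always-survivor effect, cluster random effects in strata and
outcome (outcome ICC ~ 0.02), and a two-layer (nested MAR) missingness
mechanism; an MNAR variant routes missingness through two latent covariates
withheld from the analysis models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import G00, G10, G11, TrialDataset
from .gibbs import PosteriorDraws, SamplerConfig
from .lmm import SamplerAssembly, assembly_from_label

__all__ = [
    "DgpConfig",
    "GroundTruth",
    "MetricsReport",
    "generate_dataset",
    "apply_mnar_variant",
    "generate_linear_dataset",
    "compute_metrics",
    "run_replications",
]


@dataclass
class DgpConfig:
    """Simulation design parameters (defaults reproduce the study design)."""

    n_clusters: int = 200
    cluster_size: int = 6
    sigma_bQ2: float = 0.0204
    sigma_bW2: float = 0.0204
    sigma_bY2: float = 0.02
    sigma_eY2: float = 0.98
    missingness: str = "nested_mar"   # or "mnar_latent"
    seed: int = 0

    def __post_init__(self):
        for v in (self.sigma_bQ2, self.sigma_bW2, self.sigma_bY2,
                  self.sigma_eY2):
            if v <= 0:
                raise ValueError("variance components must be positive")
        if self.missingness not in ("nested_mar", "mnar_latent"):
            raise ValueError(f"unknown missingness mode {self.missingness!r}")


@dataclass
class GroundTruth:
    """Per-individual truth retained by the generator.

    ``tau`` is the always-survivor effect, defined only where g == G11 (NaN
    elsewhere); ``tau_surface`` evaluates the same CSACE function tau11(x) at
    every individual's covariates, which is the comparison target for
    individuals selected as likely always-survivors.  ``n_log_clamped``
    counts evaluations where the protected-stratum effect's log argument had
    to be clamped away from zero.
    """

    g: np.ndarray
    s0: np.ndarray
    s1: np.ndarray
    tau: np.ndarray
    tau_surface: np.ndarray
    u1: np.ndarray | None = None
    u2: np.ndarray | None = None
    n_log_clamped: int = 0


# -- the printed mean functions ---------------------------------------------

def true_mq(X: np.ndarray) -> np.ndarray:
    x1, x2, x3, x4, x5 = X.T
    return (1.2 + 0.6 * x1 - 0.7 * np.cos(x2) + 1.5 * x3**2
            + 0.7 * x1 * x2 - 0.5 * np.sin(np.pi * x1 * x3)
            - 0.3 * x4 + 1.0 * x5)


def true_mw(X: np.ndarray) -> np.ndarray:
    x1, x2, x3, x4, x5 = X.T
    return (0.9 + 0.9 * expit(1.5 * x1) - 0.6 * x2 + 0.4 * x3
            + 0.5 * x1 * x3 - 0.4 * np.cos(np.pi * x2)
            - 0.3 * x4 + 0.9 * x5)


def true_f11(X: np.ndarray) -> np.ndarray:
    x1, x2, x3, x4, x5 = X.T
    return (0.2 + 0.2 * x1 - 0.6 * np.sin(x2) + 0.3 * x1 * x2
            + 0.2 * (x3 - 0.5) ** 3 - 0.3 * x5)


def true_tau11(X: np.ndarray) -> np.ndarray:
    x1, x2, x3, x4, x5 = X.T
    return (-0.3 + 0.5 * expit(2 * x1) - 0.7 * np.cos(np.pi * x2 * x3)
            - 0.4 * x4 + 0.2 * x5)


def true_f10(X: np.ndarray) -> np.ndarray:
    x1, x2, x3, x4, x5 = X.T
    return (-1.5 + 0.5 * x1 + 0.8 * x2**2 - 0.6 * np.arctan(x3) - 0.5 * x4)


_LOG_FLOOR = 1e-6


def true_tau10(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Protected-stratum effect; the log argument 0.5 + x1 + 1e-4 is clamped
    at 1e-6 where nonpositive (part of the standard-normal support).  Returns
    the values and the number of clamped evaluations."""
    x1, x2, x3, x4, x5 = X.T
    arg = 0.5 + x1 + 1e-4
    n_clamped = int((arg <= _LOG_FLOOR).sum())
    val = (0.2 + 0.15 * np.log(np.maximum(arg, _LOG_FLOOR)) - 0.1 * x2**2
           + 0.3 * np.sin(np.pi * x2 * x3) - 0.2 * x4 + 0.05 * x5)
    return val, n_clamped


def generate_dataset(config: DgpConfig) -> tuple[TrialDataset, GroundTruth]:
    """One replicate of the simulation DGP with its ground truth."""
    rng = np.random.default_rng(config.seed)
    I, m = config.n_clusters, config.cluster_size
    n = I * m
    cluster = np.repeat(np.arange(I), m)

    # balanced complete randomization: exactly half the clusters treated
    arm_c = np.zeros(I, dtype=int)
    arm_c[rng.permutation(I)[: I // 2]] = 1
    z = arm_c[cluster]

    X = np.column_stack([
        rng.standard_normal(n), rng.standard_normal(n),
        rng.standard_normal(n),
        rng.binomial(1, 0.5, n).astype(float),
        rng.binomial(1, 0.5, n).astype(float),
    ])

    bQ = rng.normal(0, np.sqrt(config.sigma_bQ2), I)[cluster]
    bW = rng.normal(0, np.sqrt(config.sigma_bW2), I)[cluster]
    Q = true_mq(X) + bQ + rng.standard_normal(n)
    W = true_mw(X) + bW + rng.standard_normal(n)
    g = np.where(Q <= 0, G00, np.where(W <= 0, G10, G11))
    s1 = (g != G00).astype(int)
    s0 = (g == G11).astype(int)
    s_true = np.where(z == 1, s1, s0)

    bY = rng.normal(0, np.sqrt(config.sigma_bY2), I)[cluster]
    eY = rng.normal(0, np.sqrt(config.sigma_eY2), n)
    tau_surface = true_tau11(X)
    tau10_vals, n_clamped = true_tau10(X)
    y_z = np.full(n, np.nan)          # potential outcome under the own arm
    is11, is10 = g == G11, g == G10
    f11 = true_f11(X)
    y_z[is11] = np.where(z[is11] == 1,
                         f11[is11] + tau_surface[is11],
                         f11[is11]) + bY[is11] + eY[is11]
    treated10 = is10 & (z == 1)
    y_z[treated10] = (true_f10(X)[treated10] + tau10_vals[treated10]
                      + bY[treated10] + eY[treated10])

    # -- missingness
    if config.missingness == "nested_mar":
        p_rs = expit(1.8 + 0.4 * z - 0.3 * X[:, 0] + 0.5 * X[:, 1]
                     - 0.2 * X[:, 2])
        p_ry = expit(2.5 + 0.5 * z - 0.2 * X[:, 1] - 0.6 * X[:, 2]
                     + 0.3 * X[:, 4])
        u1 = u2 = None
    else:
        u1 = rng.standard_normal(n)
        u2 = rng.standard_normal(n)
        p_rs = expit(1.8 + 0.4 * z - 0.3 * u1 + 0.5 * u2 - 0.2 * X[:, 2])
        p_ry = expit(2.5 + 0.5 * z - 0.2 * u1 - 0.6 * u2 + 0.3 * X[:, 4])
    r_s = rng.binomial(1, p_rs)
    r_y_latent = rng.binomial(1, p_ry)

    r_y = np.zeros(n, dtype=int)
    alive_obs = (r_s == 1) & (s_true == 1)
    r_y[alive_obs] = r_y_latent[alive_obs]

    s_obs = np.where(r_s == 1, s_true.astype(float), np.nan)
    truncated = (r_s == 1) & (s_true == 0)
    y_obs = np.full(n, np.nan)
    keep = alive_obs & (r_y == 1)
    y_obs[keep] = y_z[keep]

    data = TrialDataset(
        cluster=cluster, z=z, x=X,
        covariate_names=[f"x{j}" for j in range(1, 6)],
        s_obs=s_obs, r_s=r_s, r_y=r_y, y_obs=y_obs, truncated=truncated,
    )
    tau = np.where(g == G11, tau_surface, np.nan)
    truth = GroundTruth(g=g, s0=s0, s1=s1, tau=tau, tau_surface=tau_surface,
                        u1=u1, u2=u2, n_log_clamped=n_clamped)
    return data, truth


def apply_mnar_variant(config: DgpConfig) -> tuple[TrialDataset, GroundTruth]:
    """The sensitivity DGP: identical strata/outcome generation, missingness
    driven by two latent covariates excluded from the analysis models."""
    if config.missingness != "mnar_latent":
        raise ValueError("config.missingness must be 'mnar_latent'")
    return generate_dataset(config)


# ---------------------------------------------------------------------------
# linear-truth generator (parametric-recovery oracle for the LMM engine)
# ---------------------------------------------------------------------------

LINEAR_TRUTH = {
    "beta_q": np.array([0.9, 0.5, -0.4, 0.3, -0.2, 0.4]),
    "beta_w": np.array([1.0, 0.4, -0.3, 0.2, -0.3, 0.5]),
    "alpha_11_1": np.array([0.5, 0.6, -0.4, 0.3, -0.5, 0.4]),
    "alpha_11_0": np.array([0.2, 0.4, -0.2, 0.5, -0.3, 0.1]),
    "alpha_10_1": np.array([-0.5, 0.3, 0.2, -0.2, 0.1, 0.2]),
}


def generate_linear_dataset(n_clusters: int = 60, cluster_size: int = 6,
                            seed: int = 0, sigma_y2: float = 0.5,
                            missingness: bool = False
                            ) -> tuple[TrialDataset, GroundTruth, dict]:
    """Clustered data whose strata and outcome means are exactly linear.

    Uses the coefficient vectors in ``LINEAR_TRUTH`` (intercept first), small
    cluster effects, and optionally the same nested-MAR missingness models as
    the main DGP.  Returns the dataset, a GroundTruth, and the coefficients.
    """
    rng = np.random.default_rng(seed)
    I, m = n_clusters, cluster_size
    n = I * m
    cluster = np.repeat(np.arange(I), m)
    arm_c = np.zeros(I, dtype=int)
    arm_c[rng.permutation(I)[: I // 2]] = 1
    z = arm_c[cluster]
    X = np.column_stack([
        rng.standard_normal(n), rng.standard_normal(n),
        rng.standard_normal(n),
        rng.binomial(1, 0.5, n).astype(float),
        rng.binomial(1, 0.5, n).astype(float),
    ])
    D = np.column_stack([np.ones(n), X])
    t = LINEAR_TRUTH
    bQ = rng.normal(0, np.sqrt(0.0204), I)[cluster]
    bW = rng.normal(0, np.sqrt(0.0204), I)[cluster]
    Q = D @ t["beta_q"] + bQ + rng.standard_normal(n)
    W = D @ t["beta_w"] + bW + rng.standard_normal(n)
    g = np.where(Q <= 0, G00, np.where(W <= 0, G10, G11))
    s1 = (g != G00).astype(int)
    s0 = (g == G11).astype(int)
    s_true = np.where(z == 1, s1, s0)
    bY = rng.normal(0, np.sqrt(0.02), I)[cluster]
    eY = rng.normal(0, np.sqrt(sigma_y2), n)
    y_z = np.full(n, np.nan)
    m111 = D @ t["alpha_11_1"]
    m110 = D @ t["alpha_11_0"]
    m101 = D @ t["alpha_10_1"]
    is11, treated10 = g == G11, (g == G10) & (z == 1)
    y_z[is11] = np.where(z[is11] == 1, m111[is11], m110[is11]) \
        + bY[is11] + eY[is11]
    y_z[treated10] = m101[treated10] + bY[treated10] + eY[treated10]

    if missingness:
        p_rs = expit(1.8 + 0.4 * z - 0.3 * X[:, 0] + 0.5 * X[:, 1]
                     - 0.2 * X[:, 2])
        r_s = rng.binomial(1, p_rs)
        p_ry = expit(2.5 + 0.5 * z - 0.2 * X[:, 1] - 0.6 * X[:, 2]
                     + 0.3 * X[:, 4])
        r_y_latent = rng.binomial(1, p_ry)
    else:
        r_s = np.ones(n, dtype=int)
        r_y_latent = np.ones(n, dtype=int)
    r_y = np.zeros(n, dtype=int)
    alive_obs = (r_s == 1) & (s_true == 1)
    r_y[alive_obs] = r_y_latent[alive_obs]
    s_obs = np.where(r_s == 1, s_true.astype(float), np.nan)
    truncated = (r_s == 1) & (s_true == 0)
    y_obs = np.full(n, np.nan)
    keep = alive_obs & (r_y == 1)
    y_obs[keep] = y_z[keep]

    data = TrialDataset(
        cluster=cluster, z=z, x=X,
        covariate_names=[f"x{j}" for j in range(1, 6)],
        s_obs=s_obs, r_s=r_s, r_y=r_y, y_obs=y_obs, truncated=truncated,
    )
    tau_surface = m111 - m110
    truth = GroundTruth(g=g, s0=s0, s1=s1,
                        tau=np.where(g == G11, tau_surface, np.nan),
                        tau_surface=tau_surface)
    return data, truth, t


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """CSACE estimation and stratum-classification metrics for one fit."""

    pehe: float
    abs_bias: float
    regret: float
    coverage: float
    stratum_power: float
    stratum_fdr: float
    n_likely_always: int
    defined: bool = True

    def as_dict(self) -> dict:
        return {
            "PEHE": self.pehe, "AbsBias": self.abs_bias,
            "Regret": self.regret, "Coverage": self.coverage,
            "Power": self.stratum_power, "FDR": self.stratum_fdr,
            "N_G": self.n_likely_always,
        }


def compute_metrics(draws: PosteriorDraws, truth: GroundTruth,
                    q: float = 0.8) -> MetricsReport:
    """Evaluate one fitted chain against the generator's ground truth.

    Likely always-survivors are individuals with posterior stratum-11
    probability >= q.  PEHE / absolute bias / regret / coverage are computed
    over that set against the true CSACE surface; classification power and
    FDR are computed over all individuals against the true labels.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    p11 = draws.p11()
    declared = p11 >= q
    true_always = truth.g == G11
    n_declared = int(declared.sum())

    power_den = int(true_always.sum())
    power = (float((declared & true_always).sum()) / power_den
             if power_den else float("nan"))
    fdr = (float((declared & ~true_always).sum()) / n_declared
           if n_declared else float("nan"))

    if n_declared == 0:
        return MetricsReport(float("nan"), float("nan"), float("nan"),
                             float("nan"), power, fdr, 0, defined=False)

    with np.errstate(all="ignore"):
        tau_hat = np.nanmean(draws.tau, axis=0)
        lo = np.nanquantile(draws.tau, 0.025, axis=0)
        hi = np.nanquantile(draws.tau, 0.975, axis=0)
    tau_hat_d = tau_hat[declared]
    tau_true_d = truth.tau_surface[declared]
    err = tau_hat_d - tau_true_d
    pehe = float(np.sqrt(np.mean(err**2)))
    abs_bias = float(np.mean(np.abs(err)))
    disagree = (tau_hat_d > 0) != (tau_true_d > 0)
    regret = float(np.mean(np.abs(tau_true_d) * disagree))
    # draws are stored in float32; widen by one float32 ulp so degenerate
    # intervals still contain an exactly-equal truth
    eps = 1e-6 * np.maximum(1.0, np.abs(tau_true_d))
    coverage = float(np.mean((lo[declared] - eps <= tau_true_d)
                             & (tau_true_d <= hi[declared] + eps)))
    return MetricsReport(pehe, abs_bias, regret, coverage, power, fdr,
                         n_declared)


# ---------------------------------------------------------------------------
# replication studies
# ---------------------------------------------------------------------------

def run_replications(engine: str | SamplerAssembly, n_reps: int,
                     dgp: DgpConfig, sampler: SamplerConfig,
                     progress: bool = False
                     ) -> tuple[pd.DataFrame, dict]:
    """Fit one sampler variant to ``n_reps`` fresh DGP replicates.

    Replicate r uses DGP seed ``dgp.seed + r`` and sampler seed
    ``sampler.seed + r``.  Returns the per-replicate metric table and a
    summary dict with "mean (sd)" strings per metric; failed replicates are
    recorded and excluded from the summary.
    """
    from dataclasses import replace

    assembly = engine if isinstance(engine, SamplerAssembly) \
        else assembly_from_label(engine)
    rows = []
    failures = 0
    for r in range(n_reps):
        cfg_d = replace(dgp, seed=dgp.seed + r)
        cfg_s = replace(sampler, seed=sampler.seed + r)
        try:
            data, truth = generate_dataset(cfg_d)
            draws = assembly.run(data, cfg_s)
            rep = compute_metrics(draws, truth,
                                  q=cfg_s.always_survivor_threshold)
            rows.append({"replicate": r, **rep.as_dict()})
        except Exception as exc:  # noqa: BLE001 - record and continue
            failures += 1
            rows.append({"replicate": r, "error": str(exc)})
        if progress:
            print(f"[{assembly.label}] replicate {r + 1}/{n_reps} done",
                  flush=True)
    table = pd.DataFrame(rows)
    ok = table[~table.get("error", pd.Series(False, index=table.index))
               .astype(bool)] if "error" in table else table
    metric_cols = ["PEHE", "AbsBias", "Regret", "Coverage", "Power", "FDR"]
    summary = {"engine": assembly.label, "n_reps": n_reps,
               "n_failed": failures}
    for c in metric_cols:
        if c in ok and len(ok):
            summary[c] = f"{ok[c].mean():.3f} ({ok[c].std(ddof=1):.3f})"
            summary[c + "_mean"] = float(ok[c].mean())
            summary[c + "_sd"] = float(ok[c].std(ddof=1))
    return table, summary
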
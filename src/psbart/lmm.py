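"""Fully parametric linear mixed-effects benchmark.

Replaces every nonparametric mean function of the BART sampler with a linear
predictor (intercept + main effects) while keeping the identical hierarchical
structure: nested-Probit membership, arm-stratum Gaussian outcome models,
cluster random intercepts, and the same Gibbs factorization.  All full
conditionals are conjugate:

    beta | rest  ~  N( (Lambda + X'X/s2)^{-1} X'(y - b)/s2 ,
                       (Lambda + X'X/s2)^{-1} )
    b_i | rest   ~  N( (sum r_ij/s2) / (n_i/s2 + 1/s2_b),
                       1 / (n_i/s2 + 1/s2_b) )
    s2_b | rest  ~  IG(a + C/2, b + sum b_i^2 / 2)
    s2   | rest  ~  IG(a + n/2, b + SSR/2)

The linear engine doubles as an oracle for the tree engine on linear-truth
data, and as the misspecified comparator on nonlinear truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearMixedModel",
    "update_coefficients",
    "run_mcmc_lmm",
    "hybrid_variants",
    "SamplerAssembly",
]


def _draw_inv_gamma(shape: float, rate: float,
                    rng: np.random.Generator) -> float:
    return float(rate / rng.gamma(shape))


def update_coefficients(X: np.ndarray, response: np.ndarray,
                        clusters: np.ndarray, intercepts: np.ndarray,
                        variance: float, prior_precision: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw regression coefficients from their Gaussian full conditional.

    ``intercepts`` is the vector of cluster random intercepts (indexed by
    ``clusters``); the response is adjusted by them before the conjugate
    update.  Precision = Lambda + X'X / sigma^2.
    """
    X = np.asarray(X, float)
    r = np.asarray(response, float) - np.asarray(intercepts, float)[clusters]
    prec = prior_precision + X.T @ X / variance
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, X.T @ r / variance)
    z = rng.standard_normal(X.shape[1])
    return mean + np.linalg.solve(chol.T, z)


class LinearMixedModel:
    """Linear mean function + cluster random intercept, conjugate updates.

    Mirrors the MixedBartModel interface (``sweep`` / ``predict`` / ``sigma2``)
    so the Gibbs engine can swap engines per mean function.  The design is an
    intercept column plus covariate main effects; coefficients carry a
    N(0, Lambda^{-1}) prior with Lambda = lambda_prior * I.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, n_clusters: int,
                 mode: str = "gaussian", lambda_prior: float = 0.01,
                 a0: float = 0.001, b0: float = 0.001,
                 rng: np.random.Generator | None = None, **_ignored):
        if mode not in ("gaussian", "probit_latent"):
            raise ValueError(f"unknown response mode {mode!r}")
        X = np.asarray(X, float)
        self.mode = mode
        self.p = X.shape[1]
        self.n_clusters = int(n_clusters)
        self.Lambda = lambda_prior * np.eye(self.p + 1)
        self.a0, self.b0 = a0, b0
        self.beta = np.zeros(self.p + 1)
        self.b = np.zeros(self.n_clusters)
        self.sigma_b2 = 0.5
        self.sigma2 = (float(np.var(np.asarray(y, float))) or 1.0) \
            if mode == "gaussian" else 1.0
        self.rng = rng or np.random.default_rng()

    @staticmethod
    def _design(X: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(X.shape[0]), X])

    def sweep(self, X: np.ndarray, y: np.ndarray, clusters: np.ndarray,
              rng: np.random.Generator | None = None,
              cache_token: object = None) -> "LinearMixedModel":
        if rng is not None:
            self.rng = rng
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if y.size == 0:
            raise ValueError("empty response")
        clusters = np.asarray(clusters)
        D = self._design(X)
        self.beta = update_coefficients(D, y, clusters, self.b, self.sigma2,
                                        self.Lambda, self.rng)
        resid = y - D @ self.beta
        counts = np.bincount(clusters, minlength=self.n_clusters).astype(float)
        sums = np.bincount(clusters, weights=resid,
                           minlength=self.n_clusters)
        prec = counts / self.sigma2 + 1.0 / self.sigma_b2
        var = 1.0 / prec
        mean = var * sums / self.sigma2
        self.b = mean + np.sqrt(var) * self.rng.standard_normal(self.n_clusters)
        self.sigma_b2 = _draw_inv_gamma(
            self.a0 + self.n_clusters / 2.0,
            self.b0 + float((self.b ** 2).sum()) / 2.0, self.rng)
        if self.mode == "gaussian":
            ssr = float(((resid - self.b[clusters]) ** 2).sum())
            self.sigma2 = _draw_inv_gamma(self.a0 + y.size / 2.0,
                                          self.b0 + ssr / 2.0, self.rng)
        return self

    def predict(self, X: np.ndarray, clusters: np.ndarray | None = None,
                include_intercepts: bool = False) -> np.ndarray:
        out = self._design(np.asarray(X, float)) @ self.beta
        if include_intercepts:
            if clusters is None:
                raise ValueError("intercepts requested without cluster indices")
            clusters = np.asarray(clusters)
            known = (clusters >= 0) & (clusters < self.n_clusters)
            add = np.zeros(len(clusters))
            add[known] = self.b[clusters[known]]
            out = out + add
        return out


@dataclass
class SamplerAssembly:
    """A configured principal-stratification sampler.

    ``outcome_engine`` and ``membership_engine`` each select 'bart' or 'lmm'
    mean functions; (bart, bart) is the fully nonparametric sampler and
    (lmm, lmm) the fully parametric benchmark.  The four combinations are the
    YBSB / YBSP / YPSB / YPSP variants (Y = outcome model, S = stratum model,
    B = BART, P = parametric).
    """

    outcome_engine: str
    membership_engine: str

    @property
    def label(self) -> str:
        code = {"bart": "B", "lmm": "P"}
        return f"Y{code[self.outcome_engine]}S{code[self.membership_engine]}"

    def run(self, data, config):
        from .gibbs import run_mcmc
        return run_mcmc(data, config,
                        outcome_engine=self.outcome_engine,
                        membership_engine=self.membership_engine)


_ENGINE_CODES = {"ybsb": ("bart", "bart"), "ybsp": ("bart", "lmm"),
                 "ypsb": ("lmm", "bart"), "ypsp": ("lmm", "lmm")}


def hybrid_variants(outcome_engine: str,
                    membership_engine: str) -> SamplerAssembly:
    """Assemble a sampler with the requested engine per model block."""
    for eng in (outcome_engine, membership_engine):
        if eng not in ("bart", "lmm"):
            raise ValueError(f"unknown engine {eng!r}")
    return SamplerAssembly(outcome_engine, membership_engine)


def assembly_from_label(label: str) -> SamplerAssembly:
    """Build a sampler from a YBSB/YBSP/YPSB/YPSP code."""
    try:
        return SamplerAssembly(*_ENGINE_CODES[label.lower()])
    except KeyError:
        raise ValueError(f"unknown engine label {label!r}") from None


def run_mcmc_lmm(data, config):
    """The fully parametric benchmark sampler (linear means everywhere)."""
    from .gibbs import run_mcmc
    return run_mcmc(data, config, outcome_engine="lmm",
                    membership_engine="lmm")
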
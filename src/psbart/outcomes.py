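"""Arm x stratum Gaussian outcome models.

Outcomes are defined only where the potential outcome exists: always-survivors
under either arm, and protected individuals under treatment.  The three models
(11,1), (11,0), (10,1) are mixed-effects mean functions (BART or linear) with
their own residual variances and cluster random intercepts; asking for the
density or an imputation in any other (stratum, arm) cell is an error — that
guard is the operational meaning of truncation by death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import G00, G10, G11, TrialDataset

__all__ = [
    "ADMISSIBLE_CELLS",
    "OutcomeModelSet",
    "outcome_density",
    "normal_density",
    "outcome_bart_step",
    "impute_outcome",
    "observed_data_loglik",
]

#: the (stratum, arm) cells in which the non-mortality outcome is defined
ADMISSIBLE_CELLS = ((G11, 1), (G11, 0), (G10, 1))


@dataclass
class OutcomeModelSet:
    """The three admissible arm-stratum mean models keyed by (g, z)."""

    models: dict

    def __post_init__(self):
        extra = set(self.models) - set(ADMISSIBLE_CELLS)
        if extra:
            raise ValueError(f"models for undefined outcome cells: {extra}")

    def __getitem__(self, key):
        g, z = key
        if (g, z) not in ADMISSIBLE_CELLS:
            raise ValueError(
                f"outcome undefined for stratum {g} under arm {z} "
                "(truncation by death)")
        return self.models[(g, z)]

    def __contains__(self, key):
        return key in self.models

    def items(self):
        return self.models.items()


def normal_density(y, mean, var) -> np.ndarray:
    y = np.asarray(y, float)
    return np.exp(-0.5 * (y - mean) ** 2 / var) / np.sqrt(2 * np.pi * var)


def outcome_density(y, g: int, z: int, models: OutcomeModelSet,
                    x: np.ndarray, cluster) -> float | np.ndarray:
    """Normal density of y under the (g, z) outcome model at covariates x.

    Raises for inadmissible (g, z); this is the guard that keeps undefined
    outcomes out of every likelihood evaluation.
    """
    model = models[(g, z)]  # raises on inadmissible cells
    x = np.atleast_2d(np.asarray(x, float))
    clusters = np.atleast_1d(np.asarray(cluster))
    mean = model.predict(x, clusters, include_intercepts=True)
    out = normal_density(y, mean, model.sigma2)
    return float(out[0]) if out.size == 1 else out


def outcome_bart_step(models: OutcomeModelSet, X: np.ndarray,
                      y_current: np.ndarray, z: np.ndarray,
                      labels: np.ndarray, survival: np.ndarray,
                      clusters: np.ndarray,
                      rng: np.random.Generator) -> OutcomeModelSet:
    """One mean-function update per admissible (g, z) on its current subset.

    Subsets are the individuals currently labelled g in arm z whose survival
    is (possibly imputed) 1 and who carry a current outcome value — observed
    or imputed, i.e. full data augmentation.  An empty subset leaves that
    model unchanged.  The residual-variance draws are part of each model's
    update (conjugate inverse-gamma).
    """
    has_y = ~np.isnan(y_current) & (survival == 1)
    for (g, zz), model in models.items():
        rows = np.nonzero((labels == g) & (z == zz) & has_y)[0]
        if len(rows) == 0:
            continue
        model.sweep(X[rows], y_current[rows], clusters[rows], rng,
                    cache_token=("subset", rows.tobytes()))
    return models


def impute_outcome(g: int, z: int, models: OutcomeModelSet, x: np.ndarray,
                   cluster, rng: np.random.Generator,
                   survival: int = 1) -> float | np.ndarray:
    """Draw a missing outcome from N(m_{g,z}(x) + b_cluster, sigma_{g,z}^2).

    Only callable for survivors in admissible cells; a (possibly imputed)
    survival of 0 means the outcome is undefined by design, not missing.
    """
    if np.any(np.asarray(survival) == 0):
        raise ValueError("the non-mortality outcome is undefined for "
                         "non-survivors and is not imputed")
    model = models[(g, z)]
    x = np.atleast_2d(np.asarray(x, float))
    clusters = np.atleast_1d(np.asarray(cluster))
    mean = model.predict(x, clusters, include_intercepts=True)
    draw = mean + math.sqrt(model.sigma2) * rng.standard_normal(len(mean))
    return float(draw[0]) if draw.size == 1 else draw


def observed_data_loglik(data: TrialDataset, mQ: np.ndarray, mW: np.ndarray,
                         models: OutcomeModelSet) -> float:
    """Observed-data log likelihood (conditional on covariates).

    Factorizes over the four observed (arm, survival) cells: treated
    survivors mix p11 f_{11,1} + p10 f_{10,1}; treated non-survivors
    contribute p00; control survivors p11 f_{11,0}; control non-survivors
    p10 + p00.  Rows with unrecorded survival status contribute nothing
    (their likelihood term is 1 under nested MAR).
    """
    from .strata import stratum_probabilities

    probs = stratum_probabilities(mQ, mW)
    p00, p10, p11 = probs.p00, probs.p10, probs.p11
    ll = 0.0
    obs = data.r_s == 1
    for i in np.nonzero(obs)[0]:
        zi, si = int(data.z[i]), int(data.s_obs[i])
        if zi == 1 and si == 1:
            if data.r_y[i] == 1:
                f111 = outcome_density(data.y_obs[i], G11, 1, models,
                                       data.x[i], data.cluster[i])
                f101 = outcome_density(data.y_obs[i], G10, 1, models,
                                       data.x[i], data.cluster[i])
                ll += math.log(p11[i] * f111 + p10[i] * f101)
            else:
                ll += math.log(p11[i] + p10[i])
        elif zi == 1 and si == 0:
            ll += math.log(p00[i])
        elif zi == 0 and si == 1:
            if data.r_y[i] == 1:
                f110 = outcome_density(data.y_obs[i], G11, 0, models,
                                       data.x[i], data.cluster[i])
                ll += math.log(p11[i] * f110)
            else:
                ll += math.log(p11[i])
        else:
            ll += math.log(p10[i] + p00[i])
    return ll
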
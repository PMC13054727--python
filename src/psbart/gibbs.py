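"""Gibbs sampler for Bayesian principal stratification in CRTs.

Each iteration updates, in fixed order: (i) the three arm-stratum outcome
mean functions on their current label subsets, (ii) their residual variances
(conjugate, inside the model update), (iii) the two membership mean functions
regressed on the current latent normals, (iv) the latent normals from their
truncated full conditionals, (v) the stratum labels from the pattern-specific
full conditionals combining membership probabilities with outcome
likelihoods, and (vi) the missing data under the nested-MAR structure —
survival follows deterministically from the fresh label and arm under
monotonicity, outcomes are imputed for survivors and cleared for
non-survivors.

The mean-function engine is selectable per block ('bart' or 'lmm'), which
yields the four sampler variants used in the simulation studies.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from . import bart as _bart
from .data import (G00, G10, G11, CovariateTransform, ObservationPattern,
                   TrialDataset, impute_baseline_covariates)
from .lmm import LinearMixedModel
from .outcomes import OutcomeModelSet, outcome_bart_step
from .strata import (MembershipState, sample_latents, sample_truncated_normal,
                     stratum_probabilities)

__all__ = [
    "SamplerConfig",
    "ChainState",
    "PosteriorDraws",
    "initialize_chain",
    "gibbs_step",
    "run_mcmc",
    "compute_csace_draw",
]


@dataclass
class SamplerConfig:
    """MCMC settings; defaults follow the primary analysis protocol."""

    n_iter: int = 20_000
    n_burn: int = 10_000
    thin: int = 1
    seed: int = 0
    K_outcome: int = 200
    K_membership: int = 50
    a0: float = 0.001
    b0: float = 0.001
    always_survivor_threshold: float = 0.8
    k_scale: float = 2.0
    min_leaf: int = 5
    #: average each draw's SACE over that draw's always-survivors (default)
    #: or over a fixed likely-always-survivor set determined post hoc
    sace_over_current_labels: bool = True

    def __post_init__(self):
        if not self.n_burn < self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        if not 0 < self.always_survivor_threshold < 1:
            raise ValueError("always_survivor_threshold must lie in (0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ChainState:
    """Mutable state of one Gibbs chain."""

    membership: MembershipState
    models: dict                    # 'Q', 'W', and the three (g, z) keys
    outcome_set: OutcomeModelSet
    s_cur: np.ndarray               # current (possibly imputed) survival
    y_cur: np.ndarray               # current outcome; NaN where undefined

    @property
    def G(self) -> np.ndarray:
        return self.membership.G


@dataclass
class PosteriorDraws:
    """Retained MCMC output.

    ``G`` holds the label draws (draws x n, codes 0/1/2); ``tau`` the
    always-survivor effect surface evaluated at every individual's
    covariates; ``sace`` the per-draw average of tau over that draw's
    always-survivors; ``pi`` the per-draw stratum proportions
    (pi00, pi10, pi11).
    """

    G: np.ndarray
    tau: np.ndarray
    sace: np.ndarray
    pi: np.ndarray
    n_degenerate: int
    config: SamplerConfig
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.G.shape[0]

    def p11(self) -> np.ndarray:
        """Posterior probability of always-survivor status per individual."""
        return (self.G == G11).mean(axis=0)

    def stratum_proportions(self) -> np.ndarray:
        """Posterior mean of (pi00, pi10, pi11)."""
        return self.pi.mean(axis=0)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

@dataclass
class _Prepared:
    X: np.ndarray
    clusters: np.ndarray
    z: np.ndarray
    r_s: np.ndarray
    r_y: np.ndarray
    s_obs: np.ndarray
    y_obs: np.ndarray
    n_clusters: int
    transform: CovariateTransform
    covariate_names: list[str]


def _prepare(data: TrialDataset) -> _Prepared:
    if np.isnan(data.x).any():
        data = impute_baseline_covariates(data)
    transform = CovariateTransform.fit(data.x)
    X = transform.apply(data.x)
    if (data.cluster_z == 1).sum() == 0 or (data.cluster_z == 0).sum() == 0:
        raise ValueError("both arms must contain at least one cluster")
    return _Prepared(
        X=X, clusters=data.cluster, z=data.z, r_s=data.r_s, r_y=data.r_y,
        s_obs=data.s_obs, y_obs=data.y_obs, n_clusters=data.n_clusters,
        transform=transform, covariate_names=list(data.covariate_names),
    )


def _make_model(engine: str, X, y, n_clusters, mode, config: SamplerConfig,
                rng, K=None):
    if engine == "bart":
        return _bart.MixedBartModel(
            X, y, n_clusters, K=K, mode=mode, k_scale=config.k_scale,
            min_leaf=config.min_leaf, a0=config.a0, b0=config.b0, rng=rng)
    if engine == "lmm":
        return LinearMixedModel(X, y, n_clusters, mode=mode,
                                a0=config.a0, b0=config.b0, rng=rng)
    raise ValueError(f"unknown engine {engine!r}")


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _initial_survival(prep: _Prepared, engine: str, config: SamplerConfig,
                      rng) -> np.ndarray:
    """Impute survival for unrecorded-status rows from a classifier fit to
    the observed-status rows (probit BART, or logistic under the linear
    engine), thresholded at 0.5."""
    s = np.where(prep.r_s == 1, prep.s_obs, np.nan)
    miss = np.isnan(s)
    if not miss.any():
        return s.astype(int)
    obs = ~miss
    Xo = prep.X[obs]
    so = s[obs].astype(int)
    if so.min() == so.max():
        s[miss] = so[0]
        return s.astype(int)
    if engine == "bart":
        model = _make_model("bart", Xo, np.zeros(obs.sum()), prep.n_clusters,
                            "probit_latent", config, rng,
                            K=config.K_membership)
        h = np.where(so == 1, 0.5, -0.5)
        for _ in range(20):
            model.sweep(Xo, h, prep.clusters[obs], rng, cache_token="init-s")
            m = model.predict(Xo, prep.clusters[obs], include_intercepts=True)
            lo = np.where(so == 1, 0.0, -np.inf)
            hi = np.where(so == 1, np.inf, 0.0)
            h = sample_truncated_normal(m, lo, hi, rng)
        p = ndtr(model.predict(prep.X[miss], prep.clusters[miss],
                               include_intercepts=True))
    else:
        from sklearn.linear_model import LogisticRegression
        clf = LogisticRegression(max_iter=1000).fit(Xo, so)
        p = clf.predict_proba(prep.X[miss])[:, 1]
    s[miss] = (p >= 0.5).astype(float)
    return s.astype(int)


def _initial_labels(prep: _Prepared, s_init: np.ndarray, rng) -> np.ndarray:
    """Monotonicity-identified labels where possible, random admissible
    labels in the observed mixtures."""
    n = len(s_init)
    G = np.empty(n, dtype=np.int8)
    z = prep.z
    surv = s_init == 1
    # survivors: control -> always-survivor; treated -> {protected, always}
    G[surv & (z == 0)] = G11
    idx = np.nonzero(surv & (z == 1))[0]
    G[idx] = rng.choice([G10, G11], size=len(idx))
    # non-survivors: treated -> never; control -> {never, protected}
    G[~surv & (z == 1)] = G00
    idx = np.nonzero(~surv & (z == 0))[0]
    G[idx] = rng.choice([G00, G10], size=len(idx))
    return G


def _initial_membership_means(prep: _Prepared,
                              G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probit-scale starting means from logistic fits of the initial labels."""
    from sklearn.linear_model import LogisticRegression

    def _fit_prob(X, ytarget, Xall):
        if ytarget.min() == ytarget.max():
            return np.full(Xall.shape[0], 0.98 if ytarget[0] else 0.02)
        clf = LogisticRegression(max_iter=1000).fit(X, ytarget)
        return clf.predict_proba(Xall)[:, 1]

    p_surv = _fit_prob(prep.X, (G != G00).astype(int), prep.X)
    cap = G != G00
    p_always = _fit_prob(prep.X[cap], (G[cap] == G11).astype(int), prep.X)
    clip = lambda p: np.clip(p, 1e-3, 1 - 1e-3)
    return ndtri(clip(p_surv)), ndtri(clip(p_always))


def initialize_chain(data: TrialDataset, config: SamplerConfig,
                     rng: np.random.Generator,
                     outcome_engine: str = "bart",
                     membership_engine: str = "bart",
                     prep: _Prepared | None = None) -> ChainState:
    """Deterministic labels where monotonicity identifies them, random
    admissible labels elsewhere; latents drawn consistently; models
    warm-started on the initial subsets."""
    prep = prep or _prepare(data)
    s_init = _initial_survival(prep, membership_engine, config, rng)
    G = _initial_labels(prep, s_init, rng)
    mQ0, mW0 = _initial_membership_means(prep, G)
    Q, W = sample_latents(G, mQ0, mW0, rng)
    membership = MembershipState(Q=Q, W=W, G=G)
    membership.check_consistent()

    models: dict = {}
    for key, latent in (("Q", Q), ("W", W)):
        m = _make_model(membership_engine, prep.X, latent, prep.n_clusters,
                        "probit_latent", config, rng, K=config.K_membership)
        for _ in range(10):
            m.sweep(prep.X, latent, prep.clusters, rng, cache_token="all")
        models[key] = m

    y_all = prep.y_obs[~np.isnan(prep.y_obs)]
    if y_all.size == 0:
        raise ValueError("no observed outcomes to anchor the outcome models")
    outcome_models = {}
    has_y = ~np.isnan(prep.y_obs)
    for g, zz in ((G11, 1), (G11, 0), (G10, 1)):
        rows = np.nonzero((G == g) & (prep.z == zz) & has_y)[0]
        y_init = prep.y_obs[rows] if len(rows) >= 5 else y_all
        m = _make_model(outcome_engine, prep.X, y_init, prep.n_clusters,
                        "gaussian", config, rng, K=config.K_outcome)
        if len(rows):
            for _ in range(10):
                m.sweep(prep.X[rows], prep.y_obs[rows], prep.clusters[rows],
                        rng, cache_token=("init", g, zz))
        models[(g, zz)] = m
        outcome_models[(g, zz)] = m
    outcome_set = OutcomeModelSet(outcome_models)

    y_cur = prep.y_obs.copy()
    state = ChainState(membership=membership, models=models,
                       outcome_set=outcome_set,
                       s_cur=s_init, y_cur=y_cur)
    _impute_missing(state, prep, rng)
    return state


# ---------------------------------------------------------------------------
# per-iteration updates
# ---------------------------------------------------------------------------

def _impute_missing(state: ChainState, prep: _Prepared, rng) -> None:
    """Step (vi): survival from the fresh labels under monotonicity, outcome
    draws for survivors without an observed outcome, NaN for non-survivors."""
    G = state.G
    z = prep.z
    unrecorded = prep.r_s == 0
    s = np.where(prep.r_s == 1, prep.s_obs, 0.0).astype(int)
    s[unrecorded] = ((G[unrecorded] == G11)
                     | ((G[unrecorded] == G10) & (z[unrecorded] == 1))
                     ).astype(int)
    state.s_cur = s

    y = prep.y_obs.copy()
    need = (s == 1) & np.isnan(prep.y_obs)
    for g, zz in ((G11, 1), (G11, 0), (G10, 1)):
        rows = np.nonzero(need & (G == g) & (z == zz))[0]
        if len(rows) == 0:
            continue
        model = state.outcome_set[(g, zz)]
        mean = model.predict(prep.X[rows], prep.clusters[rows],
                             include_intercepts=True)
        y[rows] = mean + np.sqrt(model.sigma2) * rng.standard_normal(len(rows))
    y[s == 0] = np.nan
    state.y_cur = y


def _draw_labels(state: ChainState, prep: _Prepared, rng) -> None:
    """Step (v): stratum labels from the pattern-specific full conditionals."""
    X, cl, z = prep.X, prep.clusters, prep.z
    mQ = state.models["Q"].predict(X, cl, include_intercepts=True)
    mW = state.models["W"].predict(X, cl, include_intercepts=True)
    probs = stratum_probabilities(mQ, mW)
    w = probs.as_matrix().copy()          # n x 3 in (00, 10, 11) order

    obs_dead = (prep.r_s == 1) & (prep.s_obs == 0)
    obs_alive = (prep.r_s == 1) & (prep.s_obs == 1)
    # identified cells
    w[obs_dead & (z == 1)] = (1.0, 0.0, 0.0)
    w[obs_alive & (z == 0)] = (0.0, 0.0, 1.0)
    # control non-survivors mix {00, 10}
    rows = obs_dead & (z == 0)
    w[rows, 2] = 0.0
    # treated survivors mix {10, 11}; observed outcomes weigh in
    rows = obs_alive & (z == 1)
    w[rows, 0] = 0.0
    with_y = np.nonzero(rows & (prep.r_y == 1))[0]
    if len(with_y):
        y = prep.y_obs[with_y]
        for g, col in ((G10, 1), (G11, 2)):
            model = state.outcome_set[(g, 1)]
            mean = model.predict(X[with_y], cl[with_y],
                                 include_intercepts=True)
            dens = np.exp(-0.5 * (y - mean) ** 2 / model.sigma2) \
                / np.sqrt(2 * np.pi * model.sigma2)
            w[with_y, col] *= dens
    # unrecorded-status rows keep the plain membership probabilities

    total = w.sum(axis=1, keepdims=True)
    bad = total[:, 0] <= 0
    if bad.any():
        w[bad] = 1.0 / 3.0
        total[bad] = 1.0
    w /= total
    u = rng.random(len(w))
    cum = np.cumsum(w, axis=1)
    state.membership.G = np.int8((u[:, None] > cum).sum(axis=1))


def gibbs_step(state: ChainState, data_or_prep, config: SamplerConfig,
               rng: np.random.Generator) -> ChainState:
    """One full iteration in the fixed order (i)-(vi)."""
    prep = data_or_prep if isinstance(data_or_prep, _Prepared) \
        else _prepare(data_or_prep)
    X, cl = prep.X, prep.clusters

    # (i) + (ii): outcome mean functions and variances on current subsets
    outcome_bart_step(state.outcome_set, X, state.y_cur, prep.z,
                      state.G, state.s_cur, cl, rng)
    # (iii): membership mean functions on the current latents
    state.models["Q"].sweep(X, state.membership.Q, cl, rng, cache_token="all")
    state.models["W"].sweep(X, state.membership.W, cl, rng, cache_token="all")
    # (iv): latent normals given labels
    mQ = state.models["Q"].predict(X, cl, include_intercepts=True)
    mW = state.models["W"].predict(X, cl, include_intercepts=True)
    Q, W = sample_latents(state.G, mQ, mW, rng)
    state.membership.Q, state.membership.W = Q, W
    # (v): labels
    _draw_labels(state, prep, rng)
    # latents must match the fresh labels before the next membership fit
    Q, W = sample_latents(state.G, mQ, mW, rng)
    state.membership.Q, state.membership.W = Q, W
    # (vi): nested-MAR missing data
    _impute_missing(state, prep, rng)
    return state


def compute_csace_draw(state: ChainState,
                       prep_or_X) -> tuple[np.ndarray, float]:
    """Individual always-survivor effects for the current draw.

    tau_i = m_{11,1}(x_i) - m_{11,0}(x_i), evaluated at every individual's
    covariates from the mean functions *without* random intercepts (the
    counterfactual arm's intercept is unidentified for a given cluster; the
    estimand conditions on covariates only).  The draw's SACE averages tau
    over the individuals currently labelled always-survivor (NaN when that
    set is empty).
    """
    X = prep_or_X.X if isinstance(prep_or_X, _Prepared) else prep_or_X
    m1 = state.outcome_set[(G11, 1)].predict(X)
    m0 = state.outcome_set[(G11, 0)].predict(X)
    tau = m1 - m0
    mask = state.G == G11
    sace = float(tau[mask].mean()) if mask.any() else float("nan")
    return tau, sace


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_mcmc(data: TrialDataset, config: SamplerConfig,
             outcome_engine: str = "bart", membership_engine: str = "bart",
             progress: bool = False) -> PosteriorDraws:
    """Initialize and run the full chain; retain post-burn-in, thinned draws."""
    prep = _prepare(data)
    rng = np.random.default_rng(config.seed)
    state = initialize_chain(data, config, rng, outcome_engine,
                             membership_engine, prep=prep)

    n_keep = (config.n_iter - config.n_burn + config.thin - 1) // config.thin
    n = prep.X.shape[0]
    G_draws = np.empty((n_keep, n), dtype=np.int8)
    tau_draws = np.full((n_keep, n), np.nan, dtype=np.float32)
    sace_draws = np.full(n_keep, np.nan)
    pi_draws = np.empty((n_keep, 3))
    kept = 0
    n_degenerate = 0
    t0 = time.time()
    for it in range(config.n_iter):
        gibbs_step(state, prep, config, rng)
        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
            tau, sace = compute_csace_draw(state, prep)
            G_draws[kept] = state.G
            tau_draws[kept] = tau
            sace_draws[kept] = sace
            if np.isnan(sace):
                n_degenerate += 1
            pi_draws[kept] = [(state.G == g).mean() for g in (G00, G10, G11)]
            kept += 1
        if progress and (it + 1) % 100 == 0:
            pi = [(state.G == g).mean() for g in (G00, G10, G11)]
            print(f"iter {it + 1}/{config.n_iter}  "
                  f"pi=({pi[0]:.3f}, {pi[1]:.3f}, {pi[2]:.3f})  "
                  f"[{time.time() - t0:.1f}s]", flush=True)

    return PosteriorDraws(G=G_draws[:kept], tau=tau_draws[:kept],
                          sace=sace_draws[:kept], pi=pi_draws[:kept],
                          n_degenerate=n_degenerate, config=config,
                          covariate_names=prep.covariate_names)
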
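"""Nested-Probit principal-stratum machinery.

Two latent Gaussians with unit variance drive stratum membership under
monotonicity: Q separates never-survivors (Q <= 0) from the survivor-capable
strata, and W splits the latter into protected (W <= 0) versus
always-survivors (W > 0).  Marginalizing the latents gives

    p00 = 1 - Phi(mQ),   p10 = Phi(mQ)(1 - Phi(mW)),   p11 = Phi(mQ) Phi(mW).

This module provides the membership probabilities, truncated-normal latent
draws, and the stratum-label full conditionals for each observation pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .bart import MixedBartModel, bart_sweep
from .data import G00, G10, G11, ObservationPattern

__all__ = [
    "MembershipState",
    "MembershipProbabilities",
    "stratum_probabilities",
    "sample_latents",
    "sample_truncated_normal",
    "label_full_conditional",
    "membership_bart_step",
]


@dataclass
class MembershipState:
    """Latent normals and stratum labels for every individual."""

    Q: np.ndarray
    W: np.ndarray
    G: np.ndarray  # integer codes G00/G10/G11

    def check_consistent(self) -> None:
        g = self.G
        ok = np.where(
            g == G00, self.Q <= 0,
            np.where(g == G10, (self.Q > 0) & (self.W <= 0),
                     (self.Q > 0) & (self.W > 0)))
        if not ok.all():
            raise ValueError("latents inconsistent with stratum labels")


@dataclass
class MembershipProbabilities:
    p00: np.ndarray
    p10: np.ndarray
    p11: np.ndarray

    def as_matrix(self) -> np.ndarray:
        return np.stack([np.atleast_1d(self.p00), np.atleast_1d(self.p10),
                         np.atleast_1d(self.p11)], axis=-1)


def stratum_probabilities(mQ, mW) -> MembershipProbabilities:
    """Membership probabilities implied by the nested-Probit means."""
    a = ndtr(np.asarray(mQ, float))
    b = ndtr(np.asarray(mW, float))
    p00 = 1.0 - a
    p10 = a * (1.0 - b)
    p11 = a * b
    total = p00 + p10 + p11
    return MembershipProbabilities(p00 / total, p10 / total, p11 / total)


# ---------------------------------------------------------------------------
# truncated-normal sampling: inverse CDF in the body, Robert's exponential
# rejection in deep tails where the CDF saturates
# ---------------------------------------------------------------------------

_TAIL = 5.0


def _robert_tail(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw standard normals truncated to (a, inf) for large a > 0."""
    out = np.empty_like(a)
    todo = np.ones(len(a), dtype=bool)
    lam = (a + np.sqrt(a * a + 4.0)) / 2.0
    while todo.any():
        idx = np.nonzero(todo)[0]
        x = a[idx] + rng.exponential(1.0, len(idx)) / lam[idx]
        accept = rng.random(len(idx)) <= np.exp(-0.5 * (x - lam[idx]) ** 2)
        out[idx[accept]] = x[accept]
        todo[idx[accept]] = False
    return out


def sample_truncated_normal(mean, lower, upper,
                            rng: np.random.Generator) -> np.ndarray:
    """Vectorized N(mean, 1) draws truncated to (lower, upper).

    Bounds may be -inf/inf elementwise.  One-sided truncations further than
    ``_TAIL`` standard deviations from the mean use exponential rejection;
    everything else uses the inverse CDF.
    """
    mean = np.asarray(mean, float)
    lower = np.broadcast_to(np.asarray(lower, float), mean.shape).copy()
    upper = np.broadcast_to(np.asarray(upper, float), mean.shape).copy()
    a = lower - mean
    b = upper - mean
    out = np.empty_like(mean)

    deep_lo = (a > _TAIL) & np.isinf(b)      # truncated to a far right tail
    deep_hi = (b < -_TAIL) & np.isinf(a)     # far left tail, by symmetry
    body = ~(deep_lo | deep_hi)

    if body.any():
        pa = ndtr(a[body])
        pb = ndtr(b[body])
        u = rng.random(int(body.sum()))
        out[body] = ndtri(pa + u * (pb - pa))
        # guard against saturation at the float boundary
        out[body] = np.clip(out[body], a[body], b[body])
    if deep_lo.any():
        out[deep_lo] = _robert_tail(a[deep_lo], rng)
    if deep_hi.any():
        out[deep_hi] = -_robert_tail(-b[deep_hi], rng)
    return mean + out


def sample_latents(G: np.ndarray, mQ, mW,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (Q, W) from their truncated-normal full conditionals given labels.

    Q is truncated to (-inf, 0] for never-survivors and (0, inf) otherwise.
    W is truncated to (-inf, 0] for protected, (0, inf) for always-survivors,
    and left untruncated for never-survivors (the split rule constrains W only
    within the survivor-capable group).
    """
    G = np.asarray(G)
    mQ = np.broadcast_to(np.asarray(mQ, float), G.shape)
    mW = np.broadcast_to(np.asarray(mW, float), G.shape)
    lo_q = np.where(G == G00, -np.inf, 0.0)
    hi_q = np.where(G == G00, 0.0, np.inf)
    Q = sample_truncated_normal(mQ, lo_q, hi_q, rng)
    lo_w = np.where(G == G11, 0.0, -np.inf)
    hi_w = np.where(G == G10, 0.0, np.inf)
    W = sample_truncated_normal(mW, lo_w, hi_w, rng)
    return Q, W


# ---------------------------------------------------------------------------
# stratum-label full conditionals per observation pattern
# ---------------------------------------------------------------------------

def label_full_conditional(pattern: ObservationPattern, Z: int,
                           probs, dens11: float | None = None,
                           dens10: float | None = None) -> np.ndarray:
    """Posterior distribution over (00, 10, 11) for one individual.

    ``probs`` is a MembershipProbabilities (scalar entries) or a length-3
    sequence (p00, p10, p11).  Outcome densities are required exactly for
    treated survivors with an observed outcome, where the label mixes
    {10, 11} weighted by the arm-stratum outcome likelihoods; supplying a
    density for an inadmissible stratum raises.
    """
    if isinstance(probs, MembershipProbabilities):
        p = np.array([float(probs.p00), float(probs.p10), float(probs.p11)])
    else:
        p = np.asarray(probs, float)

    if pattern == ObservationPattern.DEATH_TRUNCATION:
        if dens11 is not None or dens10 is not None:
            raise ValueError("outcome density supplied for a non-survivor")
        if Z == 1:
            w = np.array([1.0, 0.0, 0.0])       # treated non-survivor: 00
        else:
            w = np.array([p[0], p[1], 0.0])     # control non-survivor: {00,10}
    elif pattern == ObservationPattern.STATUS_OUTCOME_MISSING:
        if dens11 is not None or dens10 is not None:
            raise ValueError("outcome density supplied without observed data")
        w = p.copy()
    elif pattern in (ObservationPattern.COMPLETE_SURVIVOR,
                     ObservationPattern.SURVIVOR_OUTCOME_MISSING):
        if Z == 0:
            # survivors under control are always-survivors by monotonicity
            if dens10 is not None:
                raise ValueError("protected outcome density inadmissible "
                                 "for control survivors")
            w = np.array([0.0, 0.0, 1.0])
        elif pattern == ObservationPattern.COMPLETE_SURVIVOR:
            if dens11 is None or dens10 is None:
                raise ValueError("treated survivors with observed outcomes "
                                 "need both outcome densities")
            w = np.array([0.0, p[1] * dens10, p[2] * dens11])
        else:
            # missing outcome integrates out under nested MAR
            if dens11 is not None or dens10 is not None:
                raise ValueError("outcome density supplied for a missing "
                                 "outcome")
            w = np.array([0.0, p[1], p[2]])
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate label full conditional")
    return w / total


def membership_bart_step(state: MembershipState, modelQ: MixedBartModel,
                         modelW: MixedBartModel, XQ: np.ndarray,
                         XW: np.ndarray, clusters: np.ndarray,
                         rng: np.random.Generator,
                         cache_token: object = None
                         ) -> tuple[MixedBartModel, MixedBartModel]:
    """One mixed-effects BART sweep of mQ on (XQ, Q) and mW on (XW, W).

    The two regressions are independent given the current latents; both run
    in probit-latent mode (unit residual variance) and include their cluster
    random-intercept updates.
    """
    bart_sweep(modelQ, XQ, state.Q, clusters, rng, cache_token)
    bart_sweep(modelW, XW, state.W, clusters, rng, cache_token)
    return modelQ, modelW
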
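"""Product-limit estimation and inverse-probability-of-censoring weights.

``kaplan_meier`` is the standard (optionally weighted) product-limit
estimator; ``reverse_kaplan_meier`` flips the event indicators to estimate
the censoring survival function ``G(t) = P(C > t)``, valid when censoring
is independent of the covariates given the arm.  ``ipcw_weights`` forms
``W_i = delta_i / G_hat(T_i^-)``: uncensored subjects are up-weighted by the
inverse probability that they escaped censoring, censored subjects get
weight zero.  ``E[delta / G(T^-)] = 1``, so the weights restore unbiased
averages over the latent event-time law.

Ties between events and censorings at the same time are handled with the
usual convention that events precede censorings in the risk-set bookkeeping.
"""

from __future__ import annotations

import logging

import numpy as np

from .data import StepSurvival

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT_FLOOR = 1e-10


def _check_sample(times, events, weights=None):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValueError("empty sample")
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be 1-d arrays of equal length")
    if np.any(t <= 0):
        raise ValueError("all times must be positive")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValueError("events must be 0/1")
    if weights is None:
        w = np.ones_like(t)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != t.shape or np.any(w < 0):
            raise ValueError("weights must be nonnegative and aligned with times")
    return t, e, w


def kaplan_meier(times, events, weights=None) -> StepSurvival:
    """(Weighted) product-limit survival estimator.

    ``S(t) = prod_{t_j <= t} (1 - d_j / Y_j)`` over distinct event times
    ``t_j``, with ``d_j`` the (weighted) events and ``Y_j`` the (weighted)
    number at risk.  Censored-only times induce no jump.
    """
    t, e, w = _check_sample(times, events, weights)
    order = np.argsort(t, kind="stable")
    t, e, w = t[order], e[order], w[order]
    ut, inv = np.unique(t, return_inverse=True)
    d = np.bincount(inv, weights=w * e, minlength=ut.size)
    at_risk = np.cumsum(np.bincount(inv, weights=w, minlength=ut.size)[::-1])[::-1]
    jumps = d > 0
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - d[jumps] / at_risk[jumps])
    return StepSurvival(ut[jumps], np.clip(surv, 0.0, 1.0))


def reverse_kaplan_meier(times, events) -> StepSurvival:
    """Product-limit estimator of the censoring survival ``G(t) = P(C > t)``.

    Identical to :func:`kaplan_meier` with the event indicators flipped.
    """
    t, e, _ = _check_sample(times, events)
    return kaplan_meier(t, 1.0 - e)


def ipcw_weights(times, events, g_hat: StepSurvival,
                 floor: float = DEFAULT_WEIGHT_FLOOR) -> np.ndarray:
    """Weights ``W_i = delta_i / max(G_hat(T_i^-), floor)``.

    ``G_hat`` is evaluated at the left limit, the standard choice that keeps
    the weight of the largest observation finite when it is an event.  The
    floor guards against division blow-up when ``G_hat`` reaches zero inside
    the observed range.
    """
    t, e, _ = _check_sample(times, events)
    if not (0 < floor < 1):
        raise ValueError("floor must lie in (0, 1)")
    g = g_hat.evaluate_left(t)
    if np.any((g < floor) & (e == 1)):
        logger.warning(
            "IPCW weight floor %.1e triggered for %d observation(s); "
            "censoring survival is ~0 at some event times", floor,
            int(np.sum((g < floor) & (e == 1))),
        )
    return e / np.maximum(g, floor)
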
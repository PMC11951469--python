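"""Comparator estimators: Naive (uncensored-only) embeddings and the
IPTW-adjusted Kaplan-Meier (AKME).

The Naive method runs the identical counterfactual-embedding pipeline with
weights ``W_i = delta_i``, i.e. it keeps only uncensored observations and
applies no inverse-censoring correction; it is consistent only when
censoring is absent and is inefficient/biased otherwise.

AKME adjusts for confounding through the treatment-assignment mechanism
instead of the outcome model: a linear logistic propensity model
``e(x) = P(Z=1 | X=x)`` supplies inverse-probability-of-treatment weights
(``1/e`` in the treated arm, ``1/(1-e)`` in the control arm), and each
arm's survival curve is the weighted product-limit estimator under those
weights.  Propensities are truncated to ``[0.01, 0.99]`` to guard against
extreme weights.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.linear_model import LogisticRegression

from .censoring import kaplan_meier
from .data import StepSurvival, SurvivalDataset
from .effects import EffectCurves, EstimatorConfig, estimate_effect_curves

PROPENSITY_TRUNCATION = (0.01, 0.99)


def naive_effect_curves(data: SurvivalDataset, grid=None,
                        config: EstimatorConfig | None = None) -> EffectCurves:
    """Effect curves with embedding weights ``W_i = delta_i`` (no censoring
    correction); the arm-wise Kaplan-Meier curves are unchanged."""
    config = config or EstimatorConfig()
    if config.weight_mode != "naive":
        config = replace(config, weight_mode="naive")
    return estimate_effect_curves(data, grid, config)


def propensity_scores(data: SurvivalDataset) -> np.ndarray:
    """Linear-in-covariates logistic propensity ``e(X) = P(Z=1 | X)``."""
    data.require_two_arms()
    model = LogisticRegression(C=np.inf, max_iter=2000)
    model.fit(data.covariates, data.treatment)
    e = model.predict_proba(data.covariates)[:, 1]
    if np.any(e <= 1e-8) or np.any(e >= 1 - 1e-8):
        raise ValueError(
            "propensity separation: fitted scores reach 0/1; IPTW weights undefined"
        )
    return e


def akme_survival(data: SurvivalDataset, arm: int, grid=None) -> StepSurvival:
    """IPTW-weighted Kaplan-Meier curve of one arm (marginal counterfactual
    survival under assignment to that arm)."""
    if arm not in (0, 1):
        raise ValueError("arm must be 0 or 1")
    e = np.clip(propensity_scores(data), *PROPENSITY_TRUNCATION)
    mask = data.treatment == arm
    weights = 1.0 / e[mask] if arm == 1 else 1.0 / (1.0 - e[mask])
    return kaplan_meier(data.times[mask], data.events[mask], weights=weights)


def akme_gain(data: SurvivalDataset, grid) -> np.ndarray:
    """AKME estimate of the counterfactual survival gain
    ``d_hat(t) = S_AKME,1(t) - S_AKME,0(t)`` on the grid."""
    grid = np.asarray(grid, dtype=float)
    s1 = akme_survival(data, 1)(grid)
    s0 = akme_survival(data, 0)(grid)
    return s1 - s0
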
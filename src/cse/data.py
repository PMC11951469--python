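"""Core containers: right-censored observational datasets and step survival curves.

A subject contributes the observed time ``T* = min(T, C)``, the event
indicator ``delta = 1{T <= C}``, a binary treatment arm ``Z`` and a numeric
covariate row ``X``.  Survival-curve estimates produced anywhere in the
package are right-continuous piecewise-constant functions represented by
:class:`StepSurvival`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class StepSurvival:
    """Right-continuous step function ``S(t)`` with ``S(t) = 1`` before the first jump.

    Parameters
    ----------
    jump_times : strictly increasing positive times at which the curve drops.
    values : value of ``S`` on ``[jump_times[j], jump_times[j+1])``; must be
        non-increasing and contained in ``[0, 1]``.
    """

    jump_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        jt = np.asarray(self.jump_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if jt.ndim != 1 or v.shape != jt.shape:
            raise ValueError("jump_times and values must be 1-d arrays of equal length")
        if jt.size and (np.any(np.diff(jt) <= 0) or jt[0] <= 0):
            raise ValueError("jump_times must be strictly increasing and positive")
        if v.size and (np.any(np.diff(v) > 1e-12) or v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("values must be non-increasing within [0, 1]")
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    def __call__(self, t) -> np.ndarray:
        """Evaluate ``S(t)`` (right-continuous)."""
        ext = np.concatenate([[1.0], self.values])
        return ext[np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="right")]

    def evaluate_left(self, t) -> np.ndarray:
        """Evaluate the left limit ``S(t-)``."""
        ext = np.concatenate([[1.0], self.values])
        return ext[np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="left")]


@dataclass(frozen=True)
class SurvivalDataset:
    """Per-subject table ``(T*, delta, Z, X)`` of a right-censored two-arm study."""

    times: np.ndarray
    events: np.ndarray
    treatment: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple = field(default=())

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        z = np.asarray(self.treatment, dtype=int)
        x = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if x.shape[0] != t.size:
            x = x.T
        n = t.size
        if not (e.size == z.size == x.shape[0] == n):
            raise ValueError("times, events, treatment and covariates must have equal row counts")
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            bad = np.flatnonzero(~(np.isfinite(t) & (t > 0)))
            raise ValueError(f"non-positive or non-finite times at rows {bad.tolist()[:10]}")
        for name, arr in (("events", e), ("treatment", z)):
            if not np.isin(arr, (0, 1)).all():
                bad = np.flatnonzero(~np.isin(arr, (0, 1)))
                raise ValueError(f"non-binary {name} at rows {bad.tolist()[:10]}")
        if np.any(~np.isfinite(x)):
            bad = np.flatnonzero(~np.isfinite(x).all(axis=1))
            raise ValueError(f"missing/non-finite covariates at rows {bad.tolist()[:10]}")
        names = tuple(self.covariate_names) or tuple(f"x{j+1}" for j in range(x.shape[1]))
        if len(names) != x.shape[1]:
            raise ValueError("covariate_names length does not match covariate columns")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        object.__setattr__(self, "treatment", z)
        object.__setattr__(self, "covariates", x)
        object.__setattr__(self, "covariate_names", names)

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def arm(self, z: int) -> "SurvivalDataset":
        """Rows of one treatment arm."""
        m = self.treatment == z
        if not m.any():
            raise ValueError(f"arm {z} is empty")
        return SurvivalDataset(
            self.times[m], self.events[m], self.treatment[m], self.covariates[m],
            self.covariate_names,
        )

    def require_two_arms(self) -> None:
        if not ((self.treatment == 0).any() and (self.treatment == 1).any()):
            raise ValueError("both treatment arms must be nonempty for causal operations")
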
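"""Gaussian-process Bayesian search over hyperparameter spaces.

Expected-improvement search with a Matern-5/2 GP surrogate on the unit
cube. The budget is exact: the objective is evaluated precisely ``n_iter``
times (or once, if the space contains a single point). Deterministic per
seed; the full trial log is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

__all__ = ["SearchSpace", "OptimizationResult", "bayesian_optimize"]


class SearchSpace:
    """Named hyperparameter dimensions.

    Each entry is either a discrete list of values or a tuple
    ``(low, high, scale)`` with scale ``"linear"``, ``"log"`` or ``"int"``.
    """

    def __init__(self, space: dict):
        if not space:
            raise ValueError("search space must have at least one dimension")
        self.names = sorted(space)
        self.dims = {name: space[name] for name in self.names}

    @property
    def is_single_point(self) -> bool:
        for dim in self.dims.values():
            if isinstance(dim, (list, tuple)) and not self._is_range(dim):
                if len(dim) > 1:
                    return False
            else:
                lo, hi, _ = dim
                if lo != hi:
                    return False
        return True

    @staticmethod
    def _is_range(dim) -> bool:
        return (isinstance(dim, tuple) and len(dim) == 3
                and dim[2] in ("linear", "log", "int"))

    def decode(self, u: np.ndarray) -> dict:
        """Unit-cube coordinates -> hyperparameter dict."""
        params = {}
        for x, name in zip(u, self.names):
            dim = self.dims[name]
            if self._is_range(dim):
                lo, hi, scale = dim
                if scale == "log":
                    params[name] = float(np.exp(np.log(lo) + x * (np.log(hi) - np.log(lo))))
                elif scale == "int":
                    params[name] = int(round(lo + x * (hi - lo)))
                else:
                    params[name] = float(lo + x * (hi - lo))
            else:
                values = list(dim)
                params[name] = values[min(int(x * len(values)), len(values) - 1)]
        return params

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.random((n, len(self.names)))


@dataclass
class OptimizationResult:
    best_params: dict
    best_value: float
    trials: list = field(default_factory=list)  # (params, value) in evaluation order

    @property
    def n_evaluations(self) -> int:
        return len(self.trials)


def bayesian_optimize(objective, space: dict | SearchSpace, n_iter: int = 100,
                      seed: int = 0, n_initial: int = 10,
                      n_candidates: int = 256) -> OptimizationResult:
    """Maximize ``objective(params_dict)`` with GP expected improvement.

    Failed evaluations (objective raising) are logged with value NaN and
    excluded from the surrogate; if every trial fails the search raises
    with the trial log attached.
    """
    if not isinstance(space, SearchSpace):
        space = SearchSpace(space)
    rng = np.random.default_rng(seed)
    trials: list[tuple[dict, float]] = []
    xs: list[np.ndarray] = []
    ys: list[float] = []

    def evaluate(u: np.ndarray) -> None:
        params = space.decode(u)
        try:
            value = float(objective(params))
        except Exception:
            trials.append((params, float("nan")))
            return
        trials.append((params, value))
        xs.append(u)
        ys.append(value)

    if space.is_single_point:
        evaluate(np.zeros(len(space.names)))
    else:
        n_initial = min(n_initial, n_iter)
        for u in space.sample(rng, n_initial):
            evaluate(u)
        kernel = Matern(nu=2.5, length_scale=np.full(len(space.names), 0.3))
        while len(trials) < n_iter:
            if len(ys) >= 2:
                gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                              alpha=1e-6, random_state=int(rng.integers(2**31)))
                gp.fit(np.vstack(xs), np.asarray(ys))
                cand = space.sample(rng, n_candidates)
                mu, sd = gp.predict(cand, return_std=True)
                best = max(ys)
                sd = np.clip(sd, 1e-12, None)
                z = (mu - best) / sd
                ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
                u_next = cand[int(np.argmax(ei))]
            else:
                u_next = space.sample(rng, 1)[0]
            evaluate(u_next)

    if not ys:
        err = RuntimeError(f"all {len(trials)} optimization trials failed")
        err.trials = trials  # type: ignore[attr-defined]
        raise err
    best_idx = int(np.argmax(ys))
    best_params = space.decode(xs[best_idx])
    return OptimizationResult(best_params=best_params, best_value=float(ys[best_idx]),
                              trials=trials)
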
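"""Monte Carlo stability of the ordination under score noise.

Each replicate perturbs every real-entity score with independent noise
(uniform on +/- half_width score units by default, optionally Gaussian with
sd = half_width), clips back into [1, 6], and re-runs the full ordination
with the same configuration and seed. The Monte Carlo index is the
per-entity median across replicates; its absolute difference from the
deterministic index is the stability diagnostic. Differences below 5 index
points mark a sufficient ordination, below 1 point a tolerable error level;
both are reported as flags, never raised as errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import InputError
from .matrix import MULTI, SCORE_MAX, SCORE_MIN, ScoreMatrix
from .ordination import OrdinationConfig, ordinate

SUFFICIENT_DIFF = 5.0
TOLERABLE_DIFF = 1.0


@dataclass
class MonteCarloResult:
    dimension: str
    reps: int
    noise: str
    half_width: float
    seed: int
    mds_index: pd.Series
    mc_index: pd.Series  # per-entity median over replicates
    diff: pd.Series  # |mds - mc|
    rep_indices: pd.DataFrame  # reps x entities

    @property
    def max_diff(self) -> float:
        return float(self.diff.max())

    @property
    def sufficient(self) -> bool:
        return self.max_diff < SUFFICIENT_DIFF

    @property
    def tolerable(self) -> bool:
        return self.max_diff < TOLERABLE_DIFF

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "reps": self.reps,
            "noise": self.noise,
            "half_width": self.half_width,
            "seed": self.seed,
            "mds_index": {k: float(v) for k, v in self.mds_index.items()},
            "mc_index": {k: float(v) for k, v in self.mc_index.items()},
            "diff": {k: float(v) for k, v in self.diff.items()},
            "max_diff": self.max_diff,
            "sufficient": self.sufficient,
            "tolerable": self.tolerable,
        }


class MonteCarloStability(BaseEstimator):
    """Replicated noisy re-ordination as a scikit-learn estimator.

    Attributes after :meth:`fit`: ``mc_index_`` (per-entity median index),
    ``diff_`` (|deterministic - Monte Carlo|), ``rep_indices_``,
    ``sufficient_`` and ``tolerable_`` flags.
    """

    def __init__(
        self,
        dimension: str = MULTI,
        reps: int = 25,
        noise: str = "uniform",  # "uniform" | "gaussian"
        half_width: float = 0.25,
        n_anchor_pairs: int = 1,
        n_restarts: int = 4,
        max_iter: int = 1000,
        tol: float = 1e-9,
        stress_formula: str = "sstress",
        random_state: int = 20210923,
    ):
        self.dimension = dimension
        self.reps = reps
        self.noise = noise
        self.half_width = half_width
        self.n_anchor_pairs = n_anchor_pairs
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.stress_formula = stress_formula
        self.random_state = random_state

    def _config(self) -> OrdinationConfig:
        return OrdinationConfig(
            n_anchor_pairs=self.n_anchor_pairs,
            n_restarts=self.n_restarts,
            mds_max_iter=self.max_iter,
            mds_tolerance=self.tol,
            seed=self.random_state,
            stress_formula=self.stress_formula,
        )

    def fit(self, X: ScoreMatrix, y=None) -> "MonteCarloStability":
        if self.reps < 1:
            raise InputError("reps must be >= 1")
        if self.half_width < 0:
            raise InputError("noise half-width must be >= 0")
        if self.noise not in ("uniform", "gaussian"):
            raise InputError(f"noise must be 'uniform' or 'gaussian', got {self.noise!r}")
        matrix = X if isinstance(X, ScoreMatrix) else ScoreMatrix.from_scores(X)
        sub = matrix.select(self.dimension)
        cfg = self._config()
        base = ordinate(sub, MULTI, cfg)

        rows = []
        for rep in range(self.reps):
            rng = np.random.default_rng([self.random_state & 0x7FFFFFFF, 1000 + rep])
            if self.half_width == 0:
                noisy = sub.scores.values.copy()
            elif self.noise == "uniform":
                noisy = sub.scores.values + rng.uniform(
                    -self.half_width, self.half_width, size=sub.scores.shape
                )
            else:
                noisy = sub.scores.values + rng.normal(
                    0.0, self.half_width, size=sub.scores.shape
                )
            noisy = np.clip(noisy, SCORE_MIN, SCORE_MAX)
            perturbed = ScoreMatrix(
                scores=pd.DataFrame(noisy, index=sub.scores.index, columns=sub.scores.columns),
                attributes=sub.attributes,
            )
            rows.append(ordinate(perturbed, MULTI, cfg).index)

        rep_indices = pd.DataFrame(rows, index=pd.RangeIndex(self.reps, name="rep"))
        self.mds_index_ = base.index
        self.mc_index_ = rep_indices.median(axis=0)
        self.diff_ = (self.mds_index_ - self.mc_index_).abs()
        self.rep_indices_ = rep_indices
        self.sufficient_ = bool(self.diff_.max() < SUFFICIENT_DIFF)
        self.tolerable_ = bool(self.diff_.max() < TOLERABLE_DIFF)
        return self

    def result_(self) -> MonteCarloResult:
        if not hasattr(self, "mc_index_"):
            raise InputError("estimator is not fitted")
        return MonteCarloResult(
            dimension=self.dimension,
            reps=self.reps,
            noise=self.noise,
            half_width=self.half_width,
            seed=self.random_state,
            mds_index=self.mds_index_,
            mc_index=self.mc_index_,
            diff=self.diff_,
            rep_indices=self.rep_indices_,
        )


def monte_carlo(
    matrix: ScoreMatrix,
    dimension: str = MULTI,
    reps: int = 25,
    noise: str = "uniform",
    half_width: float = 0.25,
    seed: int = 20210923,
    config: OrdinationConfig | None = None,
) -> MonteCarloResult:
    """Functional wrapper over :class:`MonteCarloStability`."""
    cfg = config or OrdinationConfig(seed=seed)
    est = MonteCarloStability(
        dimension=dimension,
        reps=reps,
        noise=noise,
        half_width=half_width,
        n_anchor_pairs=cfg.n_anchor_pairs,
        n_restarts=cfg.n_restarts,
        max_iter=cfg.mds_max_iter,
        tol=cfg.mds_tolerance,
        stress_formula=cfg.stress_formula,
        random_state=seed,
    )
    return est.fit(matrix).result_()
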
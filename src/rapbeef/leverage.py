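"""Attribute leverage: drop-one re-ordination summarized as an RMS.

For each attribute j in a dimension, the dimension is re-ordinated without
j (anchors rebuilt for the reduced attribute set, identical configuration
and seed) and the change in each real entity's sustainability index is
summarized as RMS_j = sqrt(mean_e (index_without_j(e) - index_full(e))^2),
in absolute index points. A larger RMS marks a more sensitive indicator.
References/anchors never enter the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import InputError
from .matrix import MULTI, ScoreMatrix
from .ordination import OrdinationConfig, ordinate


@dataclass
class LeverageProfile:
    dimension: str
    rms: pd.Series  # per attribute, descending (stable tie order = column order)
    index_full: pd.Series

    @property
    def ranking(self) -> list[str]:
        return [str(a) for a in self.rms.index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"attribute": self.rms.index, "rms": self.rms.values, "rank": np.arange(1, len(self.rms) + 1)}
        )


class LeverageAnalysis(BaseEstimator):
    """Drop-one attribute sensitivity as a scikit-learn estimator.

    Attributes after :meth:`fit`: ``rms_`` (Series, sorted descending with
    stable ties), ``ranking_`` (attribute ids by decreasing leverage),
    ``index_full_`` (the reference indices of the untouched ordination).
    """

    def __init__(
        self,
        dimension: str = MULTI,
        n_anchor_pairs: int = 1,
        n_restarts: int = 4,
        max_iter: int = 1000,
        tol: float = 1e-9,
        stress_formula: str = "sstress",
        random_state: int = 20210923,
    ):
        self.dimension = dimension
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

    def fit(self, X: ScoreMatrix, y=None) -> "LeverageAnalysis":
        matrix = X if isinstance(X, ScoreMatrix) else ScoreMatrix.from_scores(X)
        sub = matrix.select(self.dimension)
        attrs = list(sub.scores.columns)
        if len(attrs) < 3:
            raise InputError(
                f"dimension {self.dimension!r} has only {len(attrs)} attributes; "
                "leverage needs >= 3 so each drop leaves an ordinatable set"
            )
        cfg = self._config()
        full = ordinate(sub, MULTI, cfg)
        rms_values = {}
        for attr in attrs:
            reduced = ordinate(sub.drop_attribute(attr), MULTI, cfg)
            diff = reduced.index - full.index
            rms_values[attr] = float(np.sqrt(np.mean(np.square(diff.values))))
        rms = pd.Series(rms_values, name="rms")
        # descending sort, stable within ties so original attribute order wins
        rms = rms.sort_values(ascending=False, kind="stable")
        self.rms_ = rms
        self.ranking_ = [str(a) for a in rms.index]
        self.index_full_ = full.index
        return self

    def result_(self) -> LeverageProfile:
        if not hasattr(self, "rms_"):
            raise InputError("estimator is not fitted")
        return LeverageProfile(self.dimension, self.rms_, self.index_full_)


def leverage_profile(
    matrix: ScoreMatrix,
    dimension: str = MULTI,
    config: OrdinationConfig | None = None,
) -> LeverageProfile:
    """Functional wrapper over :class:`LeverageAnalysis`."""
    cfg = config or OrdinationConfig()
    est = LeverageAnalysis(
        dimension=dimension,
        n_anchor_pairs=cfg.n_anchor_pairs,
        n_restarts=cfg.n_restarts,
        max_iter=cfg.mds_max_iter,
        tol=cfg.mds_tolerance,
        stress_formula=cfg.stress_formula,
        random_state=cfg.seed,
    )
    return est.fit(matrix).result_()
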
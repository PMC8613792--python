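"""Anchored MDS ordination and the 0-100 sustainability index.

The score matrix is augmented with reference profiles — GOOD (every
attribute at its best score 6) and BAD (every attribute at 1) — plus
optional anchor pairs of mixed best/worst patterns that stabilize the
second ordination axis. Attribute scores are normalized so worst maps to 0
and best to 100, pairwise Euclidean distances are embedded in two
dimensions by SMACOF, the configuration is rigidly rotated so the BAD to
GOOD direction becomes the horizontal axis, and each entity's horizontal
position is rescaled so BAD sits at 0 and GOOD at 100. Entities ordinating
slightly beyond the references are clipped into [0, 100] so the status
bands apply.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .errors import DegenerateConfigurationError, InputError
from .indicators import classify_status
from .matrix import MULTI, SCORE_MAX, SCORE_MIN, ScoreMatrix
from . import mds

GOOD, BAD = "GOOD", "BAD"

DEFAULT_SEED = 20210923


@dataclass
class OrdinationConfig:
    """Run configuration for one ordination."""

    n_anchor_pairs: int = 1
    n_restarts: int = 4
    mds_max_iter: int = 1000
    mds_tolerance: float = 1e-9
    seed: int = DEFAULT_SEED
    stress_formula: str = "sstress"  # "sstress" | "stress1"

    def __post_init__(self) -> None:
        if self.n_anchor_pairs < 0:
            raise InputError("n_anchor_pairs must be >= 0")
        if self.n_restarts < 1:
            raise InputError("n_restarts must be >= 1")
        if self.mds_tolerance <= 0:
            raise InputError("mds_tolerance must be > 0")
        if self.stress_formula not in ("sstress", "stress1"):
            raise InputError(f"bad stress_formula {self.stress_formula!r}")


@dataclass
class ReferenceSet:
    """Score rows of real entities plus reference profiles."""

    frame: pd.DataFrame  # entities first, then GOOD, BAD, anchors
    entity_labels: list[str]
    reference_labels: list[str]  # [GOOD, BAD, anchors...]

    @property
    def good_index(self) -> int:
        return len(self.entity_labels)

    @property
    def bad_index(self) -> int:
        return len(self.entity_labels) + 1


def _anchor_pattern(pair: int, columns) -> np.ndarray:
    """Deterministic best/worst mask for anchor pair ``pair`` (1-based).

    Patterns are laid out over the attributes in sorted-label order — pair 1
    marks the first half best, higher pairs use progressively finer
    alternating blocks — so the reference set depends only on the attribute
    label set, not on column order.
    """
    n_attributes = len(columns)
    block = max(1, n_attributes // (2 * pair))
    rank = np.argsort(np.argsort([str(c) for c in columns], kind="stable"))
    return (rank // block) % 2 == 0


def build_reference_set(matrix: ScoreMatrix, config: OrdinationConfig) -> ReferenceSet:
    """Append GOOD/BAD and anchor rows to the real-entity scores."""
    p = matrix.scores.shape[1]
    if p < 2:
        raise InputError(f"need at least 2 attributes to ordinate, got {p}")
    entities = matrix.entities
    ref_rows: dict[str, np.ndarray] = {
        GOOD: np.full(p, SCORE_MAX),
        BAD: np.full(p, SCORE_MIN),
    }
    for k in range(1, config.n_anchor_pairs + 1):
        mask = _anchor_pattern(k, matrix.scores.columns)
        ref_rows[f"ANCHOR_{k}A"] = np.where(mask, SCORE_MAX, SCORE_MIN)
        ref_rows[f"ANCHOR_{k}B"] = np.where(mask, SCORE_MIN, SCORE_MAX)
    clash = set(entities) & set(ref_rows)
    if clash:
        raise InputError(f"entity ids collide with reference labels: {sorted(clash)}")
    ref = pd.DataFrame(ref_rows, index=matrix.scores.columns).T
    frame = pd.concat([matrix.scores, ref])
    return ReferenceSet(frame=frame, entity_labels=entities, reference_labels=list(ref_rows))


def normalize_scores(rows: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Linearly map each attribute so worst (1) -> 0 and best (6) -> 100."""
    values = np.asarray(rows, dtype=float)
    return (values - SCORE_MIN) / (SCORE_MAX - SCORE_MIN) * 100.0


def mds_ordinate(
    distances: np.ndarray,
    config: OrdinationConfig,
    row_keys: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float, mds.MDSSolution]:
    """Embed a dissimilarity matrix in 2-D; return coordinates, S and R2.

    S is the stress variant named by ``config.stress_formula`` (the
    ALSCAL-style S-Stress by default). ``row_keys`` (one integer per row,
    e.g. a row-label hash) makes the random restarts equivariant under row
    permutations, so results do not depend on entity ordering.
    """
    sol = mds.smacof(
        distances,
        n_components=2,
        n_restarts=config.n_restarts,
        max_iter=config.mds_max_iter,
        tol=config.mds_tolerance,
        seed=config.seed,
        row_keys=row_keys,
    )
    S = sol.sstress if config.stress_formula == "sstress" else sol.stress1
    return sol.coordinates, S, sol.r2, sol


def align_axes(
    coordinates: np.ndarray, good_index: int, bad_index: int
) -> np.ndarray:
    """Rigidly rotate so BAD -> GOOD points along +x (distances unchanged)."""
    X = np.asarray(coordinates, dtype=float)
    v = X[good_index] - X[bad_index]
    norm = float(np.hypot(*v))
    if norm < 1e-12:
        raise DegenerateConfigurationError("GOOD and BAD ordinate at the same point")
    c, s = v[0] / norm, v[1] / norm
    R = np.array([[c, s], [-s, c]])
    return X @ R.T


def sustainability_index(
    aligned: np.ndarray, good_index: int, bad_index: int
) -> np.ndarray:
    """Project horizontal positions to [0, 100] with BAD at 0, GOOD at 100."""
    x = np.asarray(aligned, dtype=float)[:, 0]
    span = x[good_index] - x[bad_index]
    if abs(span) < 1e-12:
        raise DegenerateConfigurationError("GOOD and BAD ordinate at the same point")
    index = np.clip(100.0 * (x - x[bad_index]) / span, 0.0, 100.0)
    # the references define the scale; pin them exactly against rounding
    index[good_index] = 100.0
    index[bad_index] = 0.0
    return index


@dataclass
class OrdinationResult:
    """One dimension's ordination: coordinates, fit statistics and indices."""

    dimension: str
    coordinates: pd.DataFrame  # rows: entities then references; columns x, y
    S: float
    r2: float
    stress1: float
    sstress: float
    index: pd.Series  # per real entity, 0-100
    bands: pd.Series  # status label per real entity
    converged: bool
    reference_labels: list[str]

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "S": self.S,
            "r2": self.r2,
            "stress1": self.stress1,
            "sstress": self.sstress,
            "converged": self.converged,
            "index": {k: float(v) for k, v in self.index.items()},
            "bands": dict(self.bands),
            "coordinates": {
                str(k): [float(a), float(b)]
                for k, (a, b) in self.coordinates.iterrows()
            },
        }


class RapOrdination(BaseEstimator):
    """Anchored MDS sustainability ordination as a scikit-learn estimator.

    Parameters
    ----------
    dimension:
        Which attribute dimension to ordinate; ``"multi"`` uses all
        attributes jointly.
    n_anchor_pairs:
        Number of mixed best/worst anchor pairs appended beside GOOD and
        BAD to pin the second axis.
    n_restarts, max_iter, tol:
        SMACOF settings: restarts (classical-scaling start plus seeded
        random starts), iteration cap and relative stress tolerance.
    stress_formula:
        Which stress variant is reported as ``stress_`` (``"sstress"`` or
        ``"stress1"``).
    random_state:
        Integer seed driving all random restarts.

    Attributes (after :meth:`fit`)
    ------------------------------
    coordinates_ : DataFrame of aligned 2-D positions (entities + references)
    index_ : Series of per-entity 0-100 sustainability indices
    bands_ : Series of status-band labels per entity
    stress_, stress1_, sstress_, r2_ : goodness-of-fit statistics
    converged_ : bool, False if SMACOF hit the iteration cap
    """

    def __init__(
        self,
        dimension: str = MULTI,
        n_anchor_pairs: int = 1,
        n_restarts: int = 4,
        max_iter: int = 1000,
        tol: float = 1e-9,
        stress_formula: str = "sstress",
        random_state: int = DEFAULT_SEED,
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

    def fit(self, X: ScoreMatrix | pd.DataFrame, y=None) -> "RapOrdination":
        """Run the full ordination pipeline on a score matrix."""
        matrix = X if isinstance(X, ScoreMatrix) else ScoreMatrix.from_scores(X)
        sub = matrix.select(self.dimension)
        if sub.scores.shape[1] < 2:
            raise InputError(
                f"dimension {self.dimension!r} has {sub.scores.shape[1]} attribute(s); need >= 2"
            )
        refset = build_reference_set(sub, self._config())
        normalized = normalize_scores(refset.frame)
        D = squareform(pdist(normalized))
        labels = refset.entity_labels + refset.reference_labels
        row_keys = np.array([zlib.crc32(str(lb).encode()) for lb in labels])
        coords, S, r2, sol = mds_ordinate(D, self._config(), row_keys=row_keys)
        aligned = align_axes(coords, refset.good_index, refset.bad_index)
        idx_all = sustainability_index(aligned, refset.good_index, refset.bad_index)

        self.coordinates_ = pd.DataFrame(aligned, index=labels, columns=["x", "y"])
        n_ent = len(refset.entity_labels)
        self.index_ = pd.Series(idx_all[:n_ent], index=refset.entity_labels, name="index")
        self.bands_ = self.index_.map(lambda v: classify_status(v).label)
        self.stress_ = S
        self.raw_stress_ = sol.raw_stress
        self.stress1_ = sol.stress1
        self.sstress_ = sol.sstress
        self.r2_ = r2
        self.converged_ = sol.converged
        self.n_iter_ = sol.n_iter
        self.stress_trace_ = sol.stress_trace
        self.reference_labels_ = refset.reference_labels
        self.reference_index_ = pd.Series(
            idx_all[n_ent:], index=refset.reference_labels
        )
        return self

    def transform(self, X=None) -> pd.Series:
        """Return the fitted per-entity sustainability indices."""
        if not hasattr(self, "index_"):
            raise InputError("estimator is not fitted")
        return self.index_

    def fit_transform(self, X, y=None) -> pd.Series:
        return self.fit(X).transform()

    def result_(self) -> OrdinationResult:
        if not hasattr(self, "index_"):
            raise InputError("estimator is not fitted")
        return OrdinationResult(
            dimension=self.dimension,
            coordinates=self.coordinates_,
            S=self.stress_,
            r2=self.r2_,
            stress1=self.stress1_,
            sstress=self.sstress_,
            index=self.index_,
            bands=self.bands_,
            converged=self.converged_,
            reference_labels=self.reference_labels_,
        )


def ordinate(
    matrix: ScoreMatrix,
    dimension: str = MULTI,
    config: OrdinationConfig | None = None,
) -> OrdinationResult:
    """Functional wrapper over :class:`RapOrdination`."""
    cfg = config or OrdinationConfig()
    est = RapOrdination(
        dimension=dimension,
        n_anchor_pairs=cfg.n_anchor_pairs,
        n_restarts=cfg.n_restarts,
        max_iter=cfg.mds_max_iter,
        tol=cfg.mds_tolerance,
        stress_formula=cfg.stress_formula,
        random_state=cfg.seed,
    )
    return est.fit(matrix).result_()


def multidimension_average(results: dict[str, OrdinationResult]) -> pd.Series:
    """Alternative 'multi' index: mean of the per-dimension indices."""
    if not results:
        raise InputError("no per-dimension results to average")
    frame = pd.DataFrame({d: r.index for d, r in results.items()})
    return frame.mean(axis=1)
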
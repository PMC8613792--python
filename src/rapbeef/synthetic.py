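"""Synthetic score matrices with a known latent sustainability ordering.

The generator emulates the scored survey data the appraisal consumes: each
entity e carries a latent sustainability level ``latent_e`` in [0, 1]; its
expected score on every attribute is ``1 + 5 * latent_e``; observed scores
add i.i.d. noise (Gaussian by default, sd in score units), are rounded
half-up and clipped into {1, ..., 6}. Because the ground-truth ordering is
known, the generator supports parameter-recovery tests: a sound ordination
should rank entities close to their latent order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .matrix import ScoreMatrix


@dataclass
class SyntheticSpec:
    """Generator settings.

    ``n_attributes`` maps dimension label -> number of attributes; a plain
    int is shorthand for a single "multi" dimension. ``latent`` may be an
    explicit vector; by default it is drawn uniformly on [0, 1] from the
    seed. ``sd`` is the score-unit noise standard deviation (0.5 default,
    half a scale step).
    """

    n_entities: int = 50
    n_attributes: dict[str, int] | int = 8
    sd: float = 0.5
    noise: str = "gaussian"  # "gaussian" | "uniform"
    latent: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entities < 2:
            raise InputError("n_entities must be >= 2")
        if self.sd < 0:
            raise InputError("sd must be >= 0")
        if self.noise not in ("gaussian", "uniform"):
            raise InputError(f"noise must be 'gaussian' or 'uniform', got {self.noise!r}")


def _round_half_up(values: np.ndarray) -> np.ndarray:
    return np.floor(values + 0.5)


def generate_synthetic(spec: SyntheticSpec) -> tuple[ScoreMatrix, pd.Series]:
    """Draw a score matrix and return it with its latent ground truth."""
    attr_spec = (
        {"multi": spec.n_attributes}
        if isinstance(spec.n_attributes, int)
        else dict(spec.n_attributes)
    )
    total_attrs = sum(attr_spec.values())
    if total_attrs < 2:
        raise InputError("need at least 2 attributes in total")

    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 77])
    if spec.latent is None:
        latent = rng.uniform(0.0, 1.0, size=spec.n_entities)
    else:
        latent = np.asarray(spec.latent, dtype=float)
        if latent.shape != (spec.n_entities,):
            raise InputError("latent vector length must equal n_entities")
        if latent.min() < 0 or latent.max() > 1:
            raise InputError("latent values must lie in [0, 1]")

    expected = 1.0 + 5.0 * latent[:, None]
    if spec.sd == 0:
        noise = np.zeros((spec.n_entities, total_attrs))
    elif spec.noise == "gaussian":
        noise = rng.normal(0.0, spec.sd, size=(spec.n_entities, total_attrs))
    else:
        noise = rng.uniform(-spec.sd, spec.sd, size=(spec.n_entities, total_attrs))
    scores = np.clip(_round_half_up(expected + noise), 1.0, 6.0)

    entity_ids = [f"E{i:03d}" for i in range(spec.n_entities)]
    columns: list[str] = []
    dims: dict[str, str] = {}
    for dim, count in attr_spec.items():
        for j in range(count):
            name = f"{dim[:3].upper()}{j + 1}"
            columns.append(name)
            dims[name] = dim
    frame = pd.DataFrame(scores, index=entity_ids, columns=columns)
    matrix = ScoreMatrix.from_scores(frame, dimensions=dims)
    return matrix, pd.Series(latent, index=entity_ids, name="latent")
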
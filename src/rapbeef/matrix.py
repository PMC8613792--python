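"""The entity x attribute score matrix shared by all analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError

#: Score range of the ordinal scale (1 = worst condition, 6 = best).
SCORE_MIN, SCORE_MAX = 1.0, 6.0

MULTI = "multi"


@dataclass
class ScoreMatrix:
    """Entities x attributes of 1-6 scores with dimension/level labels.

    ``scores`` holds one row per real entity and one column per attribute
    (indicator). Polarity is already folded into the scores: 6 is the best
    condition for every attribute. ``attributes`` carries at least a
    ``dimension`` column (and optionally ``level``) indexed by attribute id.
    Scores may be fractional (Monte Carlo perturbations) but must stay
    within [1, 6].
    """

    scores: pd.DataFrame
    attributes: pd.DataFrame
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        if "dimension" not in self.attributes.columns:
            raise InputError("attributes table needs a 'dimension' column")
        if list(self.attributes.index) != list(self.scores.columns):
            raise InputError("attributes index must match score columns")
        if self.scores.isna().any().any():
            bad = [
                (str(e), str(c))
                for e in self.scores.index
                for c in self.scores.columns
                if pd.isna(self.scores.at[e, c])
            ]
            raise InputError(f"missing score cell(s): {bad}")
        if len(self.scores) and (
            (self.scores.values < SCORE_MIN).any() or (self.scores.values > SCORE_MAX).any()
        ):
            raise InputError("scores must lie in [1, 6]")
        if self.scores.index.has_duplicates or self.scores.columns.has_duplicates:
            raise InputError("duplicate entity or attribute ids")

    # -- selection ----------------------------------------------------------

    @property
    def entities(self) -> list[str]:
        return [str(e) for e in self.scores.index]

    @property
    def dimensions(self) -> list[str]:
        seen: list[str] = []
        for d in self.attributes["dimension"]:
            if d not in seen:
                seen.append(d)
        return seen

    def select(self, dimension: str = MULTI) -> "ScoreMatrix":
        """Restrict to one dimension's attributes (``"multi"`` keeps all)."""
        if dimension == MULTI:
            return self
        mask = self.attributes["dimension"] == dimension
        if not mask.any():
            raise InputError(
                f"no attributes in dimension {dimension!r}; have {sorted(set(self.attributes['dimension']))}"
            )
        cols = list(self.attributes.index[mask])
        return ScoreMatrix(
            scores=self.scores[cols].copy(),
            attributes=self.attributes.loc[cols].copy(),
            provenance=None if self.provenance is None else self.provenance[cols].copy(),
        )

    def drop_attribute(self, attribute: str) -> "ScoreMatrix":
        if attribute not in self.scores.columns:
            raise InputError(f"unknown attribute {attribute!r}")
        cols = [c for c in self.scores.columns if c != attribute]
        return ScoreMatrix(
            scores=self.scores[cols].copy(),
            attributes=self.attributes.loc[cols].copy(),
            provenance=None if self.provenance is None else self.provenance[cols].copy(),
        )

    @classmethod
    def from_scores(
        cls,
        scores: pd.DataFrame,
        dimensions: dict[str, str] | pd.Series | None = None,
        level: str | None = None,
    ) -> "ScoreMatrix":
        """Wrap a plain score table; ``dimensions`` maps attribute id -> label."""
        if dimensions is None:
            dims = pd.Series(MULTI, index=scores.columns)
        else:
            dims = pd.Series(dimensions).reindex(scores.columns)
            if dims.isna().any():
                missing = list(dims.index[dims.isna()])
                raise InputError(f"no dimension label for attribute(s): {missing}")
        attrs = pd.DataFrame({"dimension": dims})
        if level is not None:
            attrs["level"] = level
        return cls(scores=scores.copy(), attributes=attrs)
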
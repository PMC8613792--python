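"""Packaged reference data: indicator scales, the three-regency performance
evaluation, and the second Delphi round.

``table3`` is the battery of 20 indicator definitions with their 6-bin
scales; ``table4`` the published actual values and printed 1-6 scores for
the three regencies (Semarang, Boyolali, Sragen) at farm and slaughterhouse
level, with a per-cell ``consistent`` flag marking cells whose printed
score disagrees with the published bins (such cells are excluded from
round-trip checks); ``table7`` the 3-expert x 13-policy rating matrix of
the second Delphi round.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO

import pandas as pd

from .errors import InputError
from .indicators import IndicatorDefinition, load_definitions
from .matrix import ScoreMatrix

FIXTURE_NAMES = ("table3", "table4", "table7")

#: Printed Delphi round-2 statistics, used only for the chi-squared
#: identity check; the W is not reproducible from the 13 printed columns.
TABLE7_PRINTED = {"W": 0.795, "chi2": 33.400, "df": 14, "p": 0.003}


@dataclass
class Table4Fixture:
    """Actual values, printed scores and consistency flags per (indicator, entity)."""

    frame: pd.DataFrame  # columns: indicator, entity, actual, printed_score, consistent
    definitions: dict[str, IndicatorDefinition]

    def level_frame(self, level: str, column: str) -> pd.DataFrame:
        """Entities x indicators table of one column for one chain level."""
        ids = [i for i, d in self.definitions.items() if d.level == level]
        sub = self.frame[self.frame["indicator"].isin(ids)]
        wide = sub.pivot(index="entity", columns="indicator", values=column)
        entity_order = list(dict.fromkeys(self.frame["entity"]))
        return wide.loc[entity_order, ids]

    def score_matrix(self, level: str) -> ScoreMatrix:
        """The printed scale scores of one level as a ScoreMatrix."""
        scores = self.level_frame(level, "printed_score").astype(float)
        dims = {i: self.definitions[i].dimension for i in scores.columns}
        return ScoreMatrix.from_scores(scores, dimensions=dims, level=level)


def _read_csv(name: str) -> pd.DataFrame:
    text = resources.files("rapbeef.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text))


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``table3`` -> dict of IndicatorDefinition; ``table4`` ->
    :class:`Table4Fixture`; ``table7`` -> raters x policies DataFrame.
    """
    if name == "table3":
        return load_definitions()
    if name == "table4":
        frame = _read_csv("table4.csv")
        frame["consistent"] = frame["consistent"].astype(bool)
        return Table4Fixture(frame=frame, definitions=load_definitions())
    if name == "table7":
        frame = _read_csv("table7.csv").set_index("rater")
        return frame.astype(int)
    raise InputError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
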
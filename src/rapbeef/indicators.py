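"""Indicator quantification, 6-point scale scoring and status banding.

The appraisal scores each supply-chain entity (a regency's beef-farm or
slaughterhouse system) on a fixed battery of indicators: 11 at the farm
level (``PE*``, ``PS*``, ``PL*``) and 9 at the slaughterhouse level
(``RE*``, ``RS*``, ``RL*``), spanning the economic, social and
environmental dimensions. Each indicator has

* a quantification formula turning raw yearly measurements (head counts,
  prices, capacities, utility costs) into a single value, and
* a 6-bin ordinal scale on that value axis; bin 1 is always the worst
  condition and bin 6 the best, so cost- and infection-type indicators run
  descending along the value axis.

Bins are contiguous half-open intervals ``[edge_k, edge_{k+1})`` built from
the published lower edges; values outside the outermost edges clamp to the
nearest extreme bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, InputError
from .matrix import ScoreMatrix

LEVELS = ("farm", "slaughterhouse")
DIMENSIONS = ("economic", "social", "environmental")

_PREFIX_LEVEL = {"P": "farm", "R": "slaughterhouse"}
_INFIX_DIMENSION = {"E": "economic", "S": "social", "L": "environmental"}


@dataclass(frozen=True)
class ScaleBins:
    """Six contiguous bins on an indicator's value axis.

    ``edges`` are the 7 ascending breakpoints (the last may be ``+inf`` for
    an unbounded top interval). ``orientation`` says how bins map to scores:
    ``"ascending"`` scores the k-th interval k (higher value = better),
    ``"descending"`` scores it 7 - k (higher value = worse).
    """

    edges: tuple[float, ...]
    orientation: str  # "ascending" | "descending"
    open_low: bool = False
    open_high: bool = True

    def __post_init__(self) -> None:
        if len(self.edges) != 7:
            raise InputError(f"expected 7 breakpoints, got {len(self.edges)}")
        if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
            raise InputError("breakpoints must be strictly increasing")
        if self.orientation not in ("ascending", "descending"):
            raise InputError(f"bad orientation {self.orientation!r}")

    def score(self, value: float) -> int:
        """Bin a value, clamping outside the outermost breakpoints."""
        inner = np.asarray(self.edges[1:6])
        k = int(np.searchsorted(inner, value, side="right"))  # 0..5, clamped
        return k + 1 if self.orientation == "ascending" else 6 - k


@dataclass(frozen=True)
class IndicatorDefinition:
    id: str
    level: str
    dimension: str
    name: str
    unit: str
    polarity: str  # "higher-is-better" | "lower-is-better"
    bins: ScaleBins

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise InputError(f"{self.id}: bad level {self.level!r}")
        if self.dimension not in DIMENSIONS:
            raise InputError(f"{self.id}: bad dimension {self.dimension!r}")
        code_level = _PREFIX_LEVEL.get(self.id[:1])
        code_dim = _INFIX_DIMENSION.get(self.id[1:2])
        if code_level != self.level or code_dim != self.dimension:
            raise InputError(
                f"{self.id}: code prefix implies {code_level}/{code_dim}, "
                f"got {self.level}/{self.dimension}"
            )


@dataclass(frozen=True)
class IndicatorValue:
    indicator: str
    entity: str
    value: float
    unit: str


@dataclass(frozen=True)
class StatusBand:
    label: str
    low: float
    high: float

    def __contains__(self, index: float) -> bool:
        return self.low <= index <= self.high


#: Sustainability bands partitioning [0, 100].
STATUS_BANDS = (
    StatusBand("unsustainable", 0.0, 25.0),
    StatusBand("fairly unsustainable", 25.0, 50.0),
    StatusBand("moderately sustainable", 50.0, 75.0),
    StatusBand("good sustainability", 75.0, 100.0),
)


def classify_status(index: float) -> StatusBand:
    """Band a 0-100 sustainability index.

    0-25 unsustainable, 26-50 fairly unsustainable, 51-75 moderately
    sustainable, 76-100 good sustainability; interior boundaries attach to
    the lower band so the four bands partition [0, 100].
    """
    if not 0.0 <= index <= 100.0:
        raise DomainError(f"index {index} outside [0, 100]")
    for band in STATUS_BANDS:
        if index <= band.high:
            return band
    return STATUS_BANDS[-1]  # pragma: no cover - unreachable


# ---------------------------------------------------------------------------
# Quantification formulas (values are yearly unless noted)
# ---------------------------------------------------------------------------

def _ratio(num: float, den: float, name: str, percent: bool) -> float:
    if den == 0:
        raise DomainError(f"zero denominator: {name}")
    r = num / den
    return 100.0 * r if percent else r


_FORMULAS: dict[str, tuple[tuple[str, ...], callable]] = {
    "PE1": (
        ("n_cattle", "price_per_head", "n_farms"),
        lambda d: _ratio(d["n_cattle"] * d["price_per_head"], d["n_farms"], "n_farms", False),
    ),
    "PE2": (
        ("n_large_farms", "n_farms"),
        lambda d: _ratio(d["n_large_farms"], d["n_farms"], "n_farms", True),
    ),
    "PE3": (
        ("slaughter_capacity", "avg_carcass_weight_kg", "consumption_per_capita_kg", "population"),
        lambda d: _ratio(
            d["slaughter_capacity"] * d["avg_carcass_weight_kg"],
            d["consumption_per_capita_kg"] * d["population"],
            "consumption_per_capita_kg * population",
            True,
        ),
    ),
    "PE4": (
        ("n_insured", "n_cattle"),
        lambda d: _ratio(d["n_insured"], d["n_cattle"], "n_cattle", True),
    ),
    "PS1": (
        ("n_farmers", "n_farms"),
        lambda d: _ratio(d["n_farmers"], d["n_farms"], "n_farms", False),
    ),
    "PS2": (
        ("n_female_farmers", "n_farmers"),
        lambda d: _ratio(d["n_female_farmers"], d["n_farmers"], "n_farmers", True),
    ),
    "PS3": (
        ("n_educated_farmers", "n_farmers"),
        lambda d: _ratio(d["n_educated_farmers"], d["n_farmers"], "n_farmers", True),
    ),
    "PS4": (
        ("n_infected", "n_cattle"),
        lambda d: _ratio(d["n_infected"], d["n_cattle"], "n_cattle", True),
    ),
    "PL1": (
        ("water_cost_per_head_month", "n_cattle"),
        lambda d: d["water_cost_per_head_month"] * d["n_cattle"] * 12.0,
    ),
    # monthly per-head consumption times herd size times tariff, as published
    "PL2": (
        ("kwh_per_head_month", "n_cattle", "price_per_kwh"),
        lambda d: d["kwh_per_head_month"] * d["n_cattle"] * d["price_per_kwh"],
    ),
    "RE1": (
        ("avg_carcass_weight_kg", "price_per_kg", "price_per_head", "slaughter_capacity", "n_labour"),
        lambda d: _ratio(
            (d["avg_carcass_weight_kg"] * d["price_per_kg"] - d["price_per_head"])
            * d["slaughter_capacity"],
            d["n_labour"],
            "n_labour",
            False,
        ),
    ),
    "RS1": (
        ("n_employees", "n_slaughterhouses"),
        lambda d: _ratio(d["n_employees"], d["n_slaughterhouses"], "n_slaughterhouses", False),
    ),
    "RS2": (
        ("n_female_employees", "n_employees"),
        lambda d: _ratio(d["n_female_employees"], d["n_employees"], "n_employees", True),
    ),
    "RS3": (
        ("n_educated_employees", "n_employees"),
        lambda d: _ratio(d["n_educated_employees"], d["n_employees"], "n_employees", True),
    ),
    "RS4": (
        ("n_infected", "slaughter_capacity"),
        lambda d: _ratio(d["n_infected"], d["slaughter_capacity"], "slaughter_capacity", True),
    ),
    "RL1": (
        ("water_cost_per_month",),
        lambda d: d["water_cost_per_month"] * 12.0,
    ),
    "RL2": (
        ("kwh_per_month", "price_per_kwh"),
        lambda d: d["kwh_per_month"] * d["price_per_kwh"] * 12.0,
    ),
}
_FORMULAS["RE2"] = _FORMULAS["PE3"]

# Fuel-cost indicators: distance divided by fuel efficiency (km per litre)
# times pump price gives a cost in USD. The published operand is printed as
# litres per km; ``pl3_as_printed=True`` keeps the literal division.
_FUEL_IDS = ("PL3", "RL3")


def _quantify_fuel(inputs: Mapping[str, float], as_printed: bool) -> float:
    if as_printed:
        need = ("distance_km", "fuel_litre_per_km", "fuel_price_per_litre")
        _require(need, inputs)
        if inputs["fuel_litre_per_km"] == 0:
            raise DomainError("zero denominator: fuel_litre_per_km")
        return inputs["distance_km"] / inputs["fuel_litre_per_km"] * inputs["fuel_price_per_litre"]
    need = ("distance_km", "fuel_km_per_litre", "fuel_price_per_litre")
    _require(need, inputs)
    if inputs["fuel_km_per_litre"] == 0:
        raise DomainError("zero denominator: fuel_km_per_litre")
    return inputs["distance_km"] / inputs["fuel_km_per_litre"] * inputs["fuel_price_per_litre"]


def _require(names: tuple[str, ...], inputs: Mapping[str, float]) -> None:
    missing = [n for n in names if n not in inputs]
    if missing:
        raise InputError(f"missing operand(s): {', '.join(missing)}")


def formula_operands(indicator_id: str, pl3_as_printed: bool = False) -> tuple[str, ...]:
    """Names of the raw measurements an indicator's formula requires."""
    if indicator_id in _FUEL_IDS:
        if pl3_as_printed:
            return ("distance_km", "fuel_litre_per_km", "fuel_price_per_litre")
        return ("distance_km", "fuel_km_per_litre", "fuel_price_per_litre")
    try:
        return _FORMULAS[indicator_id][0]
    except KeyError:
        raise InputError(f"unknown indicator {indicator_id!r}") from None


def quantify_indicator(
    definition: IndicatorDefinition,
    inputs: Mapping[str, float],
    entity: str = "",
    pl3_as_printed: bool = False,
) -> IndicatorValue:
    """Evaluate an indicator's quantification formula on raw measurements.

    Percentage-type indicators return percent-scale values (88.70, not
    0.887), matching the scale bins.
    """
    if definition.id in _FUEL_IDS:
        value = _quantify_fuel(inputs, pl3_as_printed)
    else:
        try:
            names, fn = _FORMULAS[definition.id]
        except KeyError:
            raise InputError(f"no formula registered for {definition.id!r}") from None
        _require(names, inputs)
        value = float(fn(inputs))
    return IndicatorValue(definition.id, entity, float(value), definition.unit)


def map_to_scale(
    definition: IndicatorDefinition, value: IndicatorValue | float
) -> int:
    """Map an indicator value onto its 1-6 ordinal scale.

    The bin index already encodes polarity: 6 is the best condition for
    every indicator, so low costs and low infection rates score high.
    """
    if isinstance(value, IndicatorValue):
        if value.unit != definition.unit:
            raise InputError(
                f"{definition.id}: unit mismatch ({value.unit!r} != {definition.unit!r})"
            )
        value = value.value
    return definition.bins.score(float(value))


def load_definitions() -> dict[str, IndicatorDefinition]:
    """Load the packaged battery of 20 indicator definitions, keyed by id."""
    text = resources.files("rapbeef.data").joinpath("indicators.json").read_text()
    out: dict[str, IndicatorDefinition] = {}
    for rec in json.loads(text):
        edges = tuple(np.inf if e is None else float(e) for e in rec["edges"])
        bins = ScaleBins(edges=edges, orientation=rec["orientation"])
        defn = IndicatorDefinition(
            id=rec["id"],
            level=rec["level"],
            dimension=rec["dimension"],
            name=rec["name"],
            unit=rec["unit"],
            polarity=rec["polarity"],
            bins=bins,
        )
        if defn.id in out:
            raise InputError(f"duplicate indicator id {defn.id}")
        out[defn.id] = defn
    return out


def score_entities(
    definitions: Mapping[str, IndicatorDefinition],
    observations: pd.DataFrame,
    kind: str = "values",
    pl3_as_printed: bool = False,
) -> ScoreMatrix:
    """Build a complete entity x indicator score matrix.

    ``observations`` has one row per entity and one column per indicator id.
    With ``kind="values"`` cells are indicator values (or dicts of raw
    formula operands, quantified first); with ``kind="scores"`` cells are
    pre-assigned 1-6 scores taken as-is. Provenance per cell is recorded on
    the returned matrix (``"quantified"``, ``"mapped"`` or ``"direct"``).
    """
    if kind not in ("values", "scores"):
        raise InputError(f"kind must be 'values' or 'scores', got {kind!r}")
    defs = {k: definitions[k] for k in observations.columns if k in definitions}
    unknown = [c for c in observations.columns if c not in definitions]
    if unknown:
        raise InputError(f"unknown indicator column(s): {', '.join(map(str, unknown))}")

    missing = [
        (str(e), str(c))
        for e in observations.index
        for c in observations.columns
        if pd.isna(observations.at[e, c])
    ]
    if missing:
        raise InputError(f"missing cell(s): {missing}")

    scores = pd.DataFrame(index=observations.index, columns=observations.columns, dtype=float)
    provenance = pd.DataFrame(index=observations.index, columns=observations.columns, dtype=object)
    for e in observations.index:
        for c in observations.columns:
            cell = observations.at[e, c]
            if kind == "scores":
                s = float(cell)
                if s not in (1.0, 2.0, 3.0, 4.0, 5.0, 6.0):
                    raise InputError(f"score at ({e}, {c}) must be an integer 1-6, got {cell!r}")
                scores.at[e, c], provenance.at[e, c] = s, "direct"
            elif isinstance(cell, Mapping):
                iv = quantify_indicator(defs[c], cell, str(e), pl3_as_printed)
                scores.at[e, c] = map_to_scale(defs[c], iv)
                provenance.at[e, c] = "quantified"
            else:
                scores.at[e, c] = map_to_scale(defs[c], float(cell))
                provenance.at[e, c] = "mapped"

    attributes = pd.DataFrame(
        {
            "dimension": [defs[c].dimension for c in observations.columns],
            "level": [defs[c].level for c in observations.columns],
        },
        index=observations.columns,
    )
    return ScoreMatrix(scores=scores, attributes=attributes, provenance=provenance)
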
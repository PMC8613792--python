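"""Indicator quantification, scale binning and status banding."""

import numpy as np
import pandas as pd
import pytest

from rapbeef.errors import DomainError, InputError
from rapbeef.indicators import (
    STATUS_BANDS,
    classify_status,
    map_to_scale,
    quantify_indicator,
    score_entities,
)


class TestQuantify:
    @pytest.mark.parametrize(
        "ind, inputs, expected",
        [
            ("PE2", {"n_large_farms": 0, "n_farms": 500}, 0.0),
            (
                "PE3",
                {
                    "slaughter_capacity": 10_000,
                    "avg_carcass_weight_kg": 180,
                    "consumption_per_capita_kg": 1.9,
                    "population": 900_000,
                },
                pytest.approx(105.26, abs=0.01),
            ),
            ("PL1", {"water_cost_per_head_month": 2, "n_cattle": 10}, 240.0),
            ("PS4", {"n_infected": 0, "n_cattle": 123}, 0.0),
            ("PS1", {"n_farmers": 150, "n_farms": 100}, 1.5),
            ("RL1", {"water_cost_per_month": 30}, 360.0),
            ("RL2", {"kwh_per_month": 100, "price_per_kwh": 0.1}, 120.0),
            (
                "RE1",
                {
                    "avg_carcass_weight_kg": 200,
                    "price_per_kg": 5,
                    "price_per_head": 800,
                    "slaughter_capacity": 50,
                    "n_labour": 10,
                },
                1000.0,  # ((200*5 - 800) * 50) / 10
            ),
        ],
    )
    def test_formula_values(self, definitions, ind, inputs, expected):
        value = quantify_indicator(definitions[ind], inputs)
        assert value.value == expected
        assert value.indicator == ind

    def test_fuel_cost_both_readings(self, definitions):
        # 120 km at 12 km/L and 1 USD/L costs 10 USD
        v = quantify_indicator(
            definitions["PL3"],
            {"distance_km": 120, "fuel_km_per_litre": 12, "fuel_price_per_litre": 1.0},
        )
        assert v.value == pytest.approx(10.0)
        literal = quantify_indicator(
            definitions["PL3"],
            {"distance_km": 120, "fuel_litre_per_km": 0.1, "fuel_price_per_litre": 1.0},
            pl3_as_printed=True,
        )
        assert literal.value == pytest.approx(1200.0)

    def test_missing_operand_is_named(self, definitions):
        with pytest.raises(InputError, match="n_farms"):
            quantify_indicator(definitions["PE2"], {"n_large_farms": 3})

    def test_zero_denominator(self, definitions):
        with pytest.raises(DomainError, match="n_farms"):
            quantify_indicator(definitions["PE2"], {"n_large_farms": 3, "n_farms": 0})

    def test_percentages_bounded_when_numerator_below_denominator(self, definitions):
        rng = np.random.default_rng(42)
        for ind, num, den in [
            ("PE2", "n_large_farms", "n_farms"),
            ("PE4", "n_insured", "n_cattle"),
            ("PS3", "n_educated_farmers", "n_farmers"),
            ("PS4", "n_infected", "n_cattle"),
            ("RS3", "n_educated_employees", "n_employees"),
            ("RS4", "n_infected", "slaughter_capacity"),
        ]:
            for _ in range(25):
                d = float(rng.integers(1, 1000))
                n = float(rng.integers(0, int(d) + 1))
                v = quantify_indicator(definitions[ind], {num: n, den: d}).value
                assert 0.0 <= v <= 100.0


class TestMapToScale:
    @pytest.mark.parametrize(
        "ind, value, expected",
        [
            ("PE2", 0.93, 1),
            ("PL1", 925_988.57, 2),
            ("RS1", 10.75, 4),
            ("PE3", 519.11, 6),  # clamps above the 100% top bin
            ("RE1", 3215.13, 1),  # clamps below the lowest edge
            ("PE2", 8.0, 2),  # lower breakpoint belongs to its bin
            ("PS4", 0.0, 6),  # reversed scale: no infection is best
            ("PS4", 100.0, 1),
        ],
    )
    def test_examples(self, definitions, ind, value, expected):
        assert map_to_scale(definitions[ind], value) == expected

    def test_unit_mismatch_rejected(self, definitions):
        from rapbeef.indicators import IndicatorValue

        bad = IndicatorValue("PE2", "X", 12.0, "USD")
        with pytest.raises(InputError, match="unit"):
            map_to_scale(definitions["PE2"], bad)

    def test_total_monotone_step_function(self, definitions):
        """Scanning a dense grid across every indicator's bins, the score is
        defined everywhere and monotone in the direction of its polarity."""
        for d in definitions.values():
            edges = [e for e in d.bins.edges if np.isfinite(e)]
            lo, hi = edges[0], edges[-1]
            span = hi - lo
            grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, 400)
            scores = np.array([map_to_scale(d, v) for v in grid])
            assert set(np.unique(scores)) <= {1, 2, 3, 4, 5, 6}
            diffs = np.diff(scores)
            if d.bins.orientation == "ascending":
                assert (diffs >= 0).all(), d.id
            else:
                assert (diffs <= 0).all(), d.id
            # all six bins are reachable on the scanned range
            assert set(np.unique(scores)) == {1, 2, 3, 4, 5, 6}, d.id


def test_fixture_round_trip_consistent_cells(table4):
    """Every published (actual value, printed score) pair whose cell is
    consistent with the published bins must reproduce exactly."""
    checked = 0
    for _, row in table4.frame.iterrows():
        if not row["consistent"]:
            continue
        d = table4.definitions[row["indicator"]]
        assert map_to_scale(d, float(row["actual"])) == int(row["printed_score"]), (
            row["indicator"],
            row["entity"],
        )
        checked += 1
    assert checked >= 40  # most of the 60 cells are consistent


class TestScoreEntities:
    def test_values_table_matches_printed_scores(self, definitions, table4):
        values = table4.level_frame("farm", "actual")
        consistent = table4.level_frame("farm", "consistent")
        printed = table4.level_frame("farm", "printed_score")
        matrix = score_entities(definitions, values, kind="values")
        agree = (matrix.scores == printed) | ~consistent.astype(bool)
        assert agree.all().all()
        assert (matrix.provenance == "mapped").all().all()

    def test_raw_input_cells_are_quantified(self, definitions):
        obs = pd.DataFrame(
            {
                "PE2": [{"n_large_farms": 10, "n_farms": 100}],
                "PE4": [55.0],
            },
            index=["Region"],
        )
        matrix = score_entities(definitions, obs, kind="values")
        assert matrix.scores.at["Region", "PE2"] == 2  # 10% -> bin 2
        assert matrix.scores.at["Region", "PE4"] == 3
        assert matrix.provenance.at["Region", "PE2"] == "quantified"

    def test_all_best_row(self, definitions):
        obs = pd.DataFrame({"PE3": [100.0], "PE4": [100.0], "PS4": [0.0]}, index=["E"])
        matrix = score_entities(definitions, obs, kind="values")
        assert (matrix.scores.loc["E"] == 6).all()

    def test_empty_entity_list(self, definitions):
        obs = pd.DataFrame(columns=["PE2", "PE3"])
        matrix = score_entities(definitions, obs, kind="values")
        assert matrix.scores.shape == (0, 2)

    def test_missing_cell_lists_pairs(self, definitions):
        obs = pd.DataFrame({"PE3": [100.0, None]}, index=["A", "B"])
        obs["PE4"] = [50.0, 60.0]
        with pytest.raises(InputError, match="B.*PE3"):
            score_entities(definitions, obs, kind="values")


class TestStatusBands:
    @pytest.mark.parametrize(
        "index, label",
        [
            (56.14, "moderately sustainable"),
            (47.05, "fairly unsustainable"),
            (0.0, "unsustainable"),
            (100.0, "good sustainability"),
            (25.0, "unsustainable"),
            (26.0, "fairly unsustainable"),
        ],
    )
    def test_examples(self, index, label):
        assert classify_status(index).label == label

    def test_bands_partition_unit_interval(self):
        grid = np.linspace(0, 100, 2001)
        for v in grid:
            hits = [b for b in STATUS_BANDS if classify_status(float(v)) is b]
            assert len(hits) == 1

    @pytest.mark.parametrize("bad", [-0.1, 100.1])
    def test_out_of_range(self, bad):
        with pytest.raises(DomainError):
            classify_status(bad)
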
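"""Anchored ordination: references, alignment, index and its invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from rapbeef.errors import DegenerateConfigurationError, InputError
from rapbeef.matrix import ScoreMatrix
from rapbeef.ordination import (
    OrdinationConfig,
    RapOrdination,
    align_axes,
    build_reference_set,
    multidimension_average,
    normalize_scores,
    ordinate,
    sustainability_index,
)
from rapbeef.synthetic import SyntheticSpec, generate_synthetic


def _toy(scores, dims=None):
    frame = pd.DataFrame(scores, dtype=float)
    frame.index = [f"e{i}" for i in range(frame.shape[0])]
    frame.columns = [f"a{j}" for j in range(frame.shape[1])]
    return ScoreMatrix.from_scores(frame, dimensions=dims)


class TestReferenceSet:
    def test_row_counts(self):
        m = _toy([[1, 2, 3, 4], [4, 3, 2, 1], [2, 2, 2, 2]])
        refset = build_reference_set(m, OrdinationConfig(n_anchor_pairs=2))
        assert refset.frame.shape[0] == 3 + 2 + 2 * 2
        assert list(refset.frame.index[:3]) == m.entities

    def test_good_and_bad_rows(self):
        m = _toy([[2, 3, 4, 5]])
        refset = build_reference_set(m, OrdinationConfig())
        good = refset.frame.loc["GOOD"]
        bad = refset.frame.loc["BAD"]
        assert (good == 6).all()
        assert (bad == 1).all()
        assert (good != bad).all()

    def test_anchor_pairs_are_complementary(self):
        m = _toy([[1, 1, 1, 1, 1, 1]])
        refset = build_reference_set(m, OrdinationConfig(n_anchor_pairs=2))
        for k in (1, 2):
            a = refset.frame.loc[f"ANCHOR_{k}A"]
            b = refset.frame.loc[f"ANCHOR_{k}B"]
            assert ((a == 6) == (b == 1)).all()

    def test_too_few_attributes(self):
        m = _toy([[3]])
        with pytest.raises(InputError):
            build_reference_set(m, OrdinationConfig())


@pytest.mark.parametrize(
    "score, expected", [(1.0, 0.0), (6.0, 100.0), (3.5, 50.0), (2.4, 28.0)]
)
def test_normalize_scores(score, expected):
    assert normalize_scores(np.array([[score]]))[0, 0] == pytest.approx(expected)


class TestAlignment:
    def test_quarter_turn(self):
        coords = np.array([[0.0, 1.0], [0.0, -1.0], [0.5, 0.0]])
        out = align_axes(coords, good_index=0, bad_index=1)
        assert out[0] == pytest.approx([1.0, 0.0])
        assert out[1] == pytest.approx([-1.0, 0.0])

    def test_identity_when_aligned(self):
        coords = np.array([[2.0, 0.0], [-2.0, 0.0], [0.3, 0.7]])
        out = align_axes(coords, 0, 1)
        assert np.allclose(out, coords, atol=1e-12)

    def test_mirrored_input_reflected(self):
        coords = np.array([[-2.0, 0.0], [2.0, 0.0]])  # GOOD left of BAD
        out = align_axes(coords, 0, 1)
        assert out[0, 0] > out[1, 0]

    def test_distances_preserved(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(5, 2))
        out = align_axes(coords, 0, 1)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(out), pdist(coords), atol=1e-10)

    def test_coincident_references_error(self):
        coords = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(DegenerateConfigurationError):
            align_axes(coords, 0, 1)


class TestIndex:
    def test_endpoint_and_midpoint(self):
        aligned = np.array([[10.0, 0.0], [0.0, 0.0], [5.0, 3.0], [10.0, -2.0]])
        idx = sustainability_index(aligned, good_index=0, bad_index=1)
        assert idx[0] == 100.0
        assert idx[1] == 0.0
        assert idx[2] == 50.0
        assert idx[3] == 100.0  # coincides with GOOD in x

    def test_collinear_profiles_interpolate_linearly(self):
        """Entities whose profiles lie on the GOOD-BAD segment get indices
        equal to the linear interpolation of their mean normalized score."""
        levels = [1.0, 2.25, 3.5, 4.75, 6.0]
        m = _toy([[v] * 4 for v in levels])
        res = ordinate(m, config=OrdinationConfig(n_anchor_pairs=0))
        expected = [(v - 1.0) / 5.0 * 100.0 for v in levels]
        assert np.allclose(res.index.values, expected, atol=1e-5)


class TestOrdinationPipeline:
    def test_good_bad_pinned_any_seed(self, farm_matrix):
        for seed in (1, 2, 12345):
            est = RapOrdination(dimension="economic", random_state=seed).fit(farm_matrix)
            assert est.reference_index_["GOOD"] == 100.0
            assert est.reference_index_["BAD"] == 0.0

    def test_all_entities_at_good(self):
        m = _toy([[6, 6, 6], [6, 6, 6]])
        res = ordinate(m, config=OrdinationConfig(n_anchor_pairs=0))
        assert np.allclose(res.index.values, 100.0)
        assert res.S <= 1e-6

    def test_identical_inputs_identical_results(self, farm_matrix):
        a = ordinate(farm_matrix, "environmental")
        b = ordinate(farm_matrix, "environmental")
        assert (a.coordinates.values == b.coordinates.values).all()
        assert (a.index.values == b.index.values).all()
        assert a.S == b.S and a.r2 == b.r2

    def test_farm_environment_ordering(self, farm_matrix):
        res = ordinate(farm_matrix, "environmental")
        assert res.index["Semarang"] > res.index["Sragen"]
        assert res.index["Semarang"] > res.index["Boyolali"]

    def test_monotone_under_single_attribute_improvement(self):
        """Raising one score toward best never drops that entity's index by
        more than 1.0 point (MDS jitter allowance), over 100 random
        single-step perturbations."""
        matrix, _ = generate_synthetic(
            SyntheticSpec(n_entities=12, n_attributes=5, sd=0.5, seed=21)
        )
        base = ordinate(matrix).index
        rng = np.random.default_rng(17)
        tried = 0
        while tried < 100:
            e = int(rng.integers(12))
            a = int(rng.integers(5))
            if matrix.scores.iat[e, a] >= 6.0:
                continue
            scores = matrix.scores.copy()
            scores.iat[e, a] = min(6.0, scores.iat[e, a] + 1.0)
            perturbed = ScoreMatrix(scores=scores, attributes=matrix.attributes)
            new = ordinate(perturbed).index
            assert new.iloc[e] - base.iloc[e] >= -1.0
            tried += 1

    def test_latent_gradient_recovery(self):
        matrix, latent = generate_synthetic(
            SyntheticSpec(n_entities=50, n_attributes=8, sd=0.5, seed=3)
        )
        res = ordinate(matrix)
        rho = spearmanr(latent.values, res.index.values).statistic
        assert rho >= 0.9

    def test_stress_reported_is_min_over_restarts(self, farm_matrix):
        """Extra restarts can only improve (or match) the minimized raw
        stress of the winning configuration."""
        one = RapOrdination(dimension="economic", n_restarts=1).fit(farm_matrix)
        many = RapOrdination(dimension="economic", n_restarts=6).fit(farm_matrix)
        assert many.raw_stress_ <= one.raw_stress_ + 1e-9

    def test_dimension_filter_validates(self, farm_matrix):
        with pytest.raises(InputError):
            ordinate(farm_matrix, "nutritional")

    def test_bands_attached(self, farm_matrix):
        res = ordinate(farm_matrix, "environmental")
        assert set(res.bands.index) == set(farm_matrix.entities)
        assert res.bands["Semarang"] == "good sustainability"

    def test_sklearn_params_round_trip(self):
        est = RapOrdination(dimension="social", n_anchor_pairs=3)
        params = est.get_params()
        est2 = RapOrdination(**params)
        assert est2.get_params() == params

    def test_multidimension_average_mode(self, farm_matrix):
        per_dim = {d: ordinate(farm_matrix, d) for d in ("economic", "social", "environmental")}
        avg = multidimension_average(per_dim)
        manual = np.mean([per_dim[d].index["Sragen"] for d in per_dim])
        assert avg["Sragen"] == pytest.approx(manual)
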
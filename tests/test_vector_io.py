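import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plurigon.errors import DimensionalityError, ParseError
from plurigon.vector_io import (
    DataVector,
    difference_vector,
    mean_vector,
    normalize_values,
    read_vector,
    reduce_dimensions,
    write_vector,
)


class TestReadVector:
    def test_triplet_row_major(self, tmp_path):
        f = tmp_path / "v.txt"
        f.write_text("1.0 2.0 3.0\n4.0 5.0 6.0\n")
        v = read_vector(f, dialect="triplet")
        assert v.values.tolist() == [1, 2, 3, 4, 5, 6]

    def test_flat_one_per_line(self, tmp_path):
        f = tmp_path / "v.txt"
        f.write_text("7.5\n7.5\n7.5\n7.5\n")
        assert read_vector(f, dialect="flat").values.tolist() == [7.5] * 4

    def test_triplet_violation_names_line(self, tmp_path):
        f = tmp_path / "v.txt"
        f.write_text("1.0 2.0\n3.0\n")
        with pytest.raises(ParseError, match="line 1"):
            read_vector(f, dialect="triplet")

    def test_non_numeric_token_names_line(self, tmp_path):
        f = tmp_path / "v.txt"
        f.write_text("1 2 3\n4 foo 6\n")
        with pytest.raises(ParseError, match="line 2"):
            read_vector(f, dialect="triplet")

    def test_short_vector_rejected(self, tmp_path):
        f = tmp_path / "v.txt"
        f.write_text("1 2 3\n")
        with pytest.raises(DimensionalityError):
            read_vector(f)

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "v.txt"
        f.write_text("")
        with pytest.raises(ParseError):
            read_vector(f)


class TestWriteVector:
    @pytest.mark.parametrize("dialect", ["flat", "triplet"])
    def test_round_trip_random_values(self, tmp_path, dialect):
        rng = np.random.default_rng(42)
        v = DataVector(rng.uniform(-1e6, 1e6, 1000))
        f = tmp_path / "v.txt"
        write_vector(v, f, dialect=dialect)
        back = read_vector(f, dialect=dialect)
        assert np.array_equal(back.values, v.values)  # exact decimal round-trip

    def test_triplet_final_short_line(self, tmp_path):
        f = tmp_path / "v.txt"
        write_vector(DataVector([1, 2, 3, 4, 5]), f, dialect="triplet")
        lines = f.read_text().strip().splitlines()
        assert [len(line.split()) for line in lines] == [3, 2]

    def test_flat_line_count(self, tmp_path):
        f = tmp_path / "v.txt"
        write_vector(DataVector([1, 2, 3]), f, dialect="flat")
        assert len(f.read_text().strip().splitlines()) == 3


class TestNormalize:
    def test_endpoints_map_to_target(self):
        out = normalize_values(DataVector([0, 5, 10]), target=(0.5, 1.5))
        assert np.allclose(out.values, [0.5, 1.0, 1.5])

    def test_constant_maps_to_midpoint(self):
        out = normalize_values(DataVector([3, 3, 3, 3]), target=(0.5, 1.5))
        assert np.allclose(out.values, 1.0)

    def test_negatives_legal_before_normalization(self):
        out = normalize_values(DataVector([-2, 0, 2]), target=(0.5, 1.5))
        assert np.allclose(out.values, [0.5, 1.0, 1.5])

    def test_idempotent_on_normalized_input(self):
        v = normalize_values(DataVector([1.0, 7.0, 3.0, 2.0]))
        again = normalize_values(v)
        assert np.allclose(again.values, v.values, atol=1e-15)

    def test_records_parameters(self):
        out = normalize_values(DataVector([0, 4.0, 8.0]))
        assert out.normalized
        assert out.norm_params == {"min": 0.0, "max": 8.0, "target": (0.5, 1.5)}

    def test_rejects_nonpositive_target(self):
        with pytest.raises(ValueError):
            normalize_values(DataVector([1, 2, 3]), target=(0.0, 1.0))


class TestMeanDifference:
    def test_mean_matches_brute_force_summation(self):
        rng = np.random.default_rng(7)
        vs = [DataVector(rng.uniform(0, 100, 24)) for _ in range(18)]
        expected = sum(v.values for v in vs) / 18  # independent oracle
        assert np.allclose(mean_vector(vs).values, expected, atol=1e-12)

    def test_mean_of_single_vector_is_identity(self):
        v = DataVector([1, 2, 3, 4])
        assert np.array_equal(mean_vector([v]).values, v.values)

    def test_difference_componentwise(self):
        d = difference_vector(DataVector([5, 5, 5, 5]), DataVector([2, 3, 4, 5]))
        assert d.values.tolist() == [3, 2, 1, 0]

    def test_self_difference_is_zero(self):
        v = DataVector([1.5, -2, 3, 9])
        assert np.all(difference_vector(v, v).values == 0)

    def test_length_mismatch_raises(self):
        with pytest.raises(DimensionalityError):
            difference_vector(DataVector([1, 2, 3, 4]), DataVector([1, 2, 3]))
        with pytest.raises(DimensionalityError):
            mean_vector([DataVector([1, 2, 3, 4]), DataVector([1, 2])])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mean_difference_algebra(self, seed):
        # mean(a, b) - b == (a - b) / 2 componentwise
        rng = np.random.default_rng(seed)
        a = DataVector(rng.normal(size=12))
        b = DataVector(rng.normal(size=12))
        lhs = difference_vector(mean_vector([a, b]), b).values
        rhs = (a.values - b.values) / 2
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestReduceDimensions:
    def test_preserves_distances_in_planar_collection(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 30))
        coeffs = rng.normal(size=(10, 2))
        vs = [DataVector(c @ basis) for c in coeffs]
        reduced = reduce_dimensions(vs, 2)
        X = np.stack([v.values for v in vs])
        Y = np.stack([v.values for v in reduced])
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(X), pdist(Y), rtol=1e-9)

    def test_full_rank_preserves_total_variance(self):
        rng = np.random.default_rng(1)
        vs = [DataVector(rng.normal(size=6)) for _ in range(10)]
        X = np.stack([v.values for v in vs])
        reduced = reduce_dimensions(vs, 6)
        Y = np.stack([v.values for v in reduced])
        assert np.isclose(X.var(axis=0).sum(), Y.var(axis=0).sum(), rtol=1e-9)

    def test_constant_collection_gives_zero_scores(self):
        vs = [DataVector([2.0, 2.0, 2.0, 2.0]) for _ in range(5)]
        reduced = reduce_dimensions(vs, 2)
        assert all(np.all(v.values == 0) for v in reduced)

    @pytest.mark.parametrize("d", [0, -1, 99])
    def test_invalid_target_dimension(self, d):
        vs = [DataVector(np.arange(8.0) + i) for i in range(4)]
        with pytest.raises(DimensionalityError):
            reduce_dimensions(vs, d)
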
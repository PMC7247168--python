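import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsel.dataset import (
    SpectraFormatError,
    SpectraSet,
    average_replicates,
    read_spectra_table,
    subset_wavelengths,
    write_spectra_table,
)


def test_direct_parse(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text(
        "id,780,782,784,786,ref\n"
        "a,0.1,0.2,0.3,0.4,20.0\n"
        "b,0.5,0.6,0.7,0.8,21.0\n"
        "c,0.9,1.0,1.1,1.2,22.0\n"
        "d,1.3,1.4,1.5,1.6,23.0\n"
    )
    data = read_spectra_table(p, "ref")
    assert data.n_wavelengths == 4
    assert data.n_samples == 4
    assert data.wavelengths.tolist() == [780.0, 782.0, 784.0, 786.0]
    assert data.sample_ids == ("a", "b", "c", "d")
    assert data.absorbance[1, 2] == 0.7


def test_shuffled_columns_sorted(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("id,784,780,782,ref\na,3.0,1.0,2.0,20.0\nb,6.0,4.0,5.0,21.0\n")
    data = read_spectra_table(p, "ref")
    assert data.wavelengths.tolist() == [780.0, 782.0, 784.0]
    assert data.absorbance[0].tolist() == [1.0, 2.0, 3.0]


def test_duplicate_wavelength_column_rejected(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("id,780,780.0,ref\na,1,2,20\n")
    with pytest.raises(SpectraFormatError, match="duplicate"):
        read_spectra_table(p, "ref")


def test_non_numeric_cell_reports_location(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("id,780,782,ref\na,1.0,2.0,20\nb,oops,3.0,21\n")
    with pytest.raises(SpectraFormatError, match=r"row 1.*'780'"):
        read_spectra_table(p, "ref")


def test_missing_reference_column(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("id,780,782,ref\na,1.0,2.0,20\n")
    with pytest.raises(SpectraFormatError, match="GLB"):
        read_spectra_table(p, "GLB")


def test_round_trip_exact(tmp_path, rng):
    data = SpectraSet(
        wavelengths=np.sort(rng.uniform(800, 2400, size=12)),
        absorbance=rng.normal(size=(7, 12)),
        reference=rng.normal(30, 4, size=7),
    )
    p = tmp_path / "rt.csv"
    write_spectra_table(data, p)
    back = read_spectra_table(p, "ref")
    np.testing.assert_array_equal(back.wavelengths, data.wavelengths)
    np.testing.assert_array_equal(back.absorbance, data.absorbance)
    np.testing.assert_array_equal(back.reference, data.reference)


@settings(max_examples=25, deadline=None)
@given(st.integers(1, 6), st.integers(2, 8), st.integers(0, 2**32 - 1))
def test_round_trip_property(tmp_path_factory, n, N, seed):
    rng = np.random.default_rng(seed)
    data = SpectraSet(
        wavelengths=np.cumsum(rng.uniform(0.5, 5.0, size=N)) + 700,
        absorbance=rng.normal(size=(n, N)),
        reference=rng.normal(size=n),
    )
    p = tmp_path_factory.mktemp("rt") / "x.csv"
    write_spectra_table(data, p)
    back = read_spectra_table(p, "ref")
    np.testing.assert_array_equal(back.absorbance, data.absorbance)
    np.testing.assert_array_equal(back.wavelengths, data.wavelengths)
    np.testing.assert_array_equal(back.reference, data.reference)


def test_write_empty_rejected(tmp_path):
    data = SpectraSet(
        wavelengths=np.array([780.0, 782.0]),
        absorbance=np.empty((0, 2)),
        reference=np.empty(0),
    )
    with pytest.raises(SpectraFormatError):
        write_spectra_table(data, tmp_path / "e.csv")


def test_write_single_sample(tmp_path):
    data = SpectraSet(
        wavelengths=np.array([780.0, 782.0]),
        absorbance=np.array([[1.0, 2.0]]),
        reference=np.array([20.0]),
    )
    p = tmp_path / "one.csv"
    write_spectra_table(data, p)
    assert len(p.read_text().strip().splitlines()) == 2


class TestSubset:
    def test_identity(self, small_data):
        sub = subset_wavelengths(small_data, small_data.wavelengths)
        np.testing.assert_array_equal(sub.absorbance, small_data.absorbance)

    def test_table2_window_has_159_columns(self):
        grid = np.arange(780.0, 2500.0, 2.0)
        data = SpectraSet(
            wavelengths=grid,
            absorbance=np.zeros((3, grid.size)),
            reference=np.array([1.0, 2.0, 3.0]),
        )
        sub = subset_wavelengths(data, np.arange(1504.0, 1822.0, 2.0))
        assert sub.n_wavelengths == 159

    def test_off_grid_named_in_error(self, small_data):
        with pytest.raises(KeyError, match="781"):
            subset_wavelengths(small_data, [781.0])

    def test_composition(self, small_data, rng):
        w1 = sorted(rng.choice(small_data.wavelengths, size=15, replace=False))
        w2 = sorted(rng.choice(w1, size=6, replace=False))
        via = subset_wavelengths(subset_wavelengths(small_data, w1), w2)
        direct = subset_wavelengths(small_data, w2)
        np.testing.assert_array_equal(via.absorbance, direct.absorbance)


class TestAverageReplicates:
    def test_identical_replicates(self):
        row = [0.1, 0.2]
        data = SpectraSet(
            wavelengths=[780.0, 782.0],
            absorbance=[row, row, row],
            reference=[20.0, 20.0, 20.0],
        )
        out = average_replicates(data, ["g", "g", "g"])
        assert out.n_samples == 1
        np.testing.assert_allclose(out.absorbance, [row], rtol=1e-15)
        assert out.reference[0] == 20.0

    def test_mean_of_zero_one(self):
        data = SpectraSet(
            wavelengths=[780.0],
            absorbance=[[0.0], [1.0]],
            reference=[0.0, 1.0],
        )
        out = average_replicates(data, ["g", "g"])
        assert out.absorbance[0, 0] == 0.5
        assert out.reference[0] == 0.5

    def test_230_groups_of_3(self, rng):
        n_groups = 230
        data = SpectraSet(
            wavelengths=[780.0, 782.0],
            absorbance=rng.normal(size=(3 * n_groups, 2)),
            reference=rng.normal(size=3 * n_groups),
        )
        labels = [f"g{i}" for i in range(n_groups) for _ in range(3)]
        out = average_replicates(data, labels)
        assert out.n_samples == 230

    def test_mismatched_labels(self, small_data):
        with pytest.raises(ValueError):
            average_replicates(small_data, ["a", "b"])
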
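"""Dataset container, CSV round-trips, availability masks and splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clclsa.data_model import (
    DimensionMismatchError,
    FeatureParseError,
    LabelError,
    OmicsDataset,
    StratificationError,
    make_missing_mask,
    read_dataset,
    read_manifest,
    split_dataset,
    write_dataset,
)


def _write_csv(path, array):
    with open(path, "w") as fh:
        for row in np.atleast_2d(array):
            fh.write(",".join(str(v) for v in row) + "\n")


class TestReadDataset:
    def test_reads_views_labels_and_infers_classes(self, tmp_path, rng):
        paths = []
        for i in range(3):
            p = tmp_path / f"omics{i}.csv"
            _write_csv(p, rng.normal(size=(8, 4)))
            paths.append(p)
        _write_csv(tmp_path / "y.csv", np.array([[v] for v in [0, 1, 0, 1, 1, 0, 1, 0]]))
        ds = read_dataset(paths, tmp_path / "y.csv")
        assert ds.n_views == 3 and ds.view_dims == (4, 4, 4)
        assert ds.n_classes == 2 and ds.mask.all() and ds.eta == 0.0

    def test_cohort_shaped_matrices(self, tmp_path, rng):
        # three 351-subject, 200-feature layers with binary labels
        paths = []
        for i in range(3):
            p = tmp_path / f"layer{i}.csv"
            np.savetxt(p, rng.normal(size=(351, 200)), delimiter=",", fmt="%.4f")
            paths.append(p)
        _write_csv(tmp_path / "y.csv", rng.integers(0, 2, size=(351, 1)))
        ds = read_dataset(paths, tmp_path / "y.csv")
        assert ds.n_views == 3
        assert ds.view_dims == (200, 200, 200)
        assert ds.n_classes == 2 and ds.n_subjects == 351

    def test_header_row_is_detected(self, tmp_path):
        p = tmp_path / "v.csv"
        p.write_text("geneA,geneB\n1.0,2.0\n3.0,4.0\n")
        _write_csv(tmp_path / "y.csv", np.array([[0], [1]]))
        ds = read_dataset([p], tmp_path / "y.csv")
        np.testing.assert_allclose(ds.views[0], [[1, 2], [3, 4]])

    def test_row_count_mismatch_names_files(self, tmp_path, rng):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        _write_csv(a, rng.normal(size=(10, 2)))
        _write_csv(b, rng.normal(size=(9, 2)))
        _write_csv(tmp_path / "y.csv", np.zeros((10, 1), dtype=int))
        with pytest.raises(DimensionMismatchError, match="b.csv"):
            read_dataset([a, b], tmp_path / "y.csv")

    def test_non_numeric_cell_reports_position(self, tmp_path):
        p = tmp_path / "v.csv"
        p.write_text("1.0,2.0\n3.0,oops\n")
        _write_csv(tmp_path / "y.csv", np.array([[0], [1]]))
        with pytest.raises(FeatureParseError, match="row 1"):
            read_dataset([p], tmp_path / "y.csv")

    def test_negative_label_rejected(self, tmp_path, rng):
        p = tmp_path / "v.csv"
        _write_csv(p, rng.normal(size=(3, 2)))
        _write_csv(tmp_path / "y.csv", np.array([[0], [-1], [1]]))
        with pytest.raises(LabelError):
            read_dataset([p], tmp_path / "y.csv")


def test_write_read_roundtrip(tmp_path, tiny_ds):
    write_dataset(tiny_ds, tmp_path)
    back = read_manifest(tmp_path / "manifest.json")
    for a, b in zip(tiny_ds.views, back.views):
        np.testing.assert_allclose(a, b, atol=1e-12)
    np.testing.assert_array_equal(tiny_ds.mask, back.mask)
    np.testing.assert_array_equal(tiny_ds.labels, back.labels)
    assert back.n_classes == tiny_ds.n_classes


def test_dataset_rejects_label_out_of_range(rng):
    with pytest.raises(LabelError):
        OmicsDataset(
            views=[rng.normal(size=(4, 2))],
            labels=[0, 1, 2, 1],
            mask=np.ones((4, 1), dtype=bool),
            view_names=["v"],
            n_classes=2,
        )


class TestMissingMask:
    def test_exact_incomplete_count(self):
        mask = make_missing_mask(10, 3, 0.2, seed=0)
        assert (~mask.entries.all(axis=1)).sum() == 2
        assert mask.entries.any(axis=1).all()
        assert mask.eta == 0.2

    def test_eta_zero_is_all_true(self):
        assert make_missing_mask(10, 3, 0.0, seed=0).entries.all()

    def test_single_view_cannot_be_masked(self):
        with pytest.raises(ValueError):
            make_missing_mask(5, 1, 0.5, seed=0)

    def test_eta_out_of_range(self):
        with pytest.raises(ValueError):
            make_missing_mask(5, 3, 1.2, seed=0)

    @pytest.mark.parametrize("eta", [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
    @pytest.mark.parametrize("n", [10, 37, 400, 1000])
    def test_achieved_rate_on_grid(self, n, eta):
        mask = make_missing_mask(n, 3, eta, seed=1)
        assert (~mask.entries.all(axis=1)).sum() == round(eta * n)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 300),
        m=st.integers(2, 5),
        eta=st.floats(0.0, 0.8),
        seed=st.integers(0, 2**16),
    )
    def test_every_subject_keeps_a_view(self, n, m, eta, seed):
        mask = make_missing_mask(n, m, eta, seed=seed)
        assert mask.entries.any(axis=1).all()


class TestSplit:
    def test_stratified_exact_proportions(self, rng):
        ds = OmicsDataset(
            views=[rng.normal(size=(100, 3))],
            labels=np.repeat([0, 1], 50),
            mask=np.ones((100, 1), dtype=bool),
            view_names=["v"],
            n_classes=2,
        )
        tr, te = split_dataset(ds, 0.7, seed=0)
        assert tr.n_subjects == 70 and te.n_subjects == 30
        assert np.bincount(tr.labels).tolist() == [35, 35]
        assert np.bincount(te.labels).tolist() == [15, 15]

    def test_same_seed_reproduces(self, tiny_ds):
        a = split_dataset(tiny_ds, 0.7, seed=3)[0]
        b = split_dataset(tiny_ds, 0.7, seed=3)[0]
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.views[0], b.views[0])

    def test_fraction_must_be_fractional(self, tiny_ds):
        with pytest.raises(ValueError):
            split_dataset(tiny_ds, 1.0, seed=0)

    def test_tiny_class_cannot_stratify(self, rng):
        ds = OmicsDataset(
            views=[rng.normal(size=(5, 2))],
            labels=[0, 0, 0, 0, 1],
            mask=np.ones((5, 1), dtype=bool),
            view_names=["v"],
            n_classes=2,
        )
        with pytest.raises(StratificationError):
            split_dataset(ds, 0.6, seed=0)


def test_select_views_drops_unobservable_subjects(tiny_ds):
    mask = tiny_ds.mask.copy()
    mask[0] = [True, False, False]  # subject 0 only has view 0
    ds = OmicsDataset(
        tiny_ds.views, tiny_ds.labels, mask, tiny_ds.view_names, tiny_ds.n_classes
    )
    sub = ds.select_views([1, 2])
    assert sub.n_subjects == ds.n_subjects - 1
    assert sub.n_views == 2
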
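"""Normalisation chain: completeness filter, RPM, log2, quantile, PCA QC."""

import itertools

import numpy as np
import pandas as pd
import pytest

import pifrif as p
from tests.conftest import make_expression


def _cm(values, groups):
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))])
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return p.CountMatrix(
        counts=df, groups=pd.Series(groups, index=df.columns, name="group")
    )


class TestFilterComplete:
    def test_drops_genes_with_any_zero(self, toy_counts):
        out = p.filter_complete(toy_counts)
        mins = toy_counts.counts.min(axis=1)
        assert list(out.counts.index) == list(mins.index[mins > 0])
        assert out.counts.shape[1] == toy_counts.counts.shape[1]

    def test_all_positive_matrix_unchanged(self):
        cm = _cm([[1, 2], [3, 4]], ["HFE", "LFE"])
        out = p.filter_complete(cm)
        pd.testing.assert_frame_equal(out.counts, cm.counts)

    def test_no_complete_genes_is_an_error(self):
        cm = _cm([[0, 2], [3, 0]], ["HFE", "LFE"])
        with pytest.raises(p.ValidationError, match="no complete genes"):
            p.filter_complete(cm)


class TestRPM:
    def test_hand_computed_two_gene_sample(self):
        cm = _cm([[1, 1], [3, 1]], ["HFE", "LFE"])
        rpm = p.to_rpm(cm)
        assert rpm.iloc[0, 0] == pytest.approx(250_000)
        assert rpm.iloc[1, 0] == pytest.approx(750_000)

    def test_single_gene_column_hits_one_million(self):
        cm = _cm([[50, 7]], ["HFE", "LFE"])
        rpm = p.to_rpm(cm)
        assert rpm.iloc[0].tolist() == pytest.approx([1e6, 1e6])

    def test_column_sums_equal_one_million(self, toy_counts):
        rpm = p.to_rpm(toy_counts)
        assert rpm.sum(axis=0).to_numpy() == pytest.approx(1e6, rel=1e-6)

    def test_zero_total_names_the_sample(self):
        cm = _cm([[0, 2], [0, 3]], ["HFE", "LFE"])
        with pytest.raises(p.ValidationError, match="s0"):
            p.to_rpm(cm)


class TestLog2:
    @pytest.mark.parametrize(
        "rpm,expected", [(1.0, 1.0), (0.0, 0.0), (999.0, np.log2(1000.0))]
    )
    def test_values_with_default_pseudocount(self, rpm, expected):
        df = pd.DataFrame([[rpm]])
        assert p.log2_transform(df).iloc[0, 0] == pytest.approx(expected)

    def test_nonpositive_argument_is_an_error(self):
        df = pd.DataFrame([[-2.0]], index=["gX"], columns=["sY"])
        with pytest.raises(p.ValidationError, match="gX"):
            p.log2_transform(df, pseudocount=0.5)


class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = p.quantile_normalize_frame(df)
        pd.testing.assert_frame_equal(out, df)

    def test_hand_computed_rank_means(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [1.0, 3.0, 5.0]})
        out = p.quantile_normalize_frame(df)
        expected = [1.5, 3.5, 5.5]
        assert out["a"].tolist() == pytest.approx(expected)
        assert out["b"].tolist() == pytest.approx(expected)

    def test_ties_get_mean_of_spanned_rank_means(self):
        # column a has a 2-way tie spanning rank-means 1.5 and 3.5
        df = pd.DataFrame({"a": [2.0, 2.0, 6.0], "b": [1.0, 3.0, 5.0]})
        out = p.quantile_normalize_frame(df)
        rank_means = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].tolist() == pytest.approx(
            [rank_means[:2].mean(), rank_means[:2].mean(), rank_means[2]]
        )

    def test_sorted_columns_identical_and_idempotent_without_ties(self):
        # the exact rank-mean properties hold on tie-free input; tied values
        # are averaged (see test_ties_get_mean_of_spanned_rank_means), which
        # perturbs the shared distribution by the tie spans
        rng = np.random.default_rng(17)
        vals = pd.DataFrame(rng.normal(5, 2, (500, 8)))
        out = p.quantile_normalize_frame(vals)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        assert np.ptp(sorted_cols, axis=1).max() < 1e-9
        again = p.quantile_normalize_frame(out)
        assert np.abs(again.to_numpy() - out.to_numpy()).max() < 1e-9
        assert np.ptp(out.mean(axis=0).to_numpy()) < 1e-9  # equal column means

    def test_single_sample_is_a_warned_noop(self, caplog):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with caplog.at_level("WARNING"):
            out = p.quantile_normalize_frame(df)
        pd.testing.assert_frame_equal(out, df)
        assert "single-sample" in caplog.text


def _exhaustive_linear_separation(coords, labels, max_mis=1):
    """Independent oracle: best linear boundary in 2-D by scanning all
    directions defined by point pairs and all thresholds."""
    n = len(labels)
    y = np.array([1 if g == labels[0] else -1 for g in labels])
    best = n
    dirs = []
    for i, j in itertools.combinations(range(n), 2):
        d = coords[i] - coords[j]
        if np.allclose(d, 0):
            continue
        dirs.append(d)
        dirs.append(np.array([-d[1], d[0]]))
    for d in dirs:
        proj = coords @ d
        for t in np.concatenate([proj - 1e-9, proj + 1e-9]):
            pred = np.where(proj > t, 1, -1)
            err = min((pred != y).sum(), (pred == y).sum())
            best = min(best, err)
    return best <= max_mis


class TestPCAGroupCheck:
    def test_strong_shift_separates_perfectly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, (100, 12))
        base[:, :6] += 5.0  # >= 5 SD shift on every gene
        em = make_expression(base, ["HFE"] * 6 + ["LFE"] * 6)
        rep = p.pca_group_check(em)
        assert rep.separated and rep.n_misclassified == 0
        coords = rep.coordinates[["pc1", "pc2"]].to_numpy()
        assert _exhaustive_linear_separation(
            coords, rep.coordinates["group"].tolist(), max_mis=0
        )

    def test_null_data_with_permuted_labels_rarely_separates(self):
        fails = 0
        reps = 20
        for s in range(reps):
            rng = np.random.default_rng(900 + s)
            vals = rng.normal(0, 1, (200, 12))
            labels = list(rng.permutation(["HFE"] * 6 + ["LFE"] * 6))
            em = make_expression(vals, labels)
            fails += not p.pca_group_check(em).separated
        assert fails >= int(0.9 * reps)

    def test_duplicated_samples_have_duplicated_coordinates(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (50, 6))
        doubled = np.concatenate([vals, vals], axis=1)
        em = make_expression(doubled, ["HFE"] * 6 + ["LFE"] * 6)
        rep = p.pca_group_check(em)
        c = rep.coordinates[["pc1", "pc2"]].to_numpy()
        assert np.allclose(c[:6], c[6:], atol=1e-8)

    def test_too_few_samples_is_an_error(self):
        em = make_expression(np.ones((5, 2)), ["HFE", "LFE"])
        with pytest.raises(p.ValidationError):
            p.pca_group_check(em)


def test_pipeline_order_and_provenance(small_expression):
    assert small_expression.provenance == [
        "rpm(all-gene totals)",
        "filter_complete",
        "log2(+1)",
        "quantile",
    ]
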
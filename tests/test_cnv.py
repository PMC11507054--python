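import numpy as np
import pandas as pd
import pytest

from serrapath import (
    arm_events,
    cnv_score,
    normalize,
    relative_expression,
    score_group_test,
    smooth_by_position,
)
from serrapath.cnv import CNVProfile, _smooth_block

from conftest import tiny_dataset


def brute_moving_average(x, w):
    """Independent oracle: symmetric shrinking moving average."""
    n = len(x)
    half = (w - 1) // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = np.mean(x[i - k : i + k + 1])
    return out


def profile_from(matrix, arms, cells=None, reference=()):
    matrix = np.asarray(matrix, float)
    n_cells, n_genes = matrix.shape
    if cells is None:
        cells = pd.DataFrame(
            {
                "barcode": [f"c{i}" for i in range(n_cells)],
                "sample_id": ["s1"] * n_cells,
                "stage": ["tumor"] * n_cells,
                "cell_type": ["SLC1"] * n_cells,
            }
        )
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{j}" for j in range(n_genes)],
            "gene_name": [f"g{j}" for j in range(n_genes)],
            "chromosome": [a.rstrip("pq") for a in arms],
            "start": np.arange(n_genes),
            "end": np.arange(n_genes) + 1,
            "arm": arms,
        }
    )
    return CNVProfile(
        smoothed=matrix, cells=cells, genes=genes, window=1, cap=3.0,
        reference_cells=list(reference),
    )


class TestRelativeExpression:
    def test_reference_centering_identity(self, null_dataset):
        # centering the reference on itself zeroes every column mean
        # (cap chosen non-binding: clipping deliberately breaks exactness)
        ds, _ = null_dataset
        norm = normalize(ds)
        ref = np.ones(norm.n_cells, dtype=bool)
        centered = relative_expression(norm, ref, cap=np.inf)
        np.testing.assert_allclose(centered.mean(axis=0), 0.0, atol=1e-10)

    def test_constant_gene_becomes_zero(self):
        ds = tiny_dataset([[2, 1], [2, 3]])
        norm = normalize(ds)
        norm.values[:, 0] = 0.7  # force a constant column
        centered = relative_expression(norm, np.array([True, True]))
        np.testing.assert_allclose(centered[:, 0], 0.0, atol=1e-12)

    def test_clipping_to_cap(self):
        ds = tiny_dataset([[1, 1], [1, 1], [1, 1]])
        norm = normalize(ds)
        norm.values[:, :] = 0.0
        norm.values[0, 0] = 7.5  # 5 above the reference mean of ~2.5
        centered = relative_expression(norm, np.array([False, True, True]), cap=3.0)
        assert centered[0, 0] == 3.0

    def test_empty_reference_rejected(self, null_dataset):
        ds, _ = null_dataset
        norm = normalize(ds)
        with pytest.raises(ValueError, match="empty"):
            relative_expression(norm, np.zeros(norm.n_cells, dtype=bool))


class TestSmoothing:
    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=(3, 20))
        np.testing.assert_array_equal(_smooth_block(x, 1), x)

    def test_constant_shift_preserved(self):
        x = np.full((2, 30), 1.0)
        np.testing.assert_allclose(_smooth_block(x, 7), 1.0)

    @pytest.mark.parametrize("w", [3, 5, 11])
    def test_matches_brute_force_oracle(self, w):
        rng = np.random.default_rng(w)
        x = rng.normal(size=40)
        np.testing.assert_allclose(
            _smooth_block(x[None, :], w)[0], brute_moving_average(x, w), atol=1e-12
        )

    def test_interior_spike_peak_is_a_over_w(self):
        x = np.zeros(51)
        x[25] = 5.0
        sm = _smooth_block(x[None, :], 5)[0]
        assert sm[25] == pytest.approx(5.0 / 5)

    def test_even_window_rejected(self):
        ds = tiny_dataset([[1, 2, 3]])
        norm = normalize(ds)
        with pytest.raises(ValueError, match="odd"):
            smooth_by_position(norm.values, norm.cells, norm.genes, window=4)

    def test_smoothing_respects_chromosome_boundary(self):
        # spike at the end of chr1 must not leak into chr2
        arms = ["1p"] * 10 + ["2p"] * 10
        ds = tiny_dataset([np.ones(20)], arms=arms)
        centered = np.zeros((1, 20))
        centered[0, 9] = 3.0
        prof = smooth_by_position(centered, ds.cells, ds.genes, window=5)
        assert np.all(prof.smoothed[0, 10:] == 0.0)
        assert prof.smoothed[0, 9] > 0

    def test_gene_order_is_genomic(self):
        arms = ["2p", "1p", "1q"]
        ds = tiny_dataset([[1, 2, 3]], arms=arms)
        ds.genes.loc[:, "start"] = [5, 1, 9]
        prof = smooth_by_position(np.zeros((1, 3)), ds.cells, ds.genes, window=1)
        assert list(prof.genes["arm"]) == ["1p", "1q", "2p"]


class TestScore:
    def test_zero_row_scores_zero(self):
        prof = profile_from(np.zeros((2, 10)), ["1p"] * 10)
        assert (cnv_score(prof)["cnv_score"] == 0).all()

    def test_constant_row_scores_c_squared(self):
        prof = profile_from(np.full((1, 8), 0.5), ["1p"] * 8)
        assert cnv_score(prof)["cnv_score"].iloc[0] == pytest.approx(0.25)

    def test_partial_arm_shift_arithmetic(self):
        # shift 0.5 on 10% of genes: score = 0.1 * 0.25
        m = np.zeros((1, 100))
        m[0, :10] = 0.5
        prof = profile_from(m, ["1p"] * 100)
        assert cnv_score(prof)["cnv_score"].iloc[0] == pytest.approx(0.025)

    def test_chromosome_block_permutation_invariance(self, null_dataset):
        ds, _ = null_dataset
        norm = normalize(ds)
        centered = relative_expression(norm, np.ones(norm.n_cells, bool))
        prof = smooth_by_position(centered, norm.cells, norm.genes, window=5)
        scores = cnv_score(prof)["cnv_score"].to_numpy()
        # relabel chromosomes in reverse order: blocks move, content identical
        genes2 = norm.genes.copy()
        mapping = {str(c): str(23 - int(c)) for c in range(1, 23)}
        genes2["chromosome"] = genes2["chromosome"].map(mapping)
        genes2["arm"] = genes2["chromosome"] + genes2["arm"].str[-1]
        prof2 = smooth_by_position(centered, norm.cells, genes2, window=5)
        scores2 = cnv_score(prof2)["cnv_score"].to_numpy()
        np.testing.assert_allclose(np.sort(scores), np.sort(scores2), atol=1e-12)


class TestArmEvents:
    def test_neutral_noiseless_sample(self):
        prof = profile_from(np.zeros((3, 20)), ["1p"] * 10 + ["1q"] * 10)
        ev = arm_events(prof, gain_thr=0.1, loss_thr=0.1)
        assert (ev["pct_gain"] == 0).all() and (ev["pct_loss"] == 0).all()

    def test_half_gained_arm_step_profile(self):
        # strong step on the first half of an arm, noiseless; with window 1
        # the call fraction is exactly the step fraction
        m = np.zeros((2, 50))
        m[:, :25] = 1.0
        prof = profile_from(m, ["3p"] * 50)
        ev = arm_events(prof, gain_thr=0.1, loss_thr=0.1)
        assert 40 <= ev["pct_gain"].iloc[0] <= 60

    def test_gain_pct_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        m = rng.normal(0.1, 0.2, size=(4, 60))
        prof = profile_from(m, ["5q"] * 60)
        pcts = [
            arm_events(prof, gain_thr=t, loss_thr=t)["pct_gain"].iloc[0]
            for t in (0.05, 0.1, 0.2, 0.4)
        ]
        assert pcts == sorted(pcts, reverse=True)

    def test_gain_and_loss_bounded(self):
        rng = np.random.default_rng(6)
        m = rng.normal(0, 0.5, size=(3, 40))
        prof = profile_from(m, ["8p"] * 20 + ["8q"] * 20)
        ev = arm_events(prof, gain_thr=0.05, loss_thr=0.05)
        assert ((ev["pct_gain"] + ev["pct_loss"]) <= 100).all()

    def test_reference_cells_excluded_from_sample_mean(self):
        cells = pd.DataFrame(
            {
                "barcode": ["r0", "c1"],
                "sample_id": ["s1", "s1"],
                "stage": ["tumor", "tumor"],
                "cell_type": ["SLC1", "SLC1"],
            }
        )
        m = np.array([[1.0, 1.0], [0.0, 0.0]])  # reference row is shifted
        prof = profile_from(m, ["1p", "1p"], cells=cells, reference=["r0"])
        ev = arm_events(prof, gain_thr=0.1, loss_thr=0.1)
        assert ev["pct_gain"].iloc[0] == 0.0  # only the non-reference cell counts


class TestGroupTest:
    def test_identical_groups(self):
        scores = pd.DataFrame(
            {
                "cnv_score": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                "stage": ["normal"] * 3 + ["tumor"] * 3,
            }
        )
        h, p = score_group_test(scores, "stage")
        assert h == 0.0 and p == 1.0

    def test_single_group_rejected(self):
        scores = pd.DataFrame({"cnv_score": [1.0, 2.0], "stage": ["normal"] * 2})
        with pytest.raises(ValueError):
            score_group_test(scores, "stage")

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(8)
        scores = pd.DataFrame(
            {
                "cnv_score": np.concatenate(
                    [rng.normal(0, 1, 50), rng.normal(2, 1, 50)]
                ),
                "stage": ["normal"] * 50 + ["tumor"] * 50,
            }
        )
        _, p = score_group_test(scores, "stage")
        assert p < 1e-6
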
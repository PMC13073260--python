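"""Differential screen: Welch test, BH correction, PCA, symmetry properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from revnet import OmicsMatrix, SyntheticSpec, generate_dataset, pca_scores, screen
from revnet.screen import bh_adjust


def _matrix(values: dict, n_ctrl: int, n_model: int):
    frame = pd.DataFrame(values)
    groups = pd.Series(
        ["control"] * n_ctrl + ["model"] * n_model, index=list(frame.columns)
    )
    return OmicsMatrix(values=frame, groups=groups, layer="transcript")


def bh_oracle(pvals):
    """Brute-force BH step-up: q_i = min over j>=i of p_(j) * m / j."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


class TestScreen:
    def test_log2fc_is_difference_of_group_means(self, small_matrix):
        diff = screen(small_matrix, ("model", "control"))
        # f1: model mean 6, control mean 4
        assert diff.table.at["f1", "log2fc"] == pytest.approx(2.0)
        # f2 means equal
        assert diff.table.at["f2", "log2fc"] == pytest.approx(0.0, abs=1e-9)

    def test_welch_t_matches_closed_form(self):
        """{1,2,3} vs {4,5,6}: t = -3.674, Welch-Satterthwaite df = 4."""
        mat = _matrix(
            {"a": [1.0], "b": [2.0], "c": [3.0], "d": [4.0], "e": [5.0], "f": [6.0]},
            3,
            3,
        )
        # contrast=(control, model) puts {1,2,3} first
        diff = screen(mat, ("control", "model"))
        se = np.sqrt(1 / 3 + 1 / 3)
        t_expected = -3.0 / se
        p_expected = 2 * stats.t.cdf(t_expected, df=4)
        assert t_expected == pytest.approx(-3.674, abs=5e-4)
        assert diff.table.at[0, "p"] == pytest.approx(p_expected, rel=1e-10)
        assert diff.table.at[0, "p"] == pytest.approx(0.0214, abs=5e-4)

    def test_identical_groups_nothing_significant(self):
        vals = {f"s{i}": [2.0, 3.0] for i in range(6)}
        mat = _matrix(vals, 3, 3)
        diff = screen(mat, ("model", "control"))
        assert diff.table["significant"].sum() == 0
        assert (diff.table["p"] == 1.0).all()  # zero variance, equal means

    def test_symmetry_of_contrast(self, small_matrix):
        ab = screen(small_matrix, ("model", "control"))
        ba = screen(small_matrix, ("control", "model"))
        assert np.allclose(ab.table["log2fc"], -ba.table["log2fc"])
        assert np.allclose(ab.table["p"], ba.table["p"])

    def test_too_few_samples_rejected(self, small_matrix):
        sub = small_matrix.restrict_groups(("model",))
        with pytest.raises(ValueError, match=">= 2"):
            screen(sub, ("model", "control"))

    def test_significance_uses_raw_p_and_fc(self):
        rng = np.random.default_rng(0)
        base = rng.normal(8, 0.2, size=(30, 10))
        base[0, 5:] += 3.0  # one strongly shifted feature
        frame = pd.DataFrame(
            base, index=[f"f{i}" for i in range(30)], columns=[f"s{i}" for i in range(10)]
        )
        mat = _matrix({c: frame[c] for c in frame.columns}, 5, 5)
        diff = screen(mat, ("model", "control"))
        t = diff.table
        assert (t["significant"] == ((t["log2fc"].abs() > 1) & (t["p"] < 0.05))).all()
        assert t.at["f0", "significant"]
        assert (t["q"] >= t["p"] - 1e-12).all()

    def test_type_one_error_calibration(self):
        """Null world: p<0.05 rate within 2 binomial SE of 0.05 at 1000 features."""
        spec = SyntheticSpec(n_features=1000, frac_disease=0.0, seed=11)
        mat, _ = generate_dataset(spec)
        diff = screen(mat.restrict_groups(("model", "control")), ("model", "control"))
        rate = float((diff.table["p"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) <= 2 * se


class TestBH:
    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=20)
    )
    @settings(max_examples=200, deadline=None)
    def test_bh_matches_stepup_oracle(self, pvals):
        got = bh_adjust(np.array(pvals))
        want = bh_oracle(np.array(pvals))
        assert np.allclose(got, want, atol=1e-12)

    def test_bh_monotone_in_sorted_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestPCA:
    def test_two_clusters_separated_on_pc1(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.1, size=(40, 10))
        x[:, 5:] += 3.0  # offset half the samples on every feature
        frame = pd.DataFrame(
            x, index=[f"f{i}" for i in range(40)], columns=[f"s{i}" for i in range(10)]
        )
        mat = _matrix({c: frame[c] for c in frame.columns}, 5, 5)
        scores, ratio = pca_scores(mat)
        pc1 = scores["PC1"].to_numpy()
        assert ratio[0] > ratio[1]
        assert max(pc1[:5]) < min(pc1[5:]) or min(pc1[:5]) > max(pc1[5:])

    def test_rank_one_matrix_explains_everything(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.outer(np.arange(5.0), v)
        frame = pd.DataFrame(x, columns=[f"s{i}" for i in range(4)])
        mat = _matrix({c: frame[c] for c in frame.columns}, 2, 2)
        _, ratio = pca_scores(mat, n_components=1)
        assert ratio[0] == pytest.approx(1.0)

    def test_duplicated_samples_get_identical_scores(self, small_matrix):
        vals = small_matrix.values.copy()
        vals["m3b"] = vals["m3"]
        groups = pd.concat(
            [small_matrix.groups, pd.Series({"m3b": "model"})]
        )
        mat = OmicsMatrix(values=vals, groups=groups, layer="transcript")
        scores, _ = pca_scores(mat)
        assert np.allclose(scores.loc["m3"], scores.loc["m3b"])

    def test_constant_matrix_rejected(self):
        frame = pd.DataFrame(np.ones((5, 6)), columns=[f"s{i}" for i in range(6)])
        mat = _matrix({c: frame[c] for c in frame.columns}, 3, 3)
        with pytest.raises(ValueError, match="constant"):
            pca_scores(mat)


class TestOmicsMatrixValidation:
    def test_missing_values_rejected(self):
        frame = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0], "c": [1.0, 1.0], "d": [0.0, 2.0]})
        groups = pd.Series(["control", "control", "model", "model"], index=list("abcd"))
        with pytest.raises(ValueError, match="missing"):
            OmicsMatrix(values=frame, groups=groups, layer="transcript")

    def test_counts_to_log2_round_trip(self, tmp_path):
        frame = pd.DataFrame({"a": [0.0, 3.0], "b": [1.0, 7.0], "c": [0.0, 1.0], "d": [2.0, 2.0]})
        groups = pd.Series(["control", "control", "model", "model"], index=list("abcd"))
        raw = OmicsMatrix(values=frame, groups=groups, layer="transcript", log2_scale=False)
        logm = raw.to_log2()
        assert logm.values.iloc[0, 1] == pytest.approx(1.0)  # log2(1+1)
        logm.write_tsv(tmp_path / "m.tsv", tmp_path / "s.tsv")
        back = OmicsMatrix.read_tsv(tmp_path / "m.tsv", tmp_path / "s.tsv", layer="transcript")
        assert np.allclose(back.values, logm.values)
        assert list(back.groups) == list(logm.groups)
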
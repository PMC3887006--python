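import numpy as np
import pandas as pd
import pytest

from regsubtype.expression import (
    ExpressionMatrix,
    compute_log_ratios,
    group_average,
    preprocess,
    read_expression,
    variance_support_check,
)


def _matrix(values: np.ndarray, groups: dict[str, str], genes=None,
            state="raw") -> ExpressionMatrix:
    samples = list(groups)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=pd.Series(groups),
        control_group="control",
        state=state,
    )


@pytest.fixture
def toy_files(tmp_path):
    (tmp_path / "expr.tsv").write_text(
        "gene\ts1\ts2\ts3\ts4\n"
        "g1\t1.0\t2.0\t3.0\t4.0\n"
        "g2\t2.0\t2.0\t2.0\t5.0\n"
        "g3\t8.0\t6.0\t4.0\t2.0\n"
    )
    (tmp_path / "groups.tsv").write_text(
        "sample\tgroup\ns1\tcontrol\ns2\tcontrol\ns3\tdisease\ns4\tdisease\n"
    )
    return tmp_path


class TestReading:
    def test_reads_matrix_and_groups(self, toy_files):
        m = read_expression(toy_files / "expr.tsv", toy_files / "groups.tsv", "control")
        assert m.values.shape == (3, 4)
        assert m.control_group == "control"
        assert m.control_samples == ["s1", "s2"]

    def test_unannotated_sample_is_error(self, toy_files):
        (toy_files / "groups.tsv").write_text(
            "sample\tgroup\ns1\tcontrol\ns2\tcontrol\ns3\tdisease\n"
        )
        with pytest.raises(ValueError, match="s4"):
            read_expression(toy_files / "expr.tsv", toy_files / "groups.tsv", "control")

    def test_duplicate_gene_rows_accepted_raw(self, toy_files):
        (toy_files / "expr.tsv").write_text(
            "gene\ts1\ts2\ts3\ts4\n"
            "g1\t1\t2\t3\t4\n"
            "g1\t2\t3\t4\t5\n"
        )
        m = read_expression(toy_files / "expr.tsv", toy_files / "groups.tsv", "control")
        assert m.values.index.duplicated().any()


class TestPreprocess:
    def test_collapse_keeps_max_mean_probeset(self):
        # p2 (mean 7.0) beats p1 (mean 5.0) for gene G
        m = _matrix(
            np.array([[4.0, 6.0], [6.0, 8.0], [1.0, 9.0]]),
            {"s1": "control", "s2": "disease"},
            genes=["p1", "p2", "q1"],
        )
        out = preprocess(m, probe_to_gene={"p1": "G", "p2": "G", "q1": "H"})
        assert list(out.gene_ids) == ["G", "H"]
        # retained row equals the winning probeset's values after the same
        # log/standardize steps applied without collapse ambiguity
        direct = preprocess(
            _matrix(
                np.array([[6.0, 8.0], [1.0, 9.0]]),
                {"s1": "control", "s2": "disease"},
                genes=["G", "H"],
            )
        )
        pd.testing.assert_frame_equal(out.values, direct.values)

    def test_collapse_tie_breaks_lexicographically(self):
        m = _matrix(
            np.array([[6.0, 8.0], [8.0, 6.0], [1.0, 9.0]]),
            {"s1": "control", "s2": "disease"},
            genes=["pB", "pA", "q1"],
        )
        out = preprocess(m, probe_to_gene={"pA": "G", "pB": "G", "q1": "H"})
        # equal means (7.0): pA wins; its raw values were (8, 6)
        direct = preprocess(
            _matrix(
                np.array([[8.0, 6.0], [1.0, 9.0]]),
                {"s1": "control", "s2": "disease"},
                genes=["G", "H"],
            )
        )
        pd.testing.assert_frame_equal(out.values, direct.values)

    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        m = _matrix(
            rng.lognormal(size=(50, 4)),
            {"s1": "control", "s2": "control", "s3": "d", "s4": "d"},
        )
        out = preprocess(m)
        v = out.values.to_numpy()
        assert np.allclose(v.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(v.var(axis=0), 1, atol=1e-8)

    def test_zero_variance_column_rejected(self):
        m = _matrix(
            np.array([[1.0, 1.0], [1.0, 2.0]]),
            {"s1": "control", "s2": "disease"},
        )
        with pytest.raises(ValueError, match="zero variance column"):
            preprocess(m, already_logged=True)

    def test_nonpositive_intensity_rejected(self):
        m = _matrix(
            np.array([[1.0, -2.0], [3.0, 4.0]]),
            {"s1": "control", "s2": "disease"},
        )
        with pytest.raises(ValueError, match="non-positive"):
            preprocess(m)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        groups = {"s1": "control", "s2": "control", "s3": "d", "s4": "d"}
        m = _matrix(rng.lognormal(size=(30, 4)), groups)
        out = preprocess(m)
        perm = ["s3", "s1", "s4", "s2"]
        m_perm = ExpressionMatrix(
            values=m.values[perm], groups=m.groups, control_group="control"
        )
        out_perm = preprocess(m_perm)
        pd.testing.assert_frame_equal(out.values[perm], out_perm.values)


class TestGroupAverageAndLogRatios:
    def test_group_average_is_arithmetic_mean(self):
        m = _matrix(
            np.array([[1.0, 3.0, 9.0], [2.0, 4.0, 5.0]]),
            {"s1": "control", "s2": "control", "s3": "d"},
            state="raw",
        )
        prof = group_average(m, "control")
        assert prof.tolist() == [2.0, 3.0]

    def test_single_sample_group_average_is_identity(self):
        m = _matrix(
            np.array([[1.0, 5.0], [2.0, 7.0]]),
            {"s1": "control", "s2": "d"},
        )
        assert group_average(m, "d").tolist() == [5.0, 7.0]

    def test_unknown_group_raises(self):
        m = _matrix(np.ones((2, 2)), {"s1": "control", "s2": "d"})
        with pytest.raises(KeyError):
            group_average(m, "nope")

    def test_log_ratio_is_difference_to_control_mean(self):
        rng = np.random.default_rng(2)
        m = preprocess(_matrix(
            rng.lognormal(size=(40, 5)),
            {"s1": "control", "s2": "control", "s3": "d", "s4": "d", "s5": "d"},
        ))
        lrm = compute_log_ratios(m)
        assert list(lrm.sample_ids) == ["s3", "s4", "s5"]
        expected = m.values["s3"] - m.values[["s1", "s2"]].mean(axis=1)
        assert np.allclose(lrm.values["s3"], expected)

    def test_sample_equal_to_control_mean_gives_zero(self):
        # construct standardized columns where s3 equals the control mean
        rng = np.random.default_rng(3)
        a = rng.normal(size=20)
        a = (a - a.mean()) / a.std()
        vals = np.column_stack([a, a, a])
        m = _matrix(vals, {"s1": "control", "s2": "control", "s3": "d"},
                    state="standardized")
        lrm = compute_log_ratios(m)
        assert np.allclose(lrm.values["s3"], 0.0)

    def test_control_only_dataset_is_error(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=10)
        a = (a - a.mean()) / a.std()
        m = _matrix(np.column_stack([a, a]),
                    {"s1": "control", "s2": "control"}, state="standardized")
        with pytest.raises(ValueError, match="control"):
            compute_log_ratios(m)


class TestVarianceSupport:
    def test_constant_controls_varying_disease_gives_one(self):
        vals = np.array([
            [1.0, 1.0, 0.0, 5.0],
            [2.0, 2.0, 1.0, 9.0],
        ])
        m = _matrix(vals, {"s1": "control", "s2": "control", "s3": "d", "s4": "d"})
        assert variance_support_check(m) == 1.0

    def test_single_gene_higher_control_variance_gives_zero(self):
        vals = np.array([[0.0, 2.0, 1.0, 2.0]])  # ctrl var 2.0, disease var 0.5
        m = _matrix(vals, {"s1": "control", "s2": "control", "s3": "d", "s4": "d"})
        assert variance_support_check(m) == 0.0

    def test_exchangeable_null_is_near_half(self):
        rng = np.random.default_rng(5)
        n_genes = 2000
        groups = {f"s{i}": ("control" if i < 4 else "d") for i in range(8)}
        m = _matrix(rng.normal(size=(n_genes, 8)), groups)
        frac = variance_support_check(m)
        # binomial 95% band around 0.5 at 2000 genes
        half = 1.96 * np.sqrt(0.25 / n_genes)
        assert abs(frac - 0.5) < half + 0.01

    def test_insufficient_samples_rejected(self):
        m = _matrix(np.ones((3, 2)) + np.arange(3)[:, None],
                    {"s1": "control", "s2": "d"})
        with pytest.raises(ValueError):
            variance_support_check(m)
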
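"""Relative abundance, transcription efficiency and relative-TE algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bglccr import (
    AbundanceTable,
    SimulationConfig,
    activity_gradient,
    aggregate_replicates,
    gen_qpcr,
    group_summary,
    relative_abundance,
    relative_activity,
    relative_te,
    tolerant_ratio,
    transcription_efficiency,
)
from bglccr.abundance import (
    AbundanceError,
    DEFAULT_TREATMENTS,
    high_glucose_treatments,
)


def table(values, level="DNA", index=None, **kw):
    genes = [f"g{i+1}" for i in range(np.shape(values)[1])]
    idx = index or [f"t{i+1}" for i in range(np.shape(values)[0])]
    return AbundanceTable(pd.DataFrame(values, index=idx, columns=genes), level=level, **kw)


class TestRelativeAbundance:
    def test_normalisation(self):
        t = table([[10.0, 30.0, 60.0]])
        norm = relative_abundance(t, ["g1", "g2", "g3"])
        assert list(norm.data.iloc[0]) == [0.1, 0.3, 0.6]

    def test_single_gene_universe(self):
        t = table([[10.0, 30.0]])
        norm = relative_abundance(t, ["g1"])
        assert list(norm.data.columns) == ["g1"]
        assert norm.data.iloc[0, 0] == 1.0

    def test_universe_excludes_uncharacterised_gene(self):
        t = table([[10.0, 30.0, 60.0]])
        norm = relative_abundance(t, ["g1", "g2"])
        assert list(norm.data.iloc[0]) == [0.25, 0.75]
        assert "g3" not in norm.data.columns

    def test_all_zero_sample_is_an_error(self):
        t = table([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(AbundanceError, match="t2"):
            relative_abundance(t, ["g1", "g2"])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        t = table(rng.uniform(0.1, 5.0, size=(4, 8)))
        norm = relative_abundance(t, [f"g{i+1}" for i in range(8)])
        assert np.allclose(norm.data.sum(axis=1), 1.0, atol=1e-9)

    @given(scale=st.floats(min_value=0.01, max_value=1e6))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        """Multiplying a sample's raw counts by any constant leaves the
        relative abundances unchanged."""
        raw = np.array([[5.0, 15.0, 30.0]])
        a = relative_abundance(table(raw), ["g1", "g2", "g3"])
        b = relative_abundance(table(raw * scale), ["g1", "g2", "g3"])
        assert np.allclose(a.data.values, b.data.values)


class TestReplicates:
    def test_mean_of_replicates(self):
        t = table(
            [[4.0], [6.0]],
            index=["s1", "s2"],
            replicate_of={"s1": "CK", "s2": "CK"},
        )
        collapsed, cv = aggregate_replicates(t)
        assert collapsed.data.loc["CK", "g1"] == 5.0

    def test_single_replicate_passthrough(self):
        t = table([[7.0]], index=["s1"], replicate_of={"s1": "CK"})
        collapsed, _ = aggregate_replicates(t)
        assert collapsed.data.loc["CK", "g1"] == 7.0

    def test_zero_replicates_flag_undefined_cv(self):
        t = table(
            [[0.0], [0.0], [0.0]],
            index=["s1", "s2", "s3"],
            replicate_of={s: "CK" for s in ("s1", "s2", "s3")},
        )
        collapsed, cv = aggregate_replicates(t)
        assert collapsed.data.loc["CK", "g1"] == 0.0
        assert np.isnan(cv.loc["CK", "g1"])

    def test_negative_abundance_rejected(self):
        with pytest.raises(AbundanceError):
            table([[-1.0]])


class TestTranscriptionEfficiency:
    def test_direct_ratio(self):
        dna = table([[0.1]], level="DNA")
        rna = table([[0.2]], level="RNA")
        te = transcription_efficiency(dna, rna)
        assert te.te.iloc[0, 0] == pytest.approx(2.0)

    def test_zero_rna_gives_zero_te(self):
        te = transcription_efficiency(table([[0.1]], "DNA"), table([[0.0]], "RNA"))
        assert te.te.iloc[0, 0] == 0.0

    def test_zero_dna_is_undefined(self):
        te = transcription_efficiency(table([[0.0]], "DNA"), table([[0.3]], "RNA"))
        assert np.isnan(te.te.iloc[0, 0])

    def test_direction_switch_inverts(self):
        dna, rna = table([[0.1]], "DNA"), table([[0.2]], "RNA")
        fwd = transcription_efficiency(dna, rna, direction="rna_over_dna")
        rev = transcription_efficiency(dna, rna, direction="dna_over_rna")
        assert rev.te.iloc[0, 0] == pytest.approx(1.0 / fwd.te.iloc[0, 0])

    def test_mismatched_gene_sets_error_lists_difference(self):
        dna = table([[1.0, 2.0]], "DNA")
        rna = AbundanceTable(pd.DataFrame([[1.0]], index=["t1"], columns=["g9"]), "RNA")
        with pytest.raises(AbundanceError, match="g9"):
            transcription_efficiency(dna, rna)


class TestRelativeTE:
    def _te(self, values, treatments):
        from bglccr.abundance import TETable

        return TETable(pd.DataFrame(values, index=treatments, columns=["g1"]))

    def test_fixed_point_at_control(self):
        rel = relative_te(self._te([[1.0], [1.0]], ["CK", "T"]), "CK")
        assert rel.rel_te.loc["T", "g1"] == 0.0
        assert rel.rel_te.loc["CK", "g1"] == 0.0

    def test_doubling_scores_one(self):
        rel = relative_te(self._te([[1.0], [2.0]], ["CK", "T"]), "CK")
        assert rel.rel_te.loc["T", "g1"] == pytest.approx(1.0)

    def test_zero_control_te_excludes_gene(self):
        rel = relative_te(self._te([[0.0], [2.0]], ["CK", "T"]), "CK")
        assert rel.excluded_genes == ["g1"]
        assert "g1" not in rel.rel_te.columns

    def test_missing_control_is_configuration_error(self):
        with pytest.raises(AbundanceError, match="CK"):
            relative_te(self._te([[1.0]], ["T"]), "CK")


class TestGroupSummary:
    def test_mean_and_sd(self):
        values = pd.DataFrame(
            [[0.5, 1.5]], index=["T"], columns=["g1", "g2"]
        )
        calls = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "call": ["glucose_tolerant"] * 2}
        )
        summary = group_summary(values, calls)
        gt = summary[(summary.treatment == "T") & (summary.group == "glucose_tolerant")]
        assert gt["mean"].iloc[0] == pytest.approx(1.0)
        assert gt["n_genes"].iloc[0] == 2
        non = summary[(summary.treatment == "T") & (summary.group == "non_tolerant")]
        assert non["n_genes"].iloc[0] == 0
        assert np.isnan(non["mean"].iloc[0])

    def test_indeterminate_genes_excluded(self):
        values = pd.DataFrame([[0.5, 99.0]], index=["T"], columns=["g1", "g2"])
        calls = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "call": ["glucose_tolerant", "indeterminate"]}
        )
        summary = group_summary(values, calls)
        gt = summary[(summary.group == "glucose_tolerant")]
        assert gt["mean"].iloc[0] == pytest.approx(0.5)

    def test_aggregation_agrees_with_single_replicate_when_noiseless(
        self, truth_calls_frame
    ):
        """With zero replicate noise, group summaries from the aggregated
        triplicate tables equal those from any single replicate — the
        ratio-of-means aggregation does not distort noiseless data."""
        config = SimulationConfig(n_genes=10, noise_cv=0.0, n_replicates=3, seed=13)
        dna, rna, truth = gen_qpcr(config)
        calls = truth_calls_frame(truth)
        d_mean, _ = aggregate_replicates(dna)
        r_mean, _ = aggregate_replicates(rna)
        s_mean = group_summary(
            relative_te(transcription_efficiency(d_mean, r_mean), "CK").rel_te, calls
        )
        rep1 = [s for s in dna.data.index if s.endswith("rep1")]
        d_one = AbundanceTable(
            dna.data.loc[rep1].rename(index=lambda s: s.split("__rep")[0]), "DNA"
        )
        r_one = AbundanceTable(
            rna.data.loc[rep1].rename(index=lambda s: s.split("__rep")[0]), "RNA"
        )
        s_one = group_summary(
            relative_te(transcription_efficiency(d_one, r_one), "CK").rel_te, calls
        )
        pd.testing.assert_frame_equal(
            s_mean.sort_values(["treatment", "group"]).reset_index(drop=True),
            s_one.sort_values(["treatment", "group"]).reset_index(drop=True),
        )


class TestTolerantRatio:
    def test_seventeen_of_thirtyone(self):
        calls = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(31)],
                "call": ["glucose_tolerant"] * 17 + ["non_tolerant"] * 14,
            }
        )
        assert tolerant_ratio(calls) == pytest.approx(17 / 31, abs=1e-4)
        assert tolerant_ratio(calls) == pytest.approx(0.5484, abs=1e-4)

    def test_all_tolerant(self):
        calls = pd.DataFrame({"gene_id": ["a"], "call": ["glucose_tolerant"]})
        assert tolerant_ratio(calls) == 1.0

    def test_indeterminate_excluded_from_both_sides(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "call": ["glucose_tolerant", "non_tolerant", "indeterminate"],
            }
        )
        assert tolerant_ratio(calls) == pytest.approx(0.5)

    def test_expression_weighted_ratio(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "call": ["glucose_tolerant", "non_tolerant"],
            }
        )
        assert tolerant_ratio(calls, {"a": 0.9, "b": 0.1}) == pytest.approx(0.9)

    def test_zero_weight_denominator_is_error(self):
        calls = pd.DataFrame({"gene_id": ["a"], "call": ["glucose_tolerant"]})
        with pytest.raises(AbundanceError):
            tolerant_ratio(calls, {"a": 0.0})


class TestRelativeActivity:
    def test_half_activity(self):
        assert relative_activity(50.0, 100.0) == pytest.approx(50.0)

    def test_equal_activity_is_hundred_percent(self):
        assert relative_activity(3.3, 3.3) == pytest.approx(100.0)

    def test_zero_baseline_is_error(self):
        with pytest.raises(AbundanceError):
            relative_activity(1.0, 0.0)

    def test_non_monotone_gradient_flagged_not_rejected(self):
        rel, flag = activity_gradient({50: 80.0, 100: 60.0, 200: 70.0}, 100.0)
        assert flag is True
        assert rel[200] == pytest.approx(70.0)
        rel, flag = activity_gradient({50: 80.0, 100: 60.0, 200: 40.0}, 100.0)
        assert flag is False


def test_treatment_design_high_glucose_rule():
    assert high_glucose_treatments() == ["G_H_C_L", "G_H_C_H", "G_H_C_H_D"]
    ck = [t for t in DEFAULT_TREATMENTS if t.name == "CK"][0]
    assert ck.is_control and not ck.is_high_glucose


def test_te_scale_invariance_through_pipeline(truth_calls_frame):
    """Rescaling each sample's raw counts leaves TE and relative TE
    unchanged (compositional property of per-sample normalisation)."""
    rng = np.random.default_rng(8)
    raw_d = rng.uniform(1, 100, size=(3, 6))
    raw_r = rng.uniform(1, 100, size=(3, 6))
    genes = [f"g{i+1}" for i in range(6)]
    idx = ["CK", "A", "B"]
    scales = np.array([[3.0], [0.1], [42.0]])

    def pipe(d, r):
        dt = AbundanceTable(pd.DataFrame(d, index=idx, columns=genes), "DNA")
        rt = AbundanceTable(pd.DataFrame(r, index=idx, columns=genes), "RNA")
        dn = relative_abundance(dt, genes)
        rn = relative_abundance(rt, genes)
        return relative_te(transcription_efficiency(dn, rn), "CK").rel_te

    a = pipe(raw_d, raw_r)
    b = pipe(raw_d * scales, raw_r * scales[::-1])
    assert np.allclose(a.values, b.values)
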
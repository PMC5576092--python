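"""Fisher exact test, t test, network construction, and summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from muftox.architecture import ArchitectureCall, ArchClass
from muftox.io import ProfileClass
from muftox.screen import MufProtein
from muftox.stats import (
    ContingencyTable2x2,
    adjust_report,
    build_network,
    fisher_exact_two_tailed,
    paired_association_tests,
    summarize,
    two_sample_t,
)


class TestFisher:
    def test_balanced_table_is_one(self):
        assert fisher_exact_two_tailed(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_full_enumeration_value(self):
        # support of the diagonal 3/3 table has C(6,3)=20 outcomes; the two
        # extreme tables each have probability 1/20 -> two-sided p = 0.1
        assert fisher_exact_two_tailed(ContingencyTable2x2(3, 0, 0, 3)) == pytest.approx(
            0.1, abs=1e-12
        )

    def test_asymmetric_table(self):
        p = fisher_exact_two_tailed(ContingencyTable2x2(1, 9, 11, 3))
        assert p == pytest.approx(0.002759456185, abs=1e-9)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_two_tailed(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_nested_list_input(self):
        assert fisher_exact_two_tailed([[3, 0], [0, 3]]) == pytest.approx(0.1)

    @settings(max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_agrees_with_scipy_dialect(self, counts):
        from scipy.stats import fisher_exact

        a, b, c, d = counts
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        mine = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
        ref = fisher_exact([[a, b], [c, d]]).pvalue
        assert mine == pytest.approx(ref, rel=1e-6, abs=1e-12)
        assert 0.0 < mine <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)


class TestTTest:
    def test_identical_samples(self):
        t, df, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_p_decreases_with_shift(self):
        x = [1.0, 2.0, 3.0]
        ps = [two_sample_t(x, [v + shift for v in x])[2] for shift in (1.0, 5.0, 10.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_pooled_statistic_matches_closed_form(self):
        x = [2.1, 2.5, 2.9]
        y = [3.2, 3.6, 4.0]
        t, df, p = two_sample_t(x, y, welch=False)
        # hand-computed pooled-variance statistic
        mx, my = np.mean(x), np.mean(y)
        sp2 = (np.var(x, ddof=1) * 2 + np.var(y, ddof=1) * 2) / 4
        expected = (mx - my) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(expected, abs=1e-12)
        assert df == 4

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            two_sample_t([2.0, 2.0], [3.0, 3.0])


def _muf(pid, family="MUF1"):
    return MufProtein(pid, "G", pid, ProfileClass[family], 5, 150, 400, 1e-30)


def _arch(pid, toxins=()):
    cls = ArchClass.CT_TOXIN if toxins else ArchClass.CT_UNKNOWN
    return ArchitectureCall(pid, 250, True, cls, tuple(toxins), tuple(toxins))


class TestNetwork:
    def test_min_support_filters_by_domain_total(self):
        calls = []
        for i in range(7):
            pid = f"a{i}"
            calls.append((_muf(pid, "MUF1"), _arch(pid, ["Ntox50"])))
        for i in range(4):
            pid = f"b{i}"
            calls.append((_muf(pid, "MUF2"), _arch(pid, ["EndoU_bacteria"])))
        edges = build_network(calls, min_support=5)
        assert [(e.muf_family, e.toxin_domain, e.weight) for e in edges] == [
            ("MUF1", "Ntox50", 7)
        ]

    def test_no_toxin_calls_empty_network(self):
        calls = [(_muf("a"), _arch("a"))]
        assert build_network(calls) == []

    def test_two_domain_protein_contributes_two_edges(self):
        calls = [
            (_muf(f"p{i}"), _arch(f"p{i}", ["Ntox50", "cd13442"])) for i in range(5)
        ]
        edges = build_network(calls, min_support=5)
        assert len(edges) == 2
        assert sum(e.weight for e in edges) == 10

    def test_weights_sum_to_pairs_above_support(self, minimal_result):
        prot = minimal_result.proteins
        pair_count = sum(
            len(d.split(",")) if d else 0
            for d in prot.loc[prot["arch_class"] == "CT_TOXIN", "ct_domains"]
        )
        assert minimal_result.network["weight"].sum() <= pair_count


class TestSummaries:
    def test_single_muf_genome_proportion_one(self):
        genomes = pd.DataFrame(
            [{"genome_id": "G", "kind": "phage", "clade": "Firmicutes",
              "phage_family": "Siphoviridae", "lifestyle": "temperate"}]
        )
        proteins = pd.DataFrame(
            [{"protein_id": "p", "genome_id": "G", "family": "MUF1",
              "arch_class": "SHORT"}]
        )
        row = summarize(genomes, proteins, "clade").iloc[0]
        assert row["prop_genomes_muf"] == 1.0 and row["n_muf"] == 1

    def test_class_counts_conserve_in_every_row(self, minimal_result):
        for df in minimal_result.summaries.values():
            assert (
                df["n_short"] + df["n_toxin"] + df["n_unknown"] == df["n_muf"]
            ).all()

    def test_unknown_grouping_key_rejected(self, minimal_result, minimal_ds):
        with pytest.raises(KeyError):
            summarize(minimal_ds.genomes, minimal_result.proteins, "flavor")


class TestPairedTests:
    def test_report_is_deterministic(self, minimal_ds, minimal_result):
        meta = minimal_ds.genomes.replace("", np.nan)
        a = paired_association_tests(
            minimal_result.proteins, meta, minimal_result.immunity
        )
        b = paired_association_tests(
            minimal_result.proteins, meta, minimal_result.immunity
        )
        pd.testing.assert_frame_equal(a, b)
        assert list(a["test"][:4]) == [
            "toxin_vs_short_by_firmicutes",
            "unknown_vs_short_by_proteobacteria",
            "muf_by_siphoviridae",
            "muf_by_lifestyle",
        ]

    def test_missing_metadata_column_rejected(self, minimal_result):
        with pytest.raises(KeyError, match="clade"):
            paired_association_tests(
                minimal_result.proteins, pd.DataFrame({"genome_id": []}), None
            )

    def test_bh_adjustment_is_monotone(self, minimal_ds, minimal_result):
        meta = minimal_ds.genomes.replace("", np.nan)
        rep = adjust_report(
            paired_association_tests(minimal_result.proteins, meta, minimal_result.immunity)
        )
        assert (rep["p_bh"] >= rep["p"] - 1e-12).all()
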
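"""Best-profile selection and MuF protein calling."""

import pytest

from muftox.io import DomainHit, GeneRecord, MUF_CLASSES, ProfileClass
from muftox.screen import (
    apply_ga_table,
    call_muf_proteins,
    select_best_profile,
)


def _muf_hit(profile, evalue, score=100.0, pid="p1", env=(1, 150), passed=True):
    return DomainHit(pid, profile, ProfileClass[profile.upper()], evalue, score,
                     env[0], env[1], passed)


def _gene(gene_id, aa=400, rank=0, replicon="G_c1", genome="G"):
    start = 10 + rank * 2000
    return GeneRecord(gene_id, genome, replicon, start, start + (aa + 1) * 3,
                      "+", rank, aa)


class TestSelectBestProfile:
    def test_best_evalue_wins(self):
        hits = [_muf_hit("MuF1", 1e-30), _muf_hit("MuF3", 1e-10)]
        assert select_best_profile(hits, MUF_CLASSES).profile_name == "MuF1"

    def test_tie_breaks_by_bitscore_then_name(self):
        by_score = [_muf_hit("MuF2", 1e-20, 90.0), _muf_hit("MuF1", 1e-20, 120.0)]
        assert select_best_profile(by_score, MUF_CLASSES).profile_name == "MuF1"
        by_name = [_muf_hit("MuF2", 1e-20, 90.0), _muf_hit("MuF1", 1e-20, 90.0)]
        assert select_best_profile(by_name, MUF_CLASSES).profile_name == "MuF1"

    def test_empty_and_failed_ga_give_none(self):
        assert select_best_profile([], MUF_CLASSES) is None
        assert select_best_profile([_muf_hit("MuF1", 1e-30, passed=False)],
                                   MUF_CLASSES) is None

    def test_mixed_proteins_rejected(self):
        hits = [_muf_hit("MuF1", 1e-30, pid="a"), _muf_hit("MuF2", 1e-10, pid="b")]
        with pytest.raises(ValueError, match="multiple proteins"):
            select_best_profile(hits, MUF_CLASSES)


class TestCallMufProteins:
    def test_marker_only_protein_not_called(self):
        genes = [_gene("p1")]
        hits = [DomainHit("p1", "Phage_portal", ProfileClass.PORTAL, 1e-50, 300.0, 5, 390)]
        assert call_muf_proteins(hits, genes) == []

    def test_family_from_passing_hit(self):
        genes = [_gene("p1")]
        calls = call_muf_proteins([_muf_hit("MuF2", 1e-25)], genes)
        assert len(calls) == 1 and calls[0].family is ProfileClass.MUF2

    def test_envelope_from_better_of_two_domains(self):
        genes = [_gene("p1")]
        hits = [
            _muf_hit("MuF1", 1e-8, env=(10, 110)),
            _muf_hit("MuF1", 1e-20, env=(1, 100)),
        ]
        (call,) = call_muf_proteins(hits, genes)
        assert (call.muf_env_from, call.muf_env_to) == (1, 100)

    def test_orphan_protein_listed_in_error(self):
        with pytest.raises(ValueError, match="ghost"):
            call_muf_proteins([_muf_hit("MuF1", 1e-30, pid="ghost")], [_gene("p1")])

    def test_call_count_bounded_by_muf_hit_proteins(self, minimal_ds):
        calls = call_muf_proteins(minimal_ds.hits, minimal_ds.genes)
        with_muf = {
            h.protein_id for h in minimal_ds.hits if h.profile_class in MUF_CLASSES
        }
        assert len(calls) <= len(with_muf)
        # all hits pass GA in the fixture, so equality holds
        assert len(calls) == len(with_muf)

    def test_noiseless_families_match_ground_truth(self, minimal_ds):
        calls = call_muf_proteins(minimal_ds.hits, minimal_ds.genes)
        truth = minimal_ds.gene_truth.set_index("gene_id")["family"]
        assert len(calls) == len(truth)
        for c in calls:
            assert c.family.value == truth[c.gene_id]


def test_ga_table_reflagging():
    raw = [_muf_hit("MuF1", 1e-30, score=25.0, passed=False)]
    assert select_best_profile(raw, MUF_CLASSES) is None
    flagged = apply_ga_table(raw, {"MuF1": 20.0})
    assert select_best_profile(flagged, MUF_CLASSES) is not None
    # profiles missing from the GA table stay rejected
    assert select_best_profile(apply_ga_table(raw, {}), MUF_CLASSES) is None
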
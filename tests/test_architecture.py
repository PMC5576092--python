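"""C-terminal extension measurement and architecture classification."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from muftox.architecture import (
    ArchClass,
    classify_architecture,
    ct_extension_length,
    toxin_catalog_from_table,
)
from muftox.io import DomainHit, ParseError, ProfileClass
from muftox.screen import MufProtein


def _muf(aa=400, env_to=150, pid="p1"):
    return MufProtein(pid, "G", pid, ProfileClass.MUF1, 5, env_to, aa, 1e-30)


def _hit(name, cls, env, pid="p1"):
    return DomainHit(pid, name, cls, 1e-20, 80.0, env[0], env[1])


class TestExtensionLength:
    @pytest.mark.parametrize(
        "aa,env_to,expected,has_ext",
        [
            (300, 150, 150, True),
            (350, 250, 100, True),   # boundary: exactly 100 aa counts
            (263, 150, 113, True),   # shortest toxin-carrying extension seen
            (249, 150, 99, False),
            (150, 150, 0, False),
        ],
    )
    def test_length_and_inclusive_cutoff(self, aa, env_to, expected, has_ext):
        assert ct_extension_length(aa, env_to) == (expected, has_ext)

    def test_envelope_past_protein_end_rejected(self):
        with pytest.raises(ValueError):
            ct_extension_length(100, 101)


class TestClassify:
    def test_no_extension_is_short(self):
        call = classify_architecture(_muf(aa=200, env_to=150), [], {"Ntox50"})
        assert call.arch_class is ArchClass.SHORT and not call.has_extension

    def test_toxin_domain_in_extension(self):
        hits = [_hit("Ntox50", ProfileClass.TOXIN, (250, 330))]
        call = classify_architecture(_muf(aa=350, env_to=150), hits, {"Ntox50"})
        assert call.arch_class is ArchClass.CT_TOXIN
        assert call.ct_toxin_domains == ("Ntox50",)

    def test_ctmad_only_extension_is_unknown_with_flag(self):
        hits = [_hit("Ct_MAD", ProfileClass.CT_MAD, (200, 280))]
        call = classify_architecture(_muf(aa=300, env_to=150), hits, {"Ntox50"})
        assert call.arch_class is ArchClass.CT_UNKNOWN and call.ctmad
        assert call.label == "CT_MAD"

    def test_nterminal_toxin_hit_does_not_set_class(self):
        # stray hit before the MuF domain: reported, never class-determining
        hits = [_hit("Ntox50", ProfileClass.TOXIN, (1, 60))]
        call = classify_architecture(_muf(aa=400, env_to=150), hits, {"Ntox50"})
        assert call.arch_class is ArchClass.CT_UNKNOWN
        assert call.stray_domains == ("Ntox50",)

    def test_midpoint_rule_tolerates_envelope_overlap(self):
        # envelope starts inside the MuF domain but its midpoint is past it
        hits = [_hit("Ntox50", ProfileClass.TOXIN, (140, 260))]
        call = classify_architecture(_muf(aa=400, env_to=150), hits, {"Ntox50"})
        assert call.arch_class is ArchClass.CT_TOXIN

    def test_empty_catalog_gives_unknown(self):
        hits = [_hit("Ntox50", ProfileClass.TOXIN, (250, 330))]
        call = classify_architecture(_muf(aa=350, env_to=150), hits, set())
        assert call.arch_class is ArchClass.CT_UNKNOWN

    @settings(max_examples=50, derandomize=True)
    @given(
        subset=st.sets(st.sampled_from(["Ntox50", "EndoU_bacteria", "cd13442"])),
        extra=st.sets(st.sampled_from(["ADPRT", "RelA_SpoT", "Tox-REase-5"])),
    )
    def test_enlarging_catalog_never_demotes_toxin_calls(self, subset, extra):
        hits = [
            _hit("Ntox50", ProfileClass.OTHER, (250, 330)),
            _hit("ADPRT", ProfileClass.OTHER, (340, 390)),
        ]
        muf = _muf(aa=400, env_to=150)
        small = classify_architecture(muf, hits, subset)
        big = classify_architecture(muf, hits, subset | extra)
        if small.arch_class is ArchClass.CT_TOXIN:
            assert big.arch_class is ArchClass.CT_TOXIN

    def test_classes_partition_all_calls(self, minimal_result):
        counts = minimal_result.proteins["arch_class"].value_counts()
        assert counts.sum() == len(minimal_result.proteins)
        assert set(counts.index) <= {c.value for c in ArchClass}

    def test_noiseless_architectures_match_ground_truth(self, minimal_ds, minimal_result):
        truth = minimal_ds.gene_truth.set_index("gene_id")["architecture"]
        called = minimal_result.proteins.set_index("gene_id")["architecture"]
        assert called.sort_index().equals(truth.sort_index())


class TestCatalogTable:
    def test_read_and_dedup(self):
        text = "name\tactivity\nNtox50\tnuclease\nNtox50\tnuclease\n"
        assert toxin_catalog_from_table(io.StringIO(text)) == {"Ntox50": "nuclease"}

    def test_conflicting_duplicates_rejected(self):
        text = "Ntox50\tnuclease\nNtox50\tpeptidase\n"
        with pytest.raises(ParseError, match="conflicting"):
            toxin_catalog_from_table(io.StringIO(text))
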
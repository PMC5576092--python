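"""Generator contracts: determinism, planted structure, configuration errors."""

import math

import numpy as np
import pytest

from muftox.io import MUF_CLASSES
from muftox.simulate import (
    FIXTURE_SPECS,
    SyntheticSpec,
    generate_dataset,
    make_fixture,
    write_dataset,
)


def _tiny(**overrides):
    base = dict(seed=11, n_phage_genomes=15, n_bacterial_genomes=10,
                mean_genes_per_bacterium=80)
    base.update(overrides)
    return SyntheticSpec(**base)


class TestDeterminism:
    def test_same_spec_same_bytes(self, tmp_path):
        for sub in ("a", "b"):
            write_dataset(generate_dataset(_tiny()), tmp_path / sub)
        for name in ("genes.tsv", "hits.domtblout", "regions.bed", "genomes.tsv",
                     "truth_genes.tsv", "truth_genomes.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_dataset(_tiny(seed=1))
        b = generate_dataset(_tiny(seed=2))
        assert not a.genomes.equals(b.genomes) or len(a.gene_truth) != len(b.gene_truth)


class TestSpecValidation:
    def test_prophage_range_must_straddle_18kb(self):
        with pytest.raises(ValueError, match="straddle"):
            _tiny(prophage_len_range=(19_000, 45_000))

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            _tiny(architecture_mix={"SHORT": 0.5, "CT_TOXIN": 0.2})

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError, match="probability"):
            _tiny(p_muf_phage=1.5)


class TestPlantedStructure:
    def test_degenerate_short_mix_has_no_toxins_or_immunity(self):
        ds = generate_dataset(
            _tiny(architecture_mix={"SHORT": 1.0, "CT_TOXIN": 0.0,
                                    "CT_UNKNOWN": 0.0, "CT_MAD": 0.0})
        )
        assert set(ds.gene_truth["architecture"]) <= {"SHORT"}
        assert not ds.gene_truth["planted_immunity"].any()

    def test_muf_carrier_count_within_binomial_bound(self):
        spec = SyntheticSpec(seed=97, n_phage_genomes=1000, n_bacterial_genomes=0,
                             p_muf_phage=0.35)
        ds = generate_dataset(spec)
        n_tailed = int(ds.genome_truth["tailed"].sum())
        n_muf = int(ds.genome_truth["has_muf"].sum())
        sigma = math.sqrt(n_tailed * 0.35 * 0.65)
        assert abs(n_muf - 0.35 * n_tailed) <= 3 * sigma

    def test_every_planted_muf_has_a_muf_hit(self):
        ds = generate_dataset(_tiny())
        with_hit = {
            h.protein_id for h in ds.hits if h.profile_class in MUF_CLASSES
        }
        assert set(ds.gene_truth["gene_id"]) <= with_hit

    def test_noiseless_hits_equal_truth_exactly(self):
        # with no spurious hits, the set of MuF-hit proteins IS the truth set
        ds = generate_dataset(_tiny(p_false_hit=0.0))
        with_hit = {h.protein_id for h in ds.hits if h.profile_class in MUF_CLASSES}
        assert with_hit == set(ds.gene_truth["gene_id"])

    def test_false_hits_appear_at_positive_rate(self):
        noisy = generate_dataset(_tiny(p_false_hit=0.2))
        clean = generate_dataset(_tiny(p_false_hit=0.0))
        assert len(noisy.hits) > len(clean.hits)

    def test_immunity_orfs_only_downstream_of_mufs(self):
        ds = generate_dataset(_tiny())
        truth = ds.gene_truth.set_index("gene_id")
        by_id = {g.gene_id: g for recs in ds.genes.values() for g in recs}
        for gene_id, row in truth.iterrows():
            gene = by_id[gene_id]
            replicon = ds.genes[gene.replicon_id]
            step = 1 if gene.strand == "+" else -1
            ds_gene = replicon[gene.rank + step]
            assert (ds_gene.aa_length < 150) == row["planted_small_orf"]


class TestFixtures:
    def test_minimal_covers_every_category(self, minimal_ds):
        assert set(minimal_ds.gene_truth["architecture"]) == {
            "SHORT", "CT_TOXIN", "CT_UNKNOWN", "CT_MAD"
        }
        assocs = set(minimal_ds.gene_truth["association"]) - {""}
        assert {"IN_PROPHAGE", "IN_REMNANT", "NEAR_PACKAGING"} <= assocs
        assert len(minimal_ds.genomes) <= 50

    def test_fixture_is_deterministic(self, minimal_ds):
        again = make_fixture("minimal")
        assert again.gene_truth.equals(minimal_ds.gene_truth)

    def test_unknown_fixture_rejected(self):
        with pytest.raises(KeyError, match="unknown fixture"):
            make_fixture("nope")

    def test_empty_fixture_has_no_muf(self, empty_ds):
        assert len(empty_ds.gene_truth) == 0
        assert not empty_ds.genome_truth["has_muf"].any()

    def test_registry_specs_validate(self):
        for spec in FIXTURE_SPECS.values():
            assert isinstance(spec, SyntheticSpec)
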
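"""Marker distances, prophage association, and lysogeny classification."""

import numpy as np
import pytest

from muftox.context import (
    Association,
    ContextProfile,
    assign_association,
    classify_lysogen,
    marker_distances,
    oriented_offset,
)
from muftox.io import GeneRecord, ProfileClass, ProphageRegion


def _gene(start=10_000, end=11_000, strand="+", rank=10, gene_id="m"):
    return GeneRecord(gene_id, "B", "B_c1", start, end, strand, rank, 300)


def _region(start, end):
    return ProphageRegion("B", "B_c1", start, end)


def _ctx(dp=None, dtl=None, dts=None):
    return ContextProfile("m", dp, dtl, dts)


class TestMarkerDistances:
    def test_portal_one_after_muf_is_plus_one(self):
        dp, _, _ = marker_distances(10, {ProfileClass.PORTAL: [11]}, n_genes=30)
        assert dp == 1

    def test_no_marker_within_window_is_none(self):
        dp, dtl, dts = marker_distances(10, {ProfileClass.PORTAL: [21]}, n_genes=40)
        assert dp is None and dtl is None and dts is None

    def test_minimal_absolute_offset_among_candidates(self):
        dp, _, _ = marker_distances(10, {ProfileClass.PORTAL: [3, 12]}, n_genes=30)
        assert dp == 2

    def test_tie_between_sides_resolves_positive(self):
        dp, _, _ = marker_distances(10, {ProfileClass.PORTAL: [7, 13]}, n_genes=30)
        assert dp == 3

    def test_window_boundary_inclusive_exclusive(self):
        dp, _, _ = marker_distances(10, {ProfileClass.PORTAL: [20]}, n_genes=40)
        assert dp == 10
        dp, _, _ = marker_distances(10, {ProfileClass.PORTAL: [21]}, n_genes=40)
        assert dp is None

    def test_out_of_range_rank_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            marker_distances(30, {}, n_genes=30)

    def test_circular_wraps_around_origin(self):
        dp, _, _ = marker_distances(
            0, {ProfileClass.PORTAL: [29]}, n_genes=30, circular=True
        )
        assert dp == -1

    def test_matches_exhaustive_scan_on_random_replicons(self):
        # independent oracle: check every marker rank, keep the smallest
        # absolute signed offset, prefer + on ties
        def naive(muf, ranks, window):
            best = None
            for r in ranks:
                off = r - muf
                if off == 0 or abs(off) > window:
                    continue
                if (
                    best is None
                    or abs(off) < abs(best)
                    or (abs(off) == abs(best) and off > best)
                ):
                    best = off
            return best

        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(5, 200))
            muf = int(rng.integers(0, n))
            ranks = {
                cls: rng.integers(0, n, size=rng.integers(0, 6)).tolist()
                for cls in (ProfileClass.PORTAL, ProfileClass.TLS, ProfileClass.TSS)
            }
            got = marker_distances(muf, ranks, n_genes=n)
            want = tuple(
                naive(muf, ranks[cls], 10)
                for cls in (ProfileClass.PORTAL, ProfileClass.TLS, ProfileClass.TSS)
            )
            assert got == want


def test_oriented_offset_is_strand_reflected():
    # portal one rank before a + strand muf gene: muf is at +1 downstream
    assert oriented_offset(-1, "+") == 1
    # portal one rank after a - strand muf gene: also +1 downstream
    assert oriented_offset(1, "-") == 1
    assert oriented_offset(None, "+") is None


class TestAssociation:
    def test_large_region_is_prophage(self):
        assert (
            assign_association(_gene(), [_region(0, 40_000)], _ctx())
            is Association.IN_PROPHAGE
        )

    def test_small_region_is_remnant(self):
        assert (
            assign_association(_gene(), [_region(5_000, 17_000)], _ctx())
            is Association.IN_REMNANT
        )

    def test_marker_without_region_is_near_packaging(self):
        assert (
            assign_association(_gene(), [], _ctx(dp=2)) is Association.NEAR_PACKAGING
        )

    def test_nothing_is_unassociated(self):
        assert assign_association(_gene(), [], _ctx()) is Association.UNASSOCIATED

    def test_midpoint_decides_membership(self):
        gene = _gene(start=10_000, end=11_000)
        # region covers the start but not the midpoint
        assert (
            assign_association(gene, [_region(0, 10_200)], _ctx())
            is Association.UNASSOCIATED
        )

    def test_overlapping_size_classes_largest_wins(self):
        regions = [_region(9_000, 20_000), _region(0, 40_000)]
        assert assign_association(_gene(), regions, _ctx()) is Association.IN_PROPHAGE


class TestLysogeny:
    def test_single_large_prophage_makes_lysogen(self):
        assert classify_lysogen([_region(0, 20_000)])

    def test_small_elements_do_not(self):
        assert not classify_lysogen([_region(0, 17_000)])
        assert not classify_lysogen([])
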
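"""Genomic context of muf genes: distances to packaging markers and
prophage association.

muf genes live in the DNA-packaging module of tailed phages, next to the
portal (P) and terminase (large subunit TLS, small subunit TSS) genes.  For
each muf gene we compute the signed gene-rank offset to the nearest gene of
each marker class within a +/-10-gene window, and for bacterial muf genes a
prophage-association category: inside a large prophage (> 18 kb), inside a
remnant (<= 18 kb), near packaging genes outside any detected element, or
unassociated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .io import GeneRecord, ProfileClass, ProphageRegion
from .thresholds import DEFAULT_THRESHOLDS

logger = logging.getLogger(__name__)


class Association(str, Enum):
    IN_PROPHAGE = "IN_PROPHAGE"
    IN_REMNANT = "IN_REMNANT"
    NEAR_PACKAGING = "NEAR_PACKAGING"
    UNASSOCIATED = "UNASSOCIATED"


@dataclass(frozen=True)
class ContextProfile:
    """Signed gene-rank distances from one muf gene to the nearest marker of
    each class (``None`` = no marker within the window).  The sign convention
    is positional: d = marker_rank - muf_rank, so d = +1 places the marker
    immediately after the muf gene in replicon order."""

    gene_id: str
    d_portal: int | None
    d_tls: int | None
    d_tss: int | None
    window: int = DEFAULT_THRESHOLDS.context_window
    association: Association | None = None

    @property
    def near_packaging(self) -> bool:
        return any(d is not None for d in (self.d_portal, self.d_tls, self.d_tss))


def _min_signed_offset(
    muf_rank: int,
    marker_ranks: Iterable[int],
    window: int,
    n_genes: int,
    circular: bool,
) -> int | None:
    best: int | None = None
    for r in marker_ranks:
        if circular:
            off = (r - muf_rank) % n_genes
            if off > n_genes // 2:
                off -= n_genes
        else:
            off = r - muf_rank
        if off == 0 or abs(off) > window:
            continue
        if best is None or abs(off) < abs(best) or (abs(off) == abs(best) and off > best):
            best = off
    return best


def marker_distances(
    muf_rank: int,
    marker_ranks: Mapping[ProfileClass, Sequence[int]],
    window: int = DEFAULT_THRESHOLDS.context_window,
    n_genes: int | None = None,
    circular: bool = False,
) -> tuple[int | None, int | None, int | None]:
    """Signed offsets (portal, TLS, TSS) of minimal absolute value.

    Offsets are positional (marker_rank - muf_rank); a tie between -k and +k
    resolves to +k; ``None`` when no marker of that class lies within the
    window.  ``n_genes`` bounds the replicon (required for the circular
    wrap-around and for rank validation).
    """
    if n_genes is not None and not 0 <= muf_rank < n_genes:
        raise ValueError(f"muf_rank {muf_rank} out of range [0, {n_genes})")
    if circular and n_genes is None:
        raise ValueError("circular distances require n_genes")
    n = n_genes if n_genes is not None else 0
    out = []
    for cls in (ProfileClass.PORTAL, ProfileClass.TLS, ProfileClass.TSS):
        out.append(
            _min_signed_offset(muf_rank, marker_ranks.get(cls, ()), window, n, circular)
        )
    return out[0], out[1], out[2]


def oriented_offset(d_positional: int | None, strand: str) -> int | None:
    """Convert a positional marker offset into the transcription-oriented
    offset of the muf gene relative to the marker: +1 means the muf gene is
    the marker's immediate downstream neighbour in transcription order."""
    if d_positional is None:
        return None
    return -d_positional if strand == "+" else d_positional


def assign_association(
    muf_gene: GeneRecord,
    regions: Sequence[ProphageRegion],
    ctx: ContextProfile,
    prophage_min: int = DEFAULT_THRESHOLDS.prophage_min,
) -> Association:
    """Prophage-association category of a bacterial muf gene.

    The gene midpoint decides region membership.  A containing element
    strictly longer than ``prophage_min`` bp is a prophage; a smaller one a
    remnant (exactly 18 kb falls to the remnant side); with no containing
    element, a packaging marker within the context window marks a likely
    remnant context (NEAR_PACKAGING); otherwise the gene is unassociated.
    When overlapping regions of both size classes contain the gene, the
    largest wins.
    """
    mid = muf_gene.midpoint
    containing = [
        r for r in regions if r.replicon_id == muf_gene.replicon_id and r.contains(mid)
    ]
    if containing:
        if len({r.length > prophage_min for r in containing}) > 1:
            logger.warning(
                "gene %s lies in overlapping regions of different size classes; "
                "keeping the largest", muf_gene.gene_id,
            )
        best = max(containing, key=lambda r: r.length)
        return Association.IN_PROPHAGE if best.length > prophage_min else Association.IN_REMNANT
    if ctx.near_packaging:
        return Association.NEAR_PACKAGING
    return Association.UNASSOCIATED


def classify_lysogen(
    regions: Iterable[ProphageRegion],
    prophage_min: int = DEFAULT_THRESHOLDS.prophage_min,
) -> bool:
    """A genome is a lysogen when it carries at least one element strictly
    longer than the prophage size cutoff."""
    return any(r.length > prophage_min for r in regions)


def marker_ranks_by_replicon(
    genes_by_replicon: Mapping[str, Sequence[GeneRecord]],
    marker_class_of_protein: Mapping[str, ProfileClass],
) -> dict[str, dict[ProfileClass, list[int]]]:
    """Index marker gene ranks per replicon from per-protein marker calls."""
    out: dict[str, dict[ProfileClass, list[int]]] = {}
    for replicon_id, genes in genes_by_replicon.items():
        ranks: dict[ProfileClass, list[int]] = {}
        for g in genes:
            cls = marker_class_of_protein.get(g.gene_id)
            if cls is not None:
                ranks.setdefault(cls, []).append(g.rank)
        out[replicon_id] = ranks
    return out
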
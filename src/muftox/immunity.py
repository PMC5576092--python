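"""Candidate immunity ORFs downstream of muf genes.

Toxin producers protect themselves with a small immunity protein whose gene
sits immediately downstream of the toxin gene.  Immunity ORFs are hard to
find by homology (short, no known domains), so the screen is positional:
for every MuF protein, take the next annotated gene in the muf gene's
transcription direction and flag it when its product is shorter than 150 aa.
Co-orientation and the intergenic gap are recorded but not required, so
users can filter further.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .architecture import ArchitectureCall
from .io import GeneRecord
from .screen import MufProtein
from .thresholds import DEFAULT_THRESHOLDS


@dataclass(frozen=True)
class ImmunityCandidate:
    muf_gene_id: str
    muf_label: str                      # architecture label of the MuF protein
    downstream_gene_id: str | None
    downstream_aa_length: int | None
    co_oriented: bool
    gap_bp: int | None
    is_small: bool

    def __post_init__(self) -> None:
        # is_small may be computed with a non-default cutoff; only guard the
        # impossible case of a small flag without a downstream gene.
        if self.is_small and self.downstream_aa_length is None:
            raise ValueError(f"{self.muf_gene_id}: is_small without a downstream gene")


def downstream_gene(
    replicon_genes: Sequence[GeneRecord],
    muf_gene: GeneRecord,
    circular: bool = False,
) -> GeneRecord | None:
    """Next annotated gene in the muf gene's transcription direction.

    rank+1 for a + strand gene, rank-1 for a - strand gene; ``None`` at the
    replicon end unless the replicon is circular.
    """
    step = 1 if muf_gene.strand == "+" else -1
    idx = muf_gene.rank + step
    n = len(replicon_genes)
    if circular:
        idx %= n
        if idx == muf_gene.rank:
            return None
    elif not 0 <= idx < n:
        return None
    return replicon_genes[idx]


def flag_candidates(
    mufs: Iterable[MufProtein],
    arch_by_protein: Mapping[str, ArchitectureCall],
    genes_by_replicon: Mapping[str, Sequence[GeneRecord]],
    genes_by_id: Mapping[str, GeneRecord],
    small_orf_max: int = DEFAULT_THRESHOLDS.small_orf_max,
    circular: bool = False,
) -> list[ImmunityCandidate]:
    """One candidate record per MuF protein (strict < cutoff for small)."""
    out: list[ImmunityCandidate] = []
    for muf in mufs:
        gene = genes_by_id[muf.gene_id]
        ds = downstream_gene(genes_by_replicon[gene.replicon_id], gene, circular)
        if ds is None:
            out.append(
                ImmunityCandidate(
                    muf_gene_id=muf.gene_id,
                    muf_label=arch_by_protein[muf.protein_id].label,
                    downstream_gene_id=None,
                    downstream_aa_length=None,
                    co_oriented=False,
                    gap_bp=None,
                    is_small=False,
                )
            )
            continue
        gap = ds.start - gene.end if gene.strand == "+" else gene.start - ds.end
        out.append(
            ImmunityCandidate(
                muf_gene_id=muf.gene_id,
                muf_label=arch_by_protein[muf.protein_id].label,
                downstream_gene_id=ds.gene_id,
                downstream_aa_length=ds.aa_length,
                co_oriented=ds.strand == gene.strand,
                gap_bp=gap,
                is_small=ds.aa_length < small_orf_max,
            )
        )
    out.sort(key=lambda c: c.muf_gene_id)
    return out


def length_distributions(
    candidates: Iterable[ImmunityCandidate],
    labels: Sequence[str] = ("CT_TOXIN", "CT_UNKNOWN", "SHORT"),
    merge_ctmad: bool = True,
) -> dict[str, np.ndarray]:
    """Downstream-product length samples keyed by architecture label.

    Candidates without a downstream gene are excluded.  With
    ``merge_ctmad=True`` the CT_MAD label is folded into CT_UNKNOWN, giving
    the three-way grouping used for the toxin-vs-short length comparison.
    """
    samples: dict[str, list[int]] = {lab: [] for lab in labels}
    for c in candidates:
        if c.downstream_aa_length is None:
            continue
        lab = c.muf_label
        if merge_ctmad and lab == "CT_MAD":
            lab = "CT_UNKNOWN"
        if lab in samples:
            samples[lab].append(c.downstream_aa_length)
    return {lab: np.asarray(vals, dtype=int) for lab, vals in samples.items()}
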
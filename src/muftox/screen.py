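"""Turn raw domain hits into MuF protein calls.

A protein is a MuF protein when it carries at least one gathering-threshold
hit from one of the four MuF family profiles (MuF1 = Phage_Mu_F/PF04233,
MuF2 = Phage_min_cap2/PF06152, plus the context-defined MuF3 and MuF4).
When several profiles match the same protein, only the best full-sequence
E-value profile is kept, so each protein receives exactly one family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import (
    DomainHit,
    GeneRecord,
    MUF_CLASSES,
    ProfileClass,
    flatten_genes,
    index_genes_by_id,
)


@dataclass(frozen=True)
class MufProtein:
    """A protein carrying a MuF domain, with its single family assignment."""

    protein_id: str
    genome_id: str
    gene_id: str
    family: ProfileClass
    muf_env_from: int
    muf_env_to: int
    aa_length: int
    best_evalue: float

    def __post_init__(self) -> None:
        if self.family not in MUF_CLASSES:
            raise ValueError(f"{self.protein_id}: family must be a MuF class")
        if self.muf_env_to > self.aa_length:
            raise ValueError(
                f"{self.protein_id}: envelope end {self.muf_env_to} exceeds "
                f"protein length {self.aa_length}"
            )


def select_best_profile(
    hits: Sequence[DomainHit],
    classes: Iterable[ProfileClass] | None = None,
) -> DomainHit | None:
    """Pick the best-E-value hit for one protein, optionally class-filtered.

    Ranking is by smallest full-sequence E-value, ties broken by higher
    bitscore, then lexicographic profile name.  Hits that did not pass the
    gathering threshold are ignored.  Returns ``None`` when nothing passes.
    """
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(protein_ids)}")
    wanted = frozenset(classes) if classes is not None else None
    pool = [
        h
        for h in hits
        if h.passed_ga and (wanted is None or h.profile_class in wanted)
    ]
    if not pool:
        return None
    return min(pool, key=lambda h: (h.full_evalue, -h.bitscore, h.profile_name))


def apply_ga_table(
    hits: Iterable[DomainHit],
    ga_bitscores: Mapping[str, float],
) -> list[DomainHit]:
    """Re-flag raw hits against per-profile gathering bitscore thresholds.

    Profiles absent from the table fail (conservative): a hit only passes
    when its bitscore reaches the profile's GA cutoff.
    """
    out = []
    for h in hits:
        ga = ga_bitscores.get(h.profile_name)
        passed = ga is not None and h.bitscore >= ga
        out.append(DomainHit(
            protein_id=h.protein_id,
            profile_name=h.profile_name,
            profile_class=h.profile_class,
            full_evalue=h.full_evalue,
            bitscore=h.bitscore,
            env_from=h.env_from,
            env_to=h.env_to,
            passed_ga=passed,
        ))
    return out


def group_hits_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    grouped: dict[str, list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault(h.protein_id, []).append(h)
    return grouped


def call_muf_proteins(
    hits: Iterable[DomainHit],
    genes: Mapping[str, Sequence[GeneRecord]] | Iterable[GeneRecord],
) -> list[MufProtein]:
    """Call one :class:`MufProtein` per protein with a passing MuF-class hit.

    The family and envelope come from the best-E-value MuF hit of the
    protein.  Proteins appearing in the hit table but absent from the gene
    table are an input inconsistency and raise an error listing the orphans.
    """
    by_id = index_genes_by_id(genes)
    grouped = group_hits_by_protein(hits)

    orphans = sorted(
        pid
        for pid, phits in grouped.items()
        if any(h.profile_class in MUF_CLASSES and h.passed_ga for h in phits)
        and pid not in by_id
    )
    if orphans:
        raise ValueError(
            f"MuF hits on proteins absent from the gene table: {orphans}"
        )

    calls: list[MufProtein] = []
    for pid in grouped:
        best = select_best_profile(grouped[pid], MUF_CLASSES)
        if best is None:
            continue
        gene = by_id[pid]
        calls.append(
            MufProtein(
                protein_id=pid,
                genome_id=gene.genome_id,
                gene_id=gene.gene_id,
                family=best.profile_class,
                muf_env_from=best.env_from,
                muf_env_to=min(best.env_to, gene.aa_length),
                aa_length=gene.aa_length,
                best_evalue=best.full_evalue,
            )
        )
    calls.sort(key=lambda m: (m.genome_id, m.gene_id))
    return calls
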
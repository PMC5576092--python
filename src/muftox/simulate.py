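"""Synthetic phage and bacterial genome annotations with planted MuF biology.

The generator emits exactly the tables the pipeline consumes (gene tables,
HMMER-style per-domain hit tables, prophage regions, genome metadata) plus a
ground-truth record of everything planted, so every downstream stage can be
tested without any genome download.

What is emulated, per genome kind:

* tailed phages carry a DNA-packaging module (terminase small/large subunit,
  portal) and, with probability ``p_muf_phage``, a *muf* gene placed at a
  configurable transcription-oriented offset from the portal gene (mass
  concentrated at +1, i.e. immediately downstream);
* bacterial chromosomes may be lysogens (decoy prophages > 18 kb), and when
  they carry a *muf* gene its context is drawn from ``association_mix``:
  inside a large prophage, inside a remnant (< 18 kb element), next to a
  free-standing packaging-gene cluster, or isolated;
* MuF protein architectures follow ``architecture_mix`` (short, toxin
  extension, unknown extension, Ct_MAD extension); toxin extensions carry a
  catalogued toxin-domain hit, Ct_MAD extensions a Ct_MAD hit;
* the gene immediately downstream of each *muf* gene (in transcription
  orientation) encodes a small ORF (< 150 aa) with an architecture-dependent
  probability - high after toxins, low after short MuFs - and a decoy of
  >= 150 aa otherwise, which makes the small-ORF rule discriminative by
  construction;
* background genes draw log-normal lengths (mean ~280 aa) and can receive
  spurious domain hits at rate ``p_false_hit`` with E-values above the
  planted-hit range, so best-hit selection is exercised.

All randomness flows from a single :class:`numpy.random.Generator` seeded by
``SyntheticSpec.seed``; identical specs produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .architecture import DEFAULT_TOXIN_CATALOG, write_toxin_catalog
from .io import (
    DEFAULT_PROFILE_CLASSES,
    DomainHit,
    GeneRecord,
    ProfileClass,
    ProphageRegion,
    classify_profile,
    write_domtblout,
    write_gene_table,
    write_regions,
)

TAILED_FAMILIES = ("Siphoviridae", "Myoviridae", "Podoviridae")

_MARKER_PROFILES = {
    ProfileClass.PORTAL: ("Phage_portal", (380, 620)),
    ProfileClass.TLS: ("Terminase_L", (360, 560)),
    ProfileClass.TSS: ("Terminase_S", (120, 240)),
}

_ARCHS = ("SHORT", "CT_TOXIN", "CT_UNKNOWN", "CT_MAD")


def _check_dist(name: str, dist: Mapping, total: float = 1.0) -> None:
    if abs(sum(dist.values()) - total) > 1e-9:
        raise ValueError(f"{name} must sum to {total}, got {sum(dist.values())}")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} has negative probabilities")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    The defaults reproduce the regime the pipeline is meant for: 35% of
    tailed phages carry a *muf* gene; 50% of bacteria are lysogens; among
    MuF proteins ~63% are short, ~13% carry a toxin extension and the rest
    an unknown extension (a third of which shows the Ct_MAD domain); 89.4%
    of toxin-class *muf* genes and 25.5% of short-class ones are followed by
    a small ORF; 96% of bacterial *muf* genes are prophage-associated; and
    70% of *muf* genes sit immediately downstream (+1) of the portal gene.
    """

    seed: int
    n_phage_genomes: int = 200
    n_bacterial_genomes: int = 200
    p_muf_phage: float = 0.35
    p_muf_bacteria: float = 0.25
    p_prophage: float = 0.50
    prophage_len_range: tuple[int, int] = (8_000, 45_000)
    architecture_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "SHORT": 0.628,
            "CT_TOXIN": 0.126,
            "CT_UNKNOWN": 0.164,
            "CT_MAD": 0.082,
        }
    )
    p_small_orf_given_toxin: float = 0.894
    p_small_orf_given_short: float = 0.255
    p_small_orf_given_unknown: float = 0.255
    muf_offset_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.15, 3: 0.10, 4: 0.05}
    )
    association_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "IN_PROPHAGE": 0.90,
            "IN_REMNANT": 0.03,
            "NEAR_PACKAGING": 0.03,
            "UNASSOCIATED": 0.04,
        }
    )
    p_false_hit: float = 0.0
    mean_genes_per_phage: int = 50
    mean_genes_per_bacterium: int = 250
    p_module_minus_strand: float = 0.25
    p_secondary_muf_hit: float = 0.30
    p_extra_muf: float = 0.0
    p_temperate: float = 0.60
    lifestyle_labeled_fraction: float = 0.55
    family_mix: Mapping[str, float] = field(
        default_factory=lambda: {"MuF1": 0.50, "MuF2": 0.20, "MuF3": 0.18, "MuF4": 0.12}
    )
    clade_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "Firmicutes": 0.40,
            "Proteobacteria": 0.35,
            "Actinobacteria": 0.15,
            "Bacteroidetes": 0.10,
        }
    )
    phage_family_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "Siphoviridae": 0.50,
            "Myoviridae": 0.26,
            "Podoviridae": 0.19,
            "Inoviridae": 0.05,
        }
    )
    #: optional per-clade architecture mixes (plants a clade-architecture
    #: association; None = no effect)
    clade_architecture_mix: Mapping[str, Mapping[str, float]] | None = None
    #: optional per-lifestyle / per-family muf-carriage probabilities
    p_muf_by_lifestyle: Mapping[str, float] | None = None
    p_muf_by_family: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        probs = {
            "p_muf_phage": self.p_muf_phage,
            "p_muf_bacteria": self.p_muf_bacteria,
            "p_prophage": self.p_prophage,
            "p_small_orf_given_toxin": self.p_small_orf_given_toxin,
            "p_small_orf_given_short": self.p_small_orf_given_short,
            "p_small_orf_given_unknown": self.p_small_orf_given_unknown,
            "p_false_hit": self.p_false_hit,
            "p_module_minus_strand": self.p_module_minus_strand,
            "p_secondary_muf_hit": self.p_secondary_muf_hit,
            "p_extra_muf": self.p_extra_muf,
            "p_temperate": self.p_temperate,
            "lifestyle_labeled_fraction": self.lifestyle_labeled_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        _check_dist("architecture_mix", self.architecture_mix)
        _check_dist("muf_offset_dist", self.muf_offset_dist)
        _check_dist("association_mix", self.association_mix)
        _check_dist("family_mix", self.family_mix)
        _check_dist("clade_mix", self.clade_mix)
        _check_dist("phage_family_mix", self.phage_family_mix)
        if set(self.architecture_mix) - set(_ARCHS):
            raise ValueError(f"architecture_mix keys must be among {_ARCHS}")
        if any(o == 0 for o in self.muf_offset_dist):
            raise ValueError("muf offsets are non-zero")
        lo, hi = self.prophage_len_range
        if not lo < 18_000 < hi:
            raise ValueError(
                "prophage_len_range must straddle 18,000 bp to exercise the "
                f"remnant rule, got {self.prophage_len_range}"
            )

    @property
    def max_offset(self) -> int:
        return max(abs(o) for o in self.muf_offset_dist)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["architecture_mix"] = dict(self.architecture_mix)
        d["muf_offset_dist"] = {str(k): v for k, v in self.muf_offset_dist.items()}
        return d


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    genes: dict[str, list[GeneRecord]]
    hits: list[DomainHit]
    regions: list[ProphageRegion]
    genomes: pd.DataFrame
    gene_truth: pd.DataFrame
    genome_truth: pd.DataFrame
    toxin_catalog: dict[str, str]

    @property
    def protein_lengths(self) -> dict[str, int]:
        return {
            g.gene_id: g.aa_length for recs in self.genes.values() for g in recs
        }


def _choice(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


class _Plan:
    """Mutable per-genome layout before coordinates are assigned."""

    def __init__(self, rng: np.random.Generator, n: int) -> None:
        aa = np.exp(rng.normal(math.log(280.0), 0.45, size=n))
        self.aa = np.clip(aa, 60, 1800).astype(int)
        self.strand = np.where(rng.random(n) < 0.5, "+", "-")
        self.product = [""] * n
        self.hits: list[list[tuple[str, float, float, int, int]]] = [[] for _ in range(n)]


def _plant_marker(
    rng: np.random.Generator, plan: _Plan, rank: int, cls: ProfileClass, strand: str
) -> None:
    name, (lo, hi) = _MARKER_PROFILES[cls]
    plan.aa[rank] = int(rng.integers(lo, hi))
    plan.strand[rank] = strand
    plan.product[rank] = name.replace("_", " ").lower()
    env_from = int(rng.integers(3, 15))
    env_to = max(env_from + 30, int(plan.aa[rank]) - int(rng.integers(0, 10)))
    env_to = min(env_to, int(plan.aa[rank]))
    evalue = 10.0 ** rng.uniform(-80, -30)
    plan.hits[rank].append((name, evalue, float(rng.uniform(150, 500)), env_from, env_to))


def _plan_muf_site(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    plan: _Plan,
    muf_rank: int,
    clade: str,
    toxin_names: Sequence[str],
    with_module: bool = True,
    with_terminases: bool = True,
) -> dict:
    """Overwrite plan slots around ``muf_rank`` with a muf gene and its
    context; returns the planted ground truth for the site."""
    strand = "-" if rng.random() < spec.p_module_minus_strand else "+"
    sgn = 1 if strand == "+" else -1
    offset = int(_choice(rng, spec.muf_offset_dist))

    mix = spec.architecture_mix
    if spec.clade_architecture_mix and clade in spec.clade_architecture_mix:
        mix = spec.clade_architecture_mix[clade]
    arch = str(_choice(rng, mix))
    family_name = str(_choice(rng, spec.family_mix))

    marker_ranks: dict[ProfileClass, int] = {}
    if with_module:
        portal = muf_rank - sgn * offset
        marker_ranks[ProfileClass.PORTAL] = portal
        if with_terminases:
            marker_ranks[ProfileClass.TLS] = portal - sgn
            marker_ranks[ProfileClass.TSS] = portal - 2 * sgn
        for cls, rank in marker_ranks.items():
            _plant_marker(rng, plan, rank, cls, strand)

    # the MuF protein itself
    env_from = int(rng.integers(1, 25))
    env_to = env_from + int(rng.integers(130, 181)) - 1
    if arch == "SHORT":
        ext = int(rng.integers(0, 100))
    elif arch == "CT_TOXIN":
        ext = int(rng.integers(110, 261))
    else:
        ext = int(rng.integers(100, 261))
    aa = env_to + ext
    plan.aa[muf_rank] = aa
    plan.strand[muf_rank] = strand
    plan.product[muf_rank] = "phage MuF-like protein"
    evalue = 10.0 ** rng.uniform(-60, -25)
    plan.hits[muf_rank].append(
        (family_name, evalue, float(rng.uniform(120, 400)), env_from, env_to)
    )
    if rng.random() < spec.p_secondary_muf_hit:
        other = str(_choice(rng, {k: 1.0 / (len(spec.family_mix) - 1)
                                  for k in spec.family_mix if k != family_name}))
        e2 = min(1e-6, evalue * 10.0 ** rng.uniform(3, 8))
        shift = int(rng.integers(-5, 6))
        f2 = max(1, env_from + shift)
        t2 = min(aa, env_to + shift)
        plan.hits[muf_rank].append((other, e2, float(rng.uniform(30, 110)), f2, t2))
    if arch == "CT_TOXIN":
        name = toxin_names[int(rng.integers(len(toxin_names)))]
        tf = env_to + int(rng.integers(5, 21))
        tt = min(aa, tf + int(rng.integers(40, 90)))
        plan.hits[muf_rank].append(
            (name, 10.0 ** rng.uniform(-40, -15), float(rng.uniform(60, 250)), tf, tt)
        )
    elif arch == "CT_MAD":
        tf = env_to + int(rng.integers(3, 16))
        tt = min(aa, tf + int(rng.integers(50, 90)))
        plan.hits[muf_rank].append(
            ("Ct_MAD", 10.0 ** rng.uniform(-40, -15), float(rng.uniform(60, 250)), tf, tt)
        )

    # immediate downstream gene: planted small ORF or >= 150 aa decoy
    p_small = {
        "CT_TOXIN": spec.p_small_orf_given_toxin,
        "SHORT": spec.p_small_orf_given_short,
        "CT_UNKNOWN": spec.p_small_orf_given_unknown,
        "CT_MAD": spec.p_small_orf_given_unknown,
    }[arch]
    ds_rank = muf_rank + sgn
    ds_ok = 0 <= ds_rank < len(plan.aa) and ds_rank not in marker_ranks.values()
    planted_small = bool(ds_ok and rng.random() < p_small)
    if ds_ok:
        plan.strand[ds_rank] = strand
        if planted_small:
            plan.aa[ds_rank] = int(rng.integers(50, 150))
            plan.product[ds_rank] = "hypothetical protein"
        else:
            plan.aa[ds_rank] = int(rng.integers(150, 401))
            plan.product[ds_rank] = "hypothetical protein"

    used = set(marker_ranks.values()) | {muf_rank}
    if ds_ok:
        used.add(ds_rank)
    return {
        "muf_rank": muf_rank,
        "strand": strand,
        "offset": offset,
        "family": classify_profile(family_name).value,
        "architecture": arch,
        "planted_small_orf": planted_small,
        "planted_immunity": planted_small and arch == "CT_TOXIN",
        "near_packaging": with_module,
        "used_ranks": used,
    }


def _materialize(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    plan: _Plan,
    genome_id: str,
    replicon_id: str,
    toxin_names: Sequence[str],
) -> tuple[list[GeneRecord], list[DomainHit], int]:
    n = len(plan.aa)
    gaps = rng.integers(20, 200, size=n)
    lens = (plan.aa.astype(np.int64) + 1) * 3
    cum_prev = np.concatenate([[0], np.cumsum(lens)[:-1]])
    starts = np.cumsum(gaps) + cum_prev
    ends = starts + lens

    genes: list[GeneRecord] = []
    hits: list[DomainHit] = []
    spurious_mask = rng.random(n) < spec.p_false_hit
    pool = sorted(
        {"MuF1", "MuF2", "MuF3", "MuF4", "Ct_MAD",
         "Phage_portal", "Terminase_L", "Terminase_S", "DUF4065"} | set(toxin_names)
    )
    for rank in range(n):
        gene_id = f"{genome_id}_g{rank:05d}"
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                genome_id=genome_id,
                replicon_id=replicon_id,
                start=int(starts[rank]),
                end=int(ends[rank]),
                strand=str(plan.strand[rank]),
                rank=rank,
                aa_length=int(plan.aa[rank]),
                product_label=plan.product[rank] or "hypothetical protein",
            )
        )
        for name, evalue, score, env_from, env_to in plan.hits[rank]:
            hits.append(
                DomainHit(
                    protein_id=gene_id,
                    profile_name=name,
                    profile_class=classify_profile(name, toxin_names),
                    full_evalue=evalue,
                    bitscore=score,
                    env_from=env_from,
                    env_to=min(env_to, int(plan.aa[rank])),
                )
            )
        if spurious_mask[rank]:
            name = pool[int(rng.integers(len(pool)))]
            aa = int(plan.aa[rank])
            f = int(rng.integers(1, max(2, aa - 40)))
            t = min(aa, f + int(rng.integers(20, 100)))
            hits.append(
                DomainHit(
                    protein_id=gene_id,
                    profile_name=name,
                    profile_class=classify_profile(name, toxin_names),
                    full_evalue=10.0 ** rng.uniform(-4, 0),
                    bitscore=float(rng.uniform(5, 25)),
                    env_from=f,
                    env_to=max(f, t),
                )
            )
    replicon_len = int(ends[-1]) + int(rng.integers(200, 800))
    return genes, hits, replicon_len


def _resolved_p_muf(spec: SyntheticSpec, family: str, lifestyle: str) -> float:
    p = spec.p_muf_phage
    if spec.p_muf_by_family is not None:
        p = spec.p_muf_by_family.get(family, p)
    if spec.p_muf_by_lifestyle is not None:
        p = spec.p_muf_by_lifestyle.get(lifestyle, p)
    return p


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate one complete synthetic dataset from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    toxin_catalog = dict(DEFAULT_TOXIN_CATALOG)
    toxin_names = sorted(toxin_catalog)

    genes: dict[str, list[GeneRecord]] = {}
    hits: list[DomainHit] = []
    regions: list[ProphageRegion] = []
    meta_rows: list[dict] = []
    gene_truth_rows: list[dict] = []
    genome_truth_rows: list[dict] = []

    margin = spec.max_offset + 3

    for idx in range(spec.n_phage_genomes):
        genome_id = f"PHG{idx:05d}"
        replicon_id = f"{genome_id}_c1"
        family = str(_choice(rng, spec.phage_family_mix))
        tailed = family in TAILED_FAMILIES
        clade = str(_choice(rng, spec.clade_mix))
        lifestyle = "temperate" if rng.random() < spec.p_temperate else "virulent"
        labelled = rng.random() < spec.lifestyle_labeled_fraction
        n = max(25, int(rng.poisson(spec.mean_genes_per_phage)))
        plan = _Plan(rng, n)

        sites: list[dict] = []
        if tailed:
            center = int(rng.integers(margin, n - margin))
            if rng.random() < _resolved_p_muf(spec, family, lifestyle):
                sites.append(
                    _plan_muf_site(rng, spec, plan, center, clade, toxin_names)
                )
                if spec.p_extra_muf > 0 and rng.random() < spec.p_extra_muf:
                    for _ in range(10):
                        c2 = int(rng.integers(margin, n - margin))
                        if abs(c2 - center) > 2 * margin + 2:
                            sites.append(
                                _plan_muf_site(rng, spec, plan, c2, clade, toxin_names)
                            )
                            break
            else:
                strand = "-" if rng.random() < spec.p_module_minus_strand else "+"
                sgn = 1 if strand == "+" else -1
                for k, cls in enumerate(
                    (ProfileClass.PORTAL, ProfileClass.TLS, ProfileClass.TSS)
                ):
                    _plant_marker(rng, plan, center - k * sgn, cls, strand)

        g, h, _ = _materialize(rng, spec, plan, genome_id, replicon_id, toxin_names)
        genes[replicon_id] = g
        hits.extend(h)
        for site in sites:
            gene_truth_rows.append(
                {
                    "gene_id": g[site["muf_rank"]].gene_id,
                    "genome_id": genome_id,
                    "is_muf": True,
                    "family": site["family"],
                    "architecture": site["architecture"],
                    "planted_small_orf": site["planted_small_orf"],
                    "planted_immunity": site["planted_immunity"],
                    "association": "",
                    "near_packaging": site["near_packaging"],
                    "offset": site["offset"],
                }
            )
        meta_rows.append(
            {
                "genome_id": genome_id,
                "replicon_id": replicon_id,
                "kind": "phage",
                "clade": clade,
                "phage_family": family,
                "lifestyle": lifestyle if labelled else "",
            }
        )
        genome_truth_rows.append(
            {
                "genome_id": genome_id,
                "kind": "phage",
                "clade": clade,
                "phage_family": family,
                "lifestyle_true": lifestyle,
                "tailed": tailed,
                "has_muf": bool(sites),
                "lysogen": False,
            }
        )

    rem_lo, rem_hi = spec.prophage_len_range[0], 18_000
    pro_lo, pro_hi = 19_000, max(19_001, spec.prophage_len_range[1])

    # p_prophage is the marginal lysogeny probability; muf genes planted
    # inside prophages already imply lysogeny, so decoy prophages are drawn
    # at the complementary rate that keeps the marginal exact
    p_muf_pro = spec.p_muf_bacteria * spec.association_mix.get("IN_PROPHAGE", 0.0)
    p_decoy = (
        max(0.0, (spec.p_prophage - p_muf_pro) / (1.0 - p_muf_pro))
        if p_muf_pro < 1.0
        else 0.0
    )

    for idx in range(spec.n_bacterial_genomes):
        genome_id = f"BAC{idx:05d}"
        replicon_id = f"{genome_id}_c1"
        clade = str(_choice(rng, spec.clade_mix))
        n = max(60, int(rng.poisson(spec.mean_genes_per_bacterium)))
        plan = _Plan(rng, n)

        lysogen_draw = rng.random() < p_decoy
        has_muf = rng.random() < spec.p_muf_bacteria
        site: dict | None = None
        category = ""
        muf_rank = -1
        if has_muf:
            category = str(_choice(rng, spec.association_mix))
            muf_rank = int(rng.integers(max(margin, 12), n - max(margin, 12)))
            site = _plan_muf_site(
                rng,
                spec,
                plan,
                muf_rank,
                clade,
                toxin_names,
                with_module=category != "UNASSOCIATED",
                with_terminases=category != "IN_REMNANT",
            )
            site["association"] = category

        # decoy prophages (no muf inside), placed in rank blocks disjoint
        # from the muf site so they can never change its context
        decoy_blocks: list[tuple[int, int]] = []
        if lysogen_draw:
            n_decoy = 1 + int(rng.poisson(0.5))
            for _ in range(n_decoy):
                for _attempt in range(20):
                    a = int(rng.integers(2, n - 44))
                    block = (a, a + 40)
                    if has_muf and not (
                        block[1] < muf_rank - 13 or block[0] > muf_rank + 13
                    ):
                        continue
                    if any(not (block[1] < b0 or block[0] > b1) for b0, b1 in decoy_blocks):
                        continue
                    decoy_blocks.append(block)
                    strand = "-" if rng.random() < 0.5 else "+"
                    for k, cls in enumerate(
                        (ProfileClass.TSS, ProfileClass.TLS, ProfileClass.PORTAL)
                    ):
                        _plant_marker(rng, plan, a + 3 + k, cls, strand)
                    break

        g, h, replicon_len = _materialize(
            rng, spec, plan, genome_id, replicon_id, toxin_names
        )
        genes[replicon_id] = g
        hits.extend(h)

        if site is not None and category == "IN_PROPHAGE":
            used = sorted(site["used_ranks"])
            cover_lo = g[used[0]].start
            cover_hi = g[used[-1]].end
            length = int(rng.integers(pro_lo, pro_hi + 1))
            if length <= cover_hi - cover_lo:
                length = cover_hi - cover_lo + 1000
            slack = length - (cover_hi - cover_lo)
            start = max(0, cover_lo - int(rng.integers(0, slack)))
            end = start + length
            if end > replicon_len:
                start = max(0, min(cover_lo, replicon_len - length))
                end = start + length
            regions.append(ProphageRegion(genome_id, replicon_id, start, end))
        elif site is not None and category == "IN_REMNANT":
            muf_gene = g[muf_rank]
            length = int(rng.integers(rem_lo, rem_hi + 1))
            span = muf_gene.end - muf_gene.start
            start = max(0, muf_gene.start - int(rng.integers(0, max(1, length - span))))
            regions.append(ProphageRegion(genome_id, replicon_id, start, start + length))

        for b0, _b1 in decoy_blocks:
            draw = int(rng.integers(pro_lo, pro_hi + 1))
            start = g[b0].start
            length = min(draw, g[b0 + 38].end - start)
            regions.append(ProphageRegion(genome_id, replicon_id, start, start + length))

        lysogen = any(
            r.length > 18_000 for r in regions if r.genome_id == genome_id
        )
        if site is not None:
            gene_truth_rows.append(
                {
                    "gene_id": g[muf_rank].gene_id,
                    "genome_id": genome_id,
                    "is_muf": True,
                    "family": site["family"],
                    "architecture": site["architecture"],
                    "planted_small_orf": site["planted_small_orf"],
                    "planted_immunity": site["planted_immunity"],
                    "association": category,
                    "near_packaging": site["near_packaging"],
                    "offset": site["offset"],
                }
            )
        meta_rows.append(
            {
                "genome_id": genome_id,
                "replicon_id": replicon_id,
                "kind": "bacterium",
                "clade": clade,
                "phage_family": "",
                "lifestyle": "",
            }
        )
        genome_truth_rows.append(
            {
                "genome_id": genome_id,
                "kind": "bacterium",
                "clade": clade,
                "phage_family": "",
                "lifestyle_true": "",
                "tailed": False,
                "has_muf": has_muf,
                "lysogen": lysogen,
            }
        )

    gene_truth = pd.DataFrame(
        gene_truth_rows,
        columns=[
            "gene_id", "genome_id", "is_muf", "family", "architecture",
            "planted_small_orf", "planted_immunity", "association",
            "near_packaging", "offset",
        ],
    )
    genome_truth = pd.DataFrame(
        genome_truth_rows,
        columns=[
            "genome_id", "kind", "clade", "phage_family", "lifestyle_true",
            "tailed", "has_muf", "lysogen",
        ],
    )
    genomes = pd.DataFrame(
        meta_rows,
        columns=["genome_id", "replicon_id", "kind", "clade", "phage_family", "lifestyle"],
    )
    return SyntheticDataset(
        spec=spec,
        genes=genes,
        hits=hits,
        regions=regions,
        genomes=genomes,
        gene_truth=gene_truth,
        genome_truth=genome_truth,
        toxin_catalog=toxin_catalog,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset in the pipeline's on-disk dialects.

    Files: ``genes.tsv`` (1-based inclusive coordinates), ``hits.domtblout``
    (HMMER3 per-domain layout), ``regions.bed`` (0-based half-open),
    ``genomes.tsv`` (metadata), ``toxin_catalog.tsv``, and the two
    ground-truth tables ``truth_genes.tsv`` / ``truth_genomes.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.tsv",
        "hits": outdir / "hits.domtblout",
        "regions": outdir / "regions.bed",
        "genomes": outdir / "genomes.tsv",
        "toxin_catalog": outdir / "toxin_catalog.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_genomes": outdir / "truth_genomes.tsv",
    }
    write_gene_table(dataset.genes, paths["genes"])
    write_domtblout(dataset.hits, paths["hits"], dataset.protein_lengths)
    write_regions(dataset.regions, paths["regions"])
    dataset.genomes.to_csv(paths["genomes"], sep="\t", index=False, lineterminator="\n")
    write_toxin_catalog(dataset.toxin_catalog, paths["toxin_catalog"])
    dataset.gene_truth.to_csv(
        paths["truth_genes"], sep="\t", index=False, lineterminator="\n"
    )
    dataset.genome_truth.to_csv(
        paths["truth_genomes"], sep="\t", index=False, lineterminator="\n"
    )
    return paths


# ---------------------------------------------------------------------------
# Fixture registry

_EVEN_ARCH = {"SHORT": 0.25, "CT_TOXIN": 0.25, "CT_UNKNOWN": 0.25, "CT_MAD": 0.25}

FIXTURE_SPECS: dict[str, SyntheticSpec] = {
    # small, every category represented (seed chosen for coverage)
    "minimal": SyntheticSpec(
        seed=20_170_829,
        n_phage_genomes=25,
        n_bacterial_genomes=25,
        p_muf_phage=0.9,
        p_muf_bacteria=0.9,
        architecture_mix=_EVEN_ARCH,
        association_mix={
            "IN_PROPHAGE": 0.40,
            "IN_REMNANT": 0.25,
            "NEAR_PACKAGING": 0.20,
            "UNASSOCIATED": 0.15,
        },
        mean_genes_per_bacterium=120,
    ),
    # no muf genes at all: the pipeline must produce all-zero summaries
    "empty": SyntheticSpec(
        seed=8,
        n_phage_genomes=8,
        n_bacterial_genomes=8,
        p_muf_phage=0.0,
        p_muf_bacteria=0.0,
        mean_genes_per_bacterium=80,
    ),
    # the default study conditions at modest size
    "default": SyntheticSpec(seed=1, n_phage_genomes=60, n_bacterial_genomes=60,
                             mean_genes_per_bacterium=150),
}


def make_fixture(name: str) -> SyntheticDataset:
    """Generate a registered fixture dataset (deterministic across runs)."""
    if name not in FIXTURE_SPECS:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURE_SPECS)}")
    ds = generate_dataset(FIXTURE_SPECS[name])
    if name == "minimal":
        archs = set(ds.gene_truth["architecture"])
        assocs = set(ds.gene_truth["association"]) - {""}
        if not (
            archs == set(_ARCHS)
            and {"IN_PROPHAGE", "IN_REMNANT", "NEAR_PACKAGING"} <= assocs
        ):
            raise RuntimeError("minimal fixture lost its category coverage")
    return ds
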
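"""End-to-end orchestration: screen -> architecture -> context -> immunity
-> statistics, plus ground-truth evaluation and the run manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .architecture import (
    ArchitectureCall,
    DEFAULT_TOXIN_CATALOG,
    classify_architecture,
    toxin_catalog_from_table,
)
from .context import (
    Association,
    ContextProfile,
    assign_association,
    classify_lysogen,
    marker_distances,
    marker_ranks_by_replicon,
    oriented_offset,
)
from .immunity import flag_candidates, length_distributions
from .io import (
    DomainHit,
    GeneRecord,
    MARKER_CLASSES,
    MUF_CLASSES,
    ProphageRegion,
    index_genes_by_id,
    read_domtblout,
    read_gene_table,
    read_regions,
    write_results,
)
from .screen import MufProtein, call_muf_proteins, group_hits_by_protein, select_best_profile
from .stats import (
    build_network,
    network_to_frame,
    paired_association_tests,
    summarize,
)
from .thresholds import DEFAULT_THRESHOLDS, Thresholds


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


PROTEIN_COLUMNS = [
    "protein_id", "genome_id", "gene_id", "replicon_id", "family",
    "best_evalue", "muf_env_from", "muf_env_to", "aa_length", "ct_length",
    "has_extension", "arch_class", "ctmad", "architecture", "ct_domains",
    "stray_domains",
]
CONTEXT_COLUMNS = [
    "gene_id", "genome_id", "replicon_id", "rank", "strand",
    "d_portal", "d_tls", "d_tss", "oriented_portal_offset", "association",
]
IMMUNITY_COLUMNS = [
    "muf_gene_id", "genome_id", "muf_label", "downstream_gene_id",
    "downstream_aa_length", "co_oriented", "gap_bp", "is_small",
]
LYSOGENY_COLUMNS = ["genome_id", "n_regions", "n_large_prophages", "lysogen"]


@dataclass
class PipelineResult:
    proteins: pd.DataFrame
    context: pd.DataFrame
    immunity: pd.DataFrame
    lysogeny: pd.DataFrame
    network: pd.DataFrame
    tests: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    muf_calls: list[MufProtein] = field(default_factory=list, repr=False)
    arch_calls: dict[str, ArchitectureCall] = field(default_factory=dict, repr=False)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "proteins": self.proteins,
            "context": self.context,
            "immunity": self.immunity,
            "lysogeny": self.lysogeny,
            "network": self.network,
            "tests": self.tests,
        }
        for name, df in self.summaries.items():
            out[f"summary_{name}"] = df
        return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def analyze(
    genes: Mapping[str, Sequence[GeneRecord]],
    hits: Sequence[DomainHit],
    regions: Sequence[ProphageRegion],
    genomes: pd.DataFrame,
    toxin_catalog: Mapping[str, str] | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    circular: bool = False,
) -> PipelineResult:
    """Run all analysis stages on in-memory inputs.

    ``genomes`` is the metadata table (genome_id, replicon_id, kind, clade,
    phage_family, lifestyle).  Stages run in order screen -> architecture ->
    context -> immunity -> statistics; any failure raises
    :class:`PipelineError` naming the stage.
    """
    catalog = dict(toxin_catalog) if toxin_catalog is not None else dict(DEFAULT_TOXIN_CATALOG)
    genes_by_id = index_genes_by_id(genes)
    kind_of_genome = genomes.set_index("genome_id")["kind"].to_dict()

    mufs = _stage("screen")(call_muf_proteins)(hits, genes)

    hits_by_protein = group_hits_by_protein(hits)

    @_stage("architecture")
    def _architecture() -> dict[str, ArchitectureCall]:
        calls = {}
        for muf in mufs:
            other = [
                h for h in hits_by_protein.get(muf.protein_id, ())
                if h.profile_class not in MUF_CLASSES
            ]
            calls[muf.protein_id] = classify_architecture(
                muf, other, catalog, thresholds.ct_extension_min
            )
        return calls

    arch = _architecture()

    @_stage("context")
    def _context() -> tuple[pd.DataFrame, pd.DataFrame]:
        # one marker class per protein: best E-value among marker hits
        marker_class = {}
        for pid, phits in hits_by_protein.items():
            best = select_best_profile(phits, MARKER_CLASSES)
            if best is not None and pid in genes_by_id:
                marker_class[pid] = best.profile_class
        marker_ranks = marker_ranks_by_replicon(genes, marker_class)
        regions_by_replicon: dict[str, list[ProphageRegion]] = {}
        for r in regions:
            regions_by_replicon.setdefault(r.replicon_id, []).append(r)

        ctx_rows = []
        for muf in mufs:
            gene = genes_by_id[muf.gene_id]
            replicon = genes[gene.replicon_id]
            dp, dtl, dts = marker_distances(
                gene.rank,
                marker_ranks.get(gene.replicon_id, {}),
                window=thresholds.context_window,
                n_genes=len(replicon),
                circular=circular,
            )
            ctx = ContextProfile(
                gene_id=gene.gene_id,
                d_portal=dp, d_tls=dtl, d_tss=dts,
                window=thresholds.context_window,
            )
            assoc = ""
            if kind_of_genome.get(gene.genome_id) == "bacterium":
                assoc = assign_association(
                    gene,
                    regions_by_replicon.get(gene.replicon_id, ()),
                    ctx,
                    thresholds.prophage_min,
                ).value
            ctx_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "genome_id": gene.genome_id,
                    "replicon_id": gene.replicon_id,
                    "rank": gene.rank,
                    "strand": gene.strand,
                    "d_portal": dp, "d_tls": dtl, "d_tss": dts,
                    "oriented_portal_offset": oriented_offset(dp, gene.strand),
                    "association": assoc,
                }
            )
        ctx_df = pd.DataFrame(ctx_rows, columns=CONTEXT_COLUMNS)
        ctx_df = ctx_df.sort_values(["genome_id", "gene_id"], ignore_index=True)

        lys_rows = []
        bacteria = genomes[genomes["kind"] == "bacterium"]
        regions_by_genome: dict[str, list[ProphageRegion]] = {}
        for r in regions:
            regions_by_genome.setdefault(r.genome_id, []).append(r)
        for genome_id in sorted(bacteria["genome_id"]):
            regs = regions_by_genome.get(genome_id, [])
            lys_rows.append(
                {
                    "genome_id": genome_id,
                    "n_regions": len(regs),
                    "n_large_prophages": sum(
                        1 for r in regs if r.length > thresholds.prophage_min
                    ),
                    "lysogen": classify_lysogen(regs, thresholds.prophage_min),
                }
            )
        lys_df = pd.DataFrame(lys_rows, columns=LYSOGENY_COLUMNS)
        return ctx_df, lys_df

    ctx_df, lys_df = _context()

    @_stage("immunity")
    def _immunity() -> pd.DataFrame:
        cands = flag_candidates(
            mufs, arch, genes, genes_by_id, thresholds.small_orf_max, circular
        )
        gene_to_genome = {m.gene_id: m.genome_id for m in mufs}
        rows = [
            {
                "muf_gene_id": c.muf_gene_id,
                "genome_id": gene_to_genome[c.muf_gene_id],
                "muf_label": c.muf_label,
                "downstream_gene_id": c.downstream_gene_id,
                "downstream_aa_length": c.downstream_aa_length,
                "co_oriented": c.co_oriented,
                "gap_bp": c.gap_bp,
                "is_small": c.is_small,
            }
            for c in cands
        ]
        df = pd.DataFrame(rows, columns=IMMUNITY_COLUMNS)
        return df.sort_values(["genome_id", "muf_gene_id"], ignore_index=True)

    imm_df = _immunity()

    @_stage("stats")
    def _stats() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
        prot_rows = []
        for muf in mufs:
            a = arch[muf.protein_id]
            gene = genes_by_id[muf.gene_id]
            prot_rows.append(
                {
                    "protein_id": muf.protein_id,
                    "genome_id": muf.genome_id,
                    "gene_id": muf.gene_id,
                    "replicon_id": gene.replicon_id,
                    "family": muf.family.value,
                    "best_evalue": muf.best_evalue,
                    "muf_env_from": muf.muf_env_from,
                    "muf_env_to": muf.muf_env_to,
                    "aa_length": muf.aa_length,
                    "ct_length": a.ct_length,
                    "has_extension": a.has_extension,
                    "arch_class": a.arch_class.value,
                    "ctmad": a.ctmad,
                    "architecture": a.label,
                    "ct_domains": ",".join(a.ct_domains),
                    "stray_domains": ",".join(a.stray_domains),
                }
            )
        prot_df = pd.DataFrame(prot_rows, columns=PROTEIN_COLUMNS)
        prot_df = prot_df.sort_values(["genome_id", "gene_id"], ignore_index=True)

        edges = build_network(
            [(m, arch[m.protein_id]) for m in mufs], thresholds.network_min_support
        )
        net_df = network_to_frame(edges)

        meta = genomes.copy()
        meta["lifestyle"] = meta["lifestyle"].replace("", np.nan)
        meta["phage_family"] = meta["phage_family"].replace("", np.nan)
        tests_df = paired_association_tests(prot_df, meta, imm_df)

        summaries = {
            "clade_phage": summarize(meta, prot_df, "clade", kinds=["phage"]),
            "clade_bacteria": summarize(meta, prot_df, "clade", kinds=["bacterium"]),
            "phage_family": summarize(meta, prot_df, "phage_family", kinds=["phage"]),
            "lifestyle": summarize(meta, prot_df, "lifestyle", kinds=["phage"]),
            "muf_family": summarize(meta, prot_df, "muf_family"),
        }
        return prot_df, net_df, tests_df, summaries

    prot_df, net_df, tests_df, summaries = _stats()

    return PipelineResult(
        proteins=prot_df,
        context=ctx_df,
        immunity=imm_df,
        lysogeny=lys_df,
        network=net_df,
        tests=tests_df,
        summaries=summaries,
        muf_calls=mufs,
        arch_calls=arch,
    )


# ---------------------------------------------------------------------------
# File-based runs


@dataclass
class RunConfig:
    genes: Path
    hits: Path
    genomes: Path
    outdir: Path
    regions: Path | None = None
    toxin_catalog: Path | None = None
    thresholds: Thresholds = DEFAULT_THRESHOLDS
    circular: bool = False
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        base = Path(path).parent
        paths = {
            k: (base / raw.pop(k)) if k in raw else None
            for k in ("genes", "hits", "genomes", "outdir", "regions", "toxin_catalog")
        }
        missing = [k for k in ("genes", "hits", "genomes", "outdir") if paths[k] is None]
        if missing:
            raise ValueError(f"config lacks required keys: {missing}")
        return cls(
            genes=paths["genes"], hits=paths["hits"], genomes=paths["genomes"],
            outdir=paths["outdir"], regions=paths["regions"],
            toxin_catalog=paths["toxin_catalog"], thresholds=thr,
            circular=bool(raw.pop("circular", False)), seed=raw.pop("seed", None),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full pipeline from files and write the result bundle.

    Writes one TSV per result table plus ``manifest.json`` (input paths and
    digests, thresholds, tool version, timestamp) under ``config.outdir``.
    On failure, partially written outputs are removed.
    """
    catalog = (
        toxin_catalog_from_table(config.toxin_catalog)
        if config.toxin_catalog
        else dict(DEFAULT_TOXIN_CATALOG)
    )

    @_stage("read")
    def _read():
        genes = read_gene_table(config.genes)
        hits = read_domtblout(config.hits, toxin_names=catalog)
        genomes = pd.read_csv(config.genomes, sep="\t", dtype=str, keep_default_na=False)
        genome_of_replicon = dict(zip(genomes["replicon_id"], genomes["genome_id"]))
        regions = (
            read_regions(config.regions, genome_of_replicon) if config.regions else []
        )
        return genes, hits, regions, genomes

    genes, hits, regions, genomes = _read()
    result = analyze(
        genes, hits, regions, genomes, catalog, config.thresholds, config.circular
    )

    outdir = Path(config.outdir)
    written: list[Path] = []
    try:
        written = write_results(result.tables(), outdir)
        manifest = {
            "tool": "muftox",
            "version": __version__,
            "inputs": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in (
                    ("genes", config.genes),
                    ("hits", config.hits),
                    ("genomes", config.genomes),
                    ("regions", config.regions),
                    ("toxin_catalog", config.toxin_catalog),
                )
                if p is not None
            },
            "thresholds": config.thresholds.to_dict(),
            "circular": config.circular,
            "seed": config.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage 'write' failed: {exc}") from exc
    return result


# ---------------------------------------------------------------------------
# Evaluation against ground truth


def _as_bool(v) -> bool:
    """Robust truth parsing for values round-tripped through TSV."""
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


def _prf(n_true: int, n_pred: int, tp: int) -> tuple[float, float]:
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / n_true if n_true else 1.0
    return precision, recall


def _multiclass_rows(
    category: str,
    true_by_id: Mapping[str, str],
    pred_by_id: Mapping[str, str],
) -> list[dict]:
    """Per-class one-vs-rest precision/recall over the shared id universe."""
    ids = sorted(set(true_by_id) & set(pred_by_id))
    labels = sorted(set(true_by_id.values()) | {pred_by_id[i] for i in ids})
    rows = []
    for lab in labels:
        true_ids = {i for i, v in true_by_id.items() if v == lab}
        pred_ids = {i for i in ids if pred_by_id[i] == lab}
        tp = len(true_ids & pred_ids)
        precision, recall = _prf(len(true_ids), len(pred_ids), tp)
        rows.append(
            {
                "category": category, "label": lab,
                "n_true": len(true_ids), "n_pred": len(pred_ids), "tp": tp,
                "precision": precision, "recall": recall,
            }
        )
    return rows


def evaluate_tables(
    proteins: pd.DataFrame,
    context: pd.DataFrame,
    immunity: pd.DataFrame,
    lysogeny: pd.DataFrame,
    gene_truth: pd.DataFrame,
    genome_truth: pd.DataFrame,
) -> pd.DataFrame:
    """Precision/recall of every pipeline call class against ground truth.

    Family, architecture, association and small-ORF comparisons are scored
    on genes found by both the pipeline and the truth table; the muf-call
    row itself scores detection, so false and missed calls show up there.
    """
    truth_muf = gene_truth[gene_truth["is_muf"].map(_as_bool)]
    true_ids = set(truth_muf["gene_id"])
    pred_ids = set(proteins["gene_id"])
    rows = []
    tp = len(true_ids & pred_ids)
    precision, recall = _prf(len(true_ids), len(pred_ids), tp)
    rows.append(
        {
            "category": "muf_call", "label": "MUF",
            "n_true": len(true_ids), "n_pred": len(pred_ids), "tp": tp,
            "precision": precision, "recall": recall,
        }
    )

    t_by_id = truth_muf.set_index("gene_id")
    p_by_id = proteins.set_index("gene_id")
    rows += _multiclass_rows(
        "family", t_by_id["family"].to_dict(), p_by_id["family"].to_dict()
    )
    rows += _multiclass_rows(
        "architecture", t_by_id["architecture"].to_dict(), p_by_id["architecture"].to_dict()
    )

    t_assoc = t_by_id.loc[t_by_id["association"] != "", "association"].to_dict()
    c_by_id = context.set_index("gene_id")
    p_assoc = c_by_id.loc[c_by_id["association"] != "", "association"].to_dict()
    rows += _multiclass_rows("association", t_assoc, p_assoc)

    bact = genome_truth[genome_truth["kind"] == "bacterium"]
    t_lys = {g: str(_as_bool(v)) for g, v in zip(bact["genome_id"], bact["lysogen"])}
    p_lys = {
        g: str(_as_bool(v))
        for g, v in zip(lysogeny["genome_id"], lysogeny["lysogen"])
    }
    rows += _multiclass_rows("lysogen", t_lys, p_lys)

    t_small = {
        g: str(_as_bool(v))
        for g, v in zip(truth_muf["gene_id"], truth_muf["planted_small_orf"])
    }
    p_small = {
        g: str(_as_bool(v))
        for g, v in zip(immunity["muf_gene_id"], immunity["is_small"])
    }
    rows += _multiclass_rows("small_orf", t_small, p_small)

    return pd.DataFrame(
        rows,
        columns=["category", "label", "n_true", "n_pred", "tp", "precision", "recall"],
    )


def evaluate(
    result: PipelineResult,
    gene_truth: pd.DataFrame,
    genome_truth: pd.DataFrame,
) -> pd.DataFrame:
    return evaluate_tables(
        result.proteins, result.context, result.immunity, result.lysogeny,
        gene_truth, genome_truth,
    )
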
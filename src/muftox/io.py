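"""Readers and writers for annotation tables, HMMER domain-hit tables, and
prophage region tables.

All genomic coordinates are stored internally as 0-based half-open intervals;
files on disk use the conventions of their format (GFF3 and the tabular gene
dialect are 1-based inclusive, BED-like region files are 0-based half-open).
Protein-envelope coordinates from HMMER stay 1-based inclusive, matching the
domtblout columns.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from Bio import SearchIO
from gffutils.feature import feature_from_line


class ParseError(ValueError):
    """Malformed input table (carries the offending line number when known)."""


class ProfileClass(str, Enum):
    """Functional class of an HMM profile used by the pipeline."""

    MUF1 = "MUF1"
    MUF2 = "MUF2"
    MUF3 = "MUF3"
    MUF4 = "MUF4"
    CT_MAD = "CT_MAD"
    PORTAL = "PORTAL"
    TLS = "TLS"   # terminase, large subunit
    TSS = "TSS"   # terminase, small subunit
    TOXIN = "TOXIN"
    OTHER = "OTHER"


MUF_CLASSES = frozenset(
    {ProfileClass.MUF1, ProfileClass.MUF2, ProfileClass.MUF3, ProfileClass.MUF4}
)
MARKER_CLASSES = frozenset({ProfileClass.PORTAL, ProfileClass.TLS, ProfileClass.TSS})

#: Default mapping from profile names to functional classes.  MuF1/MuF2 are
#: the Pfam Phage_Mu_F (PF04233) and Phage_min_cap2 (PF06152) domains; MuF3,
#: MuF4 and Ct_MAD are context-defined profiles; the marker names cover the
#: common portal/terminase profiles.  Callers may extend or override it.
DEFAULT_PROFILE_CLASSES: dict[str, ProfileClass] = {
    "MuF1": ProfileClass.MUF1,
    "Phage_Mu_F": ProfileClass.MUF1,
    "PF04233": ProfileClass.MUF1,
    "MuF2": ProfileClass.MUF2,
    "Phage_min_cap2": ProfileClass.MUF2,
    "PF06152": ProfileClass.MUF2,
    "MuF3": ProfileClass.MUF3,
    "MuF4": ProfileClass.MUF4,
    "Ct_MAD": ProfileClass.CT_MAD,
    "Phage_portal": ProfileClass.PORTAL,
    "Portal": ProfileClass.PORTAL,
    "Terminase_L": ProfileClass.TLS,
    "Terminase_GpA": ProfileClass.TLS,
    "Terminase_S": ProfileClass.TSS,
    "Terminase_small": ProfileClass.TSS,
}


def classify_profile(
    name: str,
    toxin_names: Iterable[str] | None = None,
    profile_classes: Mapping[str, ProfileClass] | None = None,
) -> ProfileClass:
    """Map a profile name to its :class:`ProfileClass`.

    Names found in ``toxin_names`` (a toxin-domain catalog) classify as
    ``TOXIN``; unknown names fall through to ``OTHER``.
    """
    table = DEFAULT_PROFILE_CLASSES if profile_classes is None else profile_classes
    if name in table:
        return table[name]
    if toxin_names is not None and name in set(toxin_names):
        return ProfileClass.TOXIN
    return ProfileClass.OTHER


@dataclass(frozen=True)
class GeneRecord:
    """One annotated CDS on a replicon.

    ``start``/``end`` are 0-based half-open base-pair coordinates; ``rank`` is
    the 0-based position of the gene in coordinate order on its replicon,
    regardless of strand.
    """

    gene_id: str
    genome_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    rank: int
    aa_length: int
    product_label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end ({self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.aa_length < 1:
            raise ValueError(f"{self.gene_id}: aa_length must be >= 1")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class DomainHit:
    """One profile-vs-protein match from a HMMER3 per-domain table.

    ``env_from``/``env_to`` are 1-based inclusive amino-acid coordinates of
    the domain envelope; ``full_evalue`` is the full-sequence E-value.
    """

    protein_id: str
    profile_name: str
    profile_class: ProfileClass
    full_evalue: float
    bitscore: float
    env_from: int
    env_to: int
    passed_ga: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.env_from <= self.env_to:
            raise ValueError(
                f"{self.protein_id}/{self.profile_name}: bad envelope "
                f"({self.env_from}, {self.env_to})"
            )
        if self.full_evalue < 0:
            raise ValueError(f"{self.protein_id}: negative E-value")


@dataclass(frozen=True)
class ProphageRegion:
    """A prophage (or remnant) interval on a bacterial replicon, 0-based half-open."""

    genome_id: str
    replicon_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"region on {self.replicon_id}: length must be > 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: float) -> bool:
        return self.start <= position < self.end


GENE_TABLE_COLUMNS = (
    "gene_id",
    "genome_id",
    "replicon_id",
    "start",
    "end",
    "strand",
    "aa_length",
    "product",
)


def _open_text(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    return open(source, "rt"), True


def _looks_like_gff3(source: str | Path | IO[str]) -> bool:
    if isinstance(source, (str, Path)):
        name = str(source)
        if name.endswith((".gff", ".gff3")):
            return True
        with open(source, "rt") as fh:
            head = fh.readline()
    else:
        pos = source.tell()
        head = source.readline()
        source.seek(pos)
    return head.startswith("##gff-version")


def read_gene_table(
    source: str | Path | IO[str],
    dialect: str = "auto",
) -> dict[str, list[GeneRecord]]:
    """Read a gene annotation table and return genes grouped by replicon.

    ``dialect`` is ``"tsv"`` (the package's 8-column table, 1-based inclusive
    coordinates), ``"gff3"`` (CDS features only), or ``"auto"``.  Within each
    replicon, records are sorted by start coordinate and ``rank`` is assigned
    from that order; file order is irrelevant.
    """
    if dialect == "auto":
        dialect = "gff3" if _looks_like_gff3(source) else "tsv"
    if dialect == "gff3":
        raw = _read_genes_gff3(source)
    elif dialect == "tsv":
        raw = _read_genes_tsv(source)
    else:
        raise ValueError(f"unknown gene-table dialect: {dialect!r}")

    grouped: dict[str, list[dict]] = {}
    for rec in raw:
        grouped.setdefault(rec["replicon_id"], []).append(rec)

    out: dict[str, list[GeneRecord]] = {}
    for replicon_id in sorted(grouped):
        rows = sorted(grouped[replicon_id], key=lambda r: (r["start"], r["end"], r["gene_id"]))
        seen: set[str] = set()
        records: list[GeneRecord] = []
        for rank, r in enumerate(rows):
            if r["gene_id"] in seen:
                raise ParseError(
                    f"duplicate gene_id {r['gene_id']!r} on replicon {replicon_id!r}"
                )
            seen.add(r["gene_id"])
            records.append(
                GeneRecord(
                    gene_id=r["gene_id"],
                    genome_id=r["genome_id"],
                    replicon_id=replicon_id,
                    start=r["start"] - 1,  # 1-based inclusive -> 0-based half-open
                    end=r["end"],
                    strand=r["strand"],
                    rank=rank,
                    aa_length=r["aa_length"],
                    product_label=r["product"],
                )
            )
        out[replicon_id] = records
    return out


def _read_genes_tsv(source: str | Path | IO[str]) -> list[dict]:
    fh, close = _open_text(source)
    rows: list[dict] = []
    try:
        header: Sequence[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header) != GENE_TABLE_COLUMNS:
                    raise ParseError(
                        f"line {lineno}: expected header {GENE_TABLE_COLUMNS}, got {tuple(header)}"
                    )
                continue
            if len(fields) != len(GENE_TABLE_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(GENE_TABLE_COLUMNS)} columns, got {len(fields)}"
                )
            d = dict(zip(GENE_TABLE_COLUMNS, fields))
            try:
                rows.append(
                    {
                        "gene_id": d["gene_id"],
                        "genome_id": d["genome_id"],
                        "replicon_id": d["replicon_id"],
                        "start": int(d["start"]),
                        "end": int(d["end"]),
                        "strand": d["strand"],
                        "aa_length": int(d["aa_length"]),
                        "product": d["product"],
                    }
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            fh.close()
    return rows


def _read_genes_gff3(source: str | Path | IO[str]) -> list[dict]:
    fh, close = _open_text(source)
    rows: list[dict] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if feat.featuretype != "CDS":
                continue
            attrs = feat.attributes
            gene_id = (attrs.get("ID") or attrs.get("locus_tag") or [None])[0]
            if gene_id is None:
                raise ParseError(f"line {lineno}: CDS without ID or locus_tag attribute")
            if "aa_length" in attrs:
                aa_length = int(attrs["aa_length"][0])
            elif "protein_length" in attrs:
                aa_length = int(attrs["protein_length"][0])
            else:
                # stop-codon-inclusive CDS span -> protein length
                aa_length = (feat.end - feat.start + 1) // 3 - 1
            rows.append(
                {
                    "gene_id": gene_id,
                    "genome_id": (attrs.get("genome_id") or [feat.seqid])[0],
                    "replicon_id": feat.seqid,
                    "start": feat.start,
                    "end": feat.end,
                    "strand": feat.strand if feat.strand in ("+", "-") else "+",
                    "aa_length": aa_length,
                    "product": (attrs.get("product") or [""])[0],
                }
            )
    finally:
        if close:
            fh.close()
    return rows


def write_gene_table(genes: Mapping[str, Sequence[GeneRecord]] | Iterable[GeneRecord],
                     target: str | Path | IO[str]) -> None:
    """Write genes as the package's tabular dialect (1-based inclusive coords)."""
    flat = flatten_genes(genes)
    fh, close = (open(target, "wt"), True) if not hasattr(target, "write") else (target, False)
    try:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in sorted(flat, key=lambda g: (g.replicon_id, g.rank)):
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.genome_id,
                        g.replicon_id,
                        str(g.start + 1),
                        str(g.end),
                        g.strand,
                        str(g.aa_length),
                        g.product_label,
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            fh.close()


def flatten_genes(
    genes: Mapping[str, Sequence[GeneRecord]] | Iterable[GeneRecord],
) -> list[GeneRecord]:
    if isinstance(genes, Mapping):
        return [g for recs in genes.values() for g in recs]
    return list(genes)


def index_genes_by_id(
    genes: Mapping[str, Sequence[GeneRecord]] | Iterable[GeneRecord],
) -> dict[str, GeneRecord]:
    out: dict[str, GeneRecord] = {}
    for g in flatten_genes(genes):
        out[g.gene_id] = g
    return out


# ---------------------------------------------------------------------------
# HMMER3 per-domain tables

_DOMTBL_MIN_COLUMNS = 23


def read_domtblout(
    source: str | Path | IO[str],
    toxin_names: Iterable[str] | None = None,
    profile_classes: Mapping[str, ProfileClass] | None = None,
    assume_ga: bool = True,
) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` table into :class:`DomainHit` records.

    One hit is produced per domain line, carrying the full-sequence E-value
    and bitscore of the target plus the envelope coordinates of the domain.
    ``assume_ga=True`` marks every hit as having passed the gathering
    threshold (the scan is expected to have been run with ``--cut_ga``);
    pass ``assume_ga=False`` for raw scans and apply a GA table downstream.
    """
    fh, close = _open_text(source)
    try:
        text = fh.read()
    finally:
        if close:
            fh.close()

    toxin_set = set(toxin_names) if toxin_names is not None else None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        ncol = len(line.split())
        if ncol < _DOMTBL_MIN_COLUMNS:
            raise ParseError(
                f"line {lineno}: domtblout rows need >= {_DOMTBL_MIN_COLUMNS} columns, got {ncol}"
            )

    hits: list[DomainHit] = []
    try:
        for qresult in SearchIO.parse(_io.StringIO(text), "hmmsearch3-domtab"):
            for hit in qresult:
                for hsp in hit:
                    env_from = hsp.env_start + 1  # SearchIO converts to 0-based
                    env_to = hsp.env_end
                    if env_from < 1 or env_to < env_from:
                        raise ParseError(
                            f"{hit.id}/{qresult.id}: bad envelope coordinates "
                            f"({env_from}, {env_to})"
                        )
                    hits.append(
                        DomainHit(
                            protein_id=hit.id,
                            profile_name=qresult.id,
                            profile_class=classify_profile(
                                qresult.id, toxin_set, profile_classes
                            ),
                            full_evalue=float(hit.evalue),
                            bitscore=float(hit.bitscore),
                            env_from=env_from,
                            env_to=env_to,
                            passed_ga=assume_ga,
                        )
                    )
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"malformed domtblout table: {exc}") from exc
    return hits


def write_domtblout(
    hits: Sequence[DomainHit],
    target: str | Path | IO[str],
    protein_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write hits in the HMMER3 per-domain tabular layout.

    ``protein_lengths`` supplies the ``tlen`` column; when missing, the
    envelope end is used as a lower bound.
    """
    ordered = sorted(hits, key=lambda h: (h.profile_name, h.protein_id, h.env_from))
    # number domains within each (profile, protein) pair
    counts: dict[tuple[str, str], int] = {}
    for h in ordered:
        key = (h.profile_name, h.protein_id)
        counts[key] = counts.get(key, 0) + 1

    fh, close = (open(target, "wt"), True) if not hasattr(target, "write") else (target, False)
    try:
        fh.write("# target name - tlen query name - qlen E-value score bias # of "
                 "c-Evalue i-Evalue score bias hmm_from hmm_to ali_from ali_to "
                 "env_from env_to acc description\n")
        index: dict[tuple[str, str], int] = {}
        for h in ordered:
            key = (h.profile_name, h.protein_id)
            index[key] = index.get(key, 0) + 1
            tlen = h.env_to
            if protein_lengths is not None and h.protein_id in protein_lengths:
                tlen = protein_lengths[h.protein_id]
            qlen = h.env_to - h.env_from + 1
            fields = [
                h.protein_id, "-", str(tlen),
                h.profile_name, "-", str(qlen),
                f"{h.full_evalue:.3g}", f"{h.bitscore:.1f}", "0.0",
                str(index[key]), str(counts[key]),
                f"{h.full_evalue:.3g}", f"{h.full_evalue:.3g}",
                f"{h.bitscore:.1f}", "0.0",
                "1", str(qlen),
                str(h.env_from), str(h.env_to),
                str(h.env_from), str(h.env_to),
                "0.90", "-",
            ]
            fh.write(" ".join(fields) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Prophage regions (BED-like, 0-based half-open)


def read_regions(
    source: str | Path | IO[str],
    genome_of_replicon: Mapping[str, str] | None = None,
) -> list[ProphageRegion]:
    """Read a BED-like region table: replicon, start, end[, genome_id]."""
    fh, close = _open_text(source)
    regions: list[ProphageRegion] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: need >= 3 columns")
            replicon_id = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if len(fields) >= 4 and fields[3]:
                genome_id = fields[3]
            elif genome_of_replicon and replicon_id in genome_of_replicon:
                genome_id = genome_of_replicon[replicon_id]
            else:
                genome_id = replicon_id
            regions.append(ProphageRegion(genome_id, replicon_id, start, end))
    finally:
        if close:
            fh.close()
    return regions


def write_regions(regions: Sequence[ProphageRegion], target: str | Path | IO[str]) -> None:
    fh, close = (open(target, "wt"), True) if not hasattr(target, "write") else (target, False)
    try:
        for r in sorted(regions, key=lambda r: (r.replicon_id, r.start, r.end)):
            fh.write(f"{r.replicon_id}\t{r.start}\t{r.end}\t{r.genome_id}\n")
    finally:
        if close:
            fh.close()


def write_results(tables: Mapping[str, "object"], outdir: str | Path) -> list[Path]:
    """Write a mapping of name -> DataFrame as TSV files under ``outdir``.

    Output is deterministic: the caller is expected to have sorted rows; the
    files are written with fixed column order and ``\\n`` line endings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        path = outdir / f"{name}.tsv"
        tables[name].to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
    return written
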
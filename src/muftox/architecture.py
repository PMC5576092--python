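"""Classify MuF proteins by the content of their C-terminal region.

Polymorphic-toxin families share one domain organisation: a conserved
N-terminal family domain and a variable C-terminal extension that may carry
a toxin domain.  A MuF protein is *short* when fewer than 100 aa remain
after the MuF domain envelope; otherwise it carries a C-terminal extension
(Ct_ext) that is classified by what lies inside it: a catalogued toxin
domain (CT_TOXIN) or nothing known (CT_UNKNOWN), the latter optionally
marked by the Ct_MAD domain of Proteobacterial phage MuF proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .io import DomainHit, MUF_CLASSES, ParseError, ProfileClass
from .screen import MufProtein
from .thresholds import DEFAULT_THRESHOLDS


class ArchClass(str, Enum):
    SHORT = "SHORT"
    CT_TOXIN = "CT_TOXIN"
    CT_UNKNOWN = "CT_UNKNOWN"


#: Toxin-domain catalog used by default: domain name -> predicted activity.
#: Mirrors the recurrent families of the polymorphic-toxin shared pool
#: (nucleases, peptidases, ADP-ribosyl transferases, RelA-like domains ...).
DEFAULT_TOXIN_CATALOG: dict[str, str] = {
    "Ntox50": "nuclease",
    "EndoU_bacteria": "ribonuclease",
    "cd13442": "tRNA nuclease",
    "Tox-REase-5": "DNase",
    "Tox-HNH-EHHH": "DNase",
    "ADPRT": "ADP-ribosyl transferase",
    "RelA_SpoT": "RelA-like (p)ppGpp hydrolase",
    "Peptidase_M78": "metallopeptidase",
    "Tox-MPTase4": "metallopeptidase",
    "Colicin-DNase": "DNase",
}


@dataclass(frozen=True)
class ArchitectureCall:
    """Architecture assignment of one MuF protein.

    ``ct_domains`` lists the toxin and Ct_MAD domain names whose envelope
    midpoint lies inside the extension; ``stray_domains`` lists catalogued
    domains found N-terminal of the MuF domain (reported, never
    class-determining).
    """

    protein_id: str
    ct_length: int
    has_extension: bool
    arch_class: ArchClass
    ct_domains: tuple[str, ...] = ()
    ct_toxin_domains: tuple[str, ...] = ()
    ctmad: bool = False
    stray_domains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.arch_class is ArchClass.SHORT) == self.has_extension:
            raise ValueError("SHORT iff no extension")
        if self.arch_class is ArchClass.CT_TOXIN and not self.ct_toxin_domains:
            raise ValueError("CT_TOXIN requires a toxin domain in the extension")
        if self.ctmad and self.arch_class is ArchClass.SHORT:
            raise ValueError("Ct_MAD implies an extension")

    @property
    def label(self) -> str:
        """Four-way reporting label: SHORT / CT_TOXIN / CT_MAD / CT_UNKNOWN."""
        if self.arch_class is ArchClass.CT_UNKNOWN and self.ctmad:
            return "CT_MAD"
        return self.arch_class.value


def ct_extension_length(aa_length: int, muf_env_to: int,
                        min_extension: int = DEFAULT_THRESHOLDS.ct_extension_min,
                        ) -> tuple[int, bool]:
    """Length of the region after the MuF envelope, and whether it counts
    as a C-terminal extension (inclusive cutoff: exactly ``min_extension``
    residues is an extension)."""
    if muf_env_to > aa_length:
        raise ValueError(f"envelope end {muf_env_to} exceeds protein length {aa_length}")
    ext = aa_length - muf_env_to
    return ext, ext >= min_extension


def classify_architecture(
    muf: MufProtein,
    hits: Sequence[DomainHit],
    toxin_catalog: Mapping[str, str] | Iterable[str] | None = None,
    min_extension: int = DEFAULT_THRESHOLDS.ct_extension_min,
) -> ArchitectureCall:
    """Classify one MuF protein from its non-MuF domain hits.

    A domain lies "in the extension" when its envelope midpoint falls after
    the MuF envelope end; this is robust to small envelope overlaps.  Unknown
    domains are tolerated and simply do not contribute to the call.
    """
    catalog = set(toxin_catalog) if toxin_catalog is not None else set(DEFAULT_TOXIN_CATALOG)
    ext, has_ext = ct_extension_length(muf.aa_length, muf.muf_env_to, min_extension)

    ct_names: list[str] = []
    ct_toxins: list[str] = []
    ctmad = False
    strays: list[str] = []
    for h in hits:
        if not h.passed_ga or h.profile_class in MUF_CLASSES:
            continue
        is_toxin = h.profile_name in catalog
        is_ctmad = h.profile_class is ProfileClass.CT_MAD
        if not (is_toxin or is_ctmad):
            continue
        midpoint = (h.env_from + h.env_to) / 2.0
        if has_ext and midpoint > muf.muf_env_to:
            ct_names.append(h.profile_name)
            if is_toxin:
                ct_toxins.append(h.profile_name)
            if is_ctmad:
                ctmad = True
        else:
            strays.append(h.profile_name)

    if not has_ext:
        arch = ArchClass.SHORT
        ctmad = False
        ct_names, ct_toxins = [], []
    elif ct_toxins:
        arch = ArchClass.CT_TOXIN
    else:
        arch = ArchClass.CT_UNKNOWN

    return ArchitectureCall(
        protein_id=muf.protein_id,
        ct_length=ext,
        has_extension=has_ext,
        arch_class=arch,
        ct_domains=tuple(sorted(set(ct_names))),
        ct_toxin_domains=tuple(sorted(set(ct_toxins))),
        ctmad=ctmad,
        stray_domains=tuple(sorted(set(strays))),
    )


def toxin_catalog_from_table(source: str | Path | IO[str]) -> dict[str, str]:
    """Read a two-column TSV (domain name, activity class) into a catalog.

    Duplicate rows with the same activity are deduplicated; conflicting
    duplicates are an error.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    catalog: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ParseError(f"line {lineno}: need name and activity columns")
        name, activity = fields[0], fields[1]
        if name in ("name", "domain"):  # header row
            continue
        if name in catalog and catalog[name] != activity:
            raise ParseError(
                f"line {lineno}: conflicting activities for {name!r}: "
                f"{catalog[name]!r} vs {activity!r}"
            )
        catalog[name] = activity
    return catalog


def write_toxin_catalog(catalog: Mapping[str, str], target: str | Path) -> None:
    with open(target, "wt") as fh:
        fh.write("name\tactivity\n")
        for name in sorted(catalog):
            fh.write(f"{name}\t{catalog[name]}\n")
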
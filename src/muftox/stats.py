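"""Association statistics, summary tables, and the family-toxin network.

The comparisons mirror a classical comparative-genomics workflow: two-tailed
Fisher's exact tests on 2x2 contingency tables (with the two-sided rule of
R's ``fisher.test``: sum the hypergeometric probabilities of every table, at
fixed margins, no more probable than the observed one), a two-sample
unpaired t test on downstream-ORF lengths, per-group summary rows, and a
bipartite network linking MuF families to the toxin domains found in their
C-terminal extensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .architecture import ArchitectureCall
from .screen import MufProtein
from .thresholds import DEFAULT_THRESHOLDS

#: Relative tolerance of the "no more probable than observed" rule, matching
#: the dialect of R's fisher.test.
_TWO_SIDED_REL_EPS = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] of a 2x2 contingency table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


def fisher_exact_two_tailed(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact p-value of a 2x2 table.

    Enumerates the full hypergeometric support at fixed margins and sums the
    probabilities of all tables whose probability does not exceed that of
    the observed table (within a 1e-7 relative tolerance).  A zero margin
    makes the test undefined; by convention p = 1 with a warning.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    a, b, c, d = table.counts
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        warnings.warn("zero margin in 2x2 table; Fisher p set to 1", stacklevel=2)
        return 1.0
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    x = np.arange(lo, hi + 1)
    # log hypergeometric pmf at fixed margins
    logp = (
        gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
        + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - (c1 - x) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    p = np.exp(logp)
    p_obs = p[a - lo]
    total = float(p[p <= p_obs * (1.0 + _TWO_SIDED_REL_EPS)].sum())
    return min(1.0, total)


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    welch: bool = True,
) -> tuple[float, float, float]:
    """Two-sample unpaired t test; returns (t, df, two-sided p).

    ``welch=True`` uses the Satterthwaite degrees of freedom (the default of
    R's ``t.test``); ``welch=False`` pools the variances (classical Student).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class NetworkEdge:
    """A weighted MuF-family <-> toxin-domain association."""

    muf_family: str
    toxin_domain: str
    weight: int


def build_network(
    calls: Iterable[tuple[MufProtein, ArchitectureCall]],
    min_support: int = DEFAULT_THRESHOLDS.network_min_support,
) -> list[NetworkEdge]:
    """Bipartite edges (family, toxin domain) weighted by protein count.

    A protein carrying several catalogued toxin domains contributes to one
    edge per domain.  A toxin domain enters the network only when the total
    number of MuF proteins carrying it (across families) reaches
    ``min_support``.
    """
    pair_counts: dict[tuple[str, str], int] = {}
    domain_totals: dict[str, int] = {}
    for muf, arch in calls:
        for domain in arch.ct_toxin_domains:
            key = (muf.family.value, domain)
            pair_counts[key] = pair_counts.get(key, 0) + 1
            domain_totals[domain] = domain_totals.get(domain, 0) + 1
    edges = [
        NetworkEdge(family, domain, count)
        for (family, domain), count in pair_counts.items()
        if domain_totals[domain] >= min_support
    ]
    edges.sort(key=lambda e: (e.muf_family, e.toxin_domain))
    return edges


def network_to_frame(edges: Sequence[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.muf_family, e.toxin_domain, e.weight) for e in edges],
        columns=["muf_family", "toxin_domain", "weight"],
    )


def network_to_graph(edges: Sequence[NetworkEdge]):
    """Export the edge list as a networkx bipartite graph."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_node(e.muf_family, kind="muf_family")
        g.add_node(e.toxin_domain, kind="toxin_domain")
        g.add_edge(e.muf_family, e.toxin_domain, weight=e.weight)
    return g


SUMMARY_COLUMNS = [
    "group",
    "n_genomes",
    "n_genomes_muf",
    "prop_genomes_muf",
    "n_muf",
    "n_short",
    "n_toxin",
    "n_unknown",
    "prop_short",
    "prop_toxin",
    "prop_unknown",
]


def summarize(
    genomes: pd.DataFrame,
    proteins: pd.DataFrame,
    by: str,
    kinds: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group summary rows: MuF+ genome proportions and architecture counts.

    ``genomes`` needs columns genome_id plus the grouping key (clade,
    phage_family, lifestyle); ``proteins`` needs genome_id, family and
    arch_class.  ``by="muf_family"`` groups proteins by family instead of
    genomes by metadata.  ``kinds`` restricts the genome universe (e.g. only
    phages).  In every row n_short + n_toxin + n_unknown = n_muf.
    """
    gmeta = genomes
    if kinds is not None:
        gmeta = gmeta[gmeta["kind"].isin(kinds)]
    prot = proteins[proteins["genome_id"].isin(set(gmeta["genome_id"]))]

    if by == "muf_family":
        keys = sorted(prot["family"].unique())
        key_of_protein = prot["family"]
    else:
        if by not in gmeta.columns:
            raise KeyError(f"unknown grouping key {by!r}")
        key_by_genome = gmeta.set_index("genome_id")[by]
        keys = sorted(k for k in key_by_genome.unique() if pd.notna(k))
        key_of_protein = prot["genome_id"].map(key_by_genome)

    rows = []
    muf_genomes = set(prot["genome_id"])
    for key in keys:
        if by == "muf_family":
            sub = prot[key_of_protein == key]
            group_genomes = set(sub["genome_id"])
            n_genomes = len(group_genomes)
            n_genomes_muf = n_genomes
        else:
            group_ids = set(gmeta.loc[gmeta[by] == key, "genome_id"])
            sub = prot[key_of_protein == key]
            n_genomes = len(group_ids)
            n_genomes_muf = len(group_ids & muf_genomes)
        n_muf = len(sub)
        n_short = int((sub["arch_class"] == "SHORT").sum())
        n_toxin = int((sub["arch_class"] == "CT_TOXIN").sum())
        n_unknown = int((sub["arch_class"] == "CT_UNKNOWN").sum())
        rows.append(
            {
                "group": key,
                "n_genomes": n_genomes,
                "n_genomes_muf": n_genomes_muf,
                "prop_genomes_muf": n_genomes_muf / n_genomes if n_genomes else 0.0,
                "n_muf": n_muf,
                "n_short": n_short,
                "n_toxin": n_toxin,
                "n_unknown": n_unknown,
                "prop_short": n_short / n_muf if n_muf else 0.0,
                "prop_toxin": n_toxin / n_muf if n_muf else 0.0,
                "prop_unknown": n_unknown / n_muf if n_muf else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


TAILED_FAMILIES = ("Siphoviridae", "Myoviridae", "Podoviridae")

TEST_REPORT_COLUMNS = [
    "test", "method", "a", "b", "c", "d", "n_x", "n_y", "statistic", "df", "p",
]


def _fisher_row(name: str, a: int, b: int, c: int, d: int) -> dict:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
    return {
        "test": name, "method": "fisher_exact_two_tailed",
        "a": a, "b": b, "c": c, "d": d,
        "n_x": np.nan, "n_y": np.nan, "statistic": np.nan, "df": np.nan, "p": p,
    }


def paired_association_tests(
    proteins: pd.DataFrame,
    genomes: pd.DataFrame,
    candidates: pd.DataFrame | None = None,
    welch: bool = True,
) -> pd.DataFrame:
    """The pipeline's standard comparisons, as one deterministic report.

    Rows (2x2 Fisher unless noted):

    * ``toxin_vs_short_by_firmicutes`` - architecture (CT_TOXIN vs SHORT)
      against Firmicutes vs any other clade, over MuF proteins;
    * ``unknown_vs_short_by_proteobacteria`` - CT_UNKNOWN vs SHORT against
      Proteobacteria vs other;
    * ``muf_by_siphoviridae`` - MuF+ genomes against Siphoviridae vs the
      other tailed-phage families;
    * ``muf_by_lifestyle`` - MuF+ genomes against temperate vs virulent
      (lifestyle-labelled phages only);
    * ``small_orf_toxin_vs_short`` - downstream ORF < 150 aa against
      architecture (needs ``candidates``);
    * ``downstream_length_toxin_vs_short`` - t test on downstream product
      lengths (needs ``candidates``).

    No multiple-testing correction is applied (raw p-values are reported);
    see :func:`adjust_report` for an optional Benjamini-Hochberg column.
    """
    for col in ("genome_id", "clade", "kind"):
        if col not in genomes.columns:
            raise KeyError(f"genome metadata lacks required column {col!r}")
    meta = genomes.set_index("genome_id")
    prot = proteins.copy()
    prot["clade"] = prot["genome_id"].map(meta["clade"])

    rows = []

    def arch_vs_clade(name: str, arch: str, clade: str) -> dict:
        sub = prot[prot["arch_class"].isin([arch, "SHORT"])]
        is_arch = sub["arch_class"] == arch
        is_clade = sub["clade"] == clade
        return _fisher_row(
            name,
            int((is_arch & is_clade).sum()),
            int((is_arch & ~is_clade).sum()),
            int((~is_arch & is_clade).sum()),
            int((~is_arch & ~is_clade).sum()),
        )

    rows.append(arch_vs_clade("toxin_vs_short_by_firmicutes", "CT_TOXIN", "Firmicutes"))
    rows.append(
        arch_vs_clade("unknown_vs_short_by_proteobacteria", "CT_UNKNOWN", "Proteobacteria")
    )

    muf_genomes = set(prot["genome_id"])
    phages = genomes[genomes["kind"] == "phage"]
    tailed = phages[phages["phage_family"].isin(TAILED_FAMILIES)]
    is_muf = tailed["genome_id"].isin(muf_genomes)
    is_sipho = tailed["phage_family"] == "Siphoviridae"
    rows.append(
        _fisher_row(
            "muf_by_siphoviridae",
            int((is_muf & is_sipho).sum()),
            int((is_muf & ~is_sipho).sum()),
            int((~is_muf & is_sipho).sum()),
            int((~is_muf & ~is_sipho).sum()),
        )
    )

    labelled = phages[phages["lifestyle"].isin(["temperate", "virulent"])]
    is_muf = labelled["genome_id"].isin(muf_genomes)
    is_temp = labelled["lifestyle"] == "temperate"
    rows.append(
        _fisher_row(
            "muf_by_lifestyle",
            int((is_muf & is_temp).sum()),
            int((is_muf & ~is_temp).sum()),
            int((~is_muf & is_temp).sum()),
            int((~is_muf & ~is_temp).sum()),
        )
    )

    if candidates is not None and len(candidates):
        cand = candidates.copy()
        cand["muf_label"] = cand["muf_label"].replace({"CT_MAD": "CT_UNKNOWN"})
        sub = cand[cand["muf_label"].isin(["CT_TOXIN", "SHORT"])]
        is_tox = sub["muf_label"] == "CT_TOXIN"
        is_small = sub["is_small"].astype(bool)
        rows.append(
            _fisher_row(
                "small_orf_toxin_vs_short",
                int((is_tox & is_small).sum()),
                int((is_tox & ~is_small).sum()),
                int((~is_tox & is_small).sum()),
                int((~is_tox & ~is_small).sum()),
            )
        )
        with_ds = sub.dropna(subset=["downstream_aa_length"])
        x = with_ds.loc[is_tox, "downstream_aa_length"].to_numpy(float)
        y = with_ds.loc[~is_tox, "downstream_aa_length"].to_numpy(float)
        if len(x) >= 2 and len(y) >= 2 and (np.var(x) > 0 or np.var(y) > 0):
            t, df, p = two_sample_t(x, y, welch=welch)
            rows.append(
                {
                    "test": "downstream_length_toxin_vs_short",
                    "method": "welch_t" if welch else "student_t",
                    "a": np.nan, "b": np.nan, "c": np.nan, "d": np.nan,
                    "n_x": len(x), "n_y": len(y),
                    "statistic": t, "df": df, "p": p,
                }
            )

    return pd.DataFrame(rows, columns=TEST_REPORT_COLUMNS)


def adjust_report(report: pd.DataFrame) -> pd.DataFrame:
    """Append a Benjamini-Hochberg adjusted column (off the default path)."""
    out = report.copy()
    out["p_bh"] = sps.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out
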
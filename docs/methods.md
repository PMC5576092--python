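# Methods

## The analysis in one paragraph

MuF proteins are defined by an N-terminal domain of the MuF superfamily
(MuF1/PF04233, MuF2/PF06152, and the context-defined MuF3 and MuF4) and live
in the DNA-packaging module of tailed phages, typically immediately
downstream of the portal gene.  The pipeline takes per-genome gene tables,
HMMER3 per-domain hit tables for the MuF profiles, the packaging markers
(portal P, terminase large/small subunits TLS/TSS) and a toxin-domain
catalog, plus externally detected prophage regions.  It calls MuF proteins,
classifies their C-terminal architecture, profiles the genomic context of
the encoding *muf* genes, screens for candidate immunity ORFs, and computes
association statistics and the family–toxin network.

## Decision rules and thresholds

All cutoffs live in `muftox.thresholds.Thresholds`; every stage reads them
from there, so a sensitivity analysis changes one object (or one CLI flag).

| parameter | default | unit | role |
|---|---|---|---|
| `ct_extension_min` | 100 | aa | a C-terminal extension exists when ≥ 100 aa remain after the MuF envelope end.  The cutoff is inclusive and deliberately sits below the shortest toxin-carrying extension observed in practice (113 aa), so no toxin extension is missed. |
| `small_orf_max` | 150 | aa | candidate immunity ORFs encode **strictly fewer** than 150 aa; a 150-aa product is not small. |
| `prophage_min` | 18,000 | bp | elements **strictly longer** than 18 kb are prophages; an element of exactly 18,000 bp falls on the remnant side, consistent with the lysogen definition (≥ 1 element > 18 kb). |
| `context_window` | 10 | genes | markers are searched 10 genes on either side of a *muf* gene; rank 10 is in-window, rank 11 is not. |
| `network_min_support` | 5 | proteins | a toxin domain enters the association network only when carried by at least five MuF proteins **in total** (summed over families); edge weights then count per-(family, domain) proteins. |

## Conventions that needed a decision

* **Coordinates.**  Internal gene coordinates are 0-based half-open;
  GFF3/tabular input and output are 1-based inclusive, converted exactly
  once at the I/O boundary.  Protein-envelope coordinates stay 1-based
  inclusive as in `domtblout`.  When a gene table carries no protein length,
  it is derived as span/3 − 1 (stop codon excluded).
* **Best profile per protein.**  "Best E-value" means the full-sequence
  E-value (not the per-domain i-Evalue): profiles are ranked per protein,
  and the full-sequence E-value is the natural per-protein score.  Ties
  break by higher bitscore, then lexicographic profile name — fully
  deterministic.  The same rule assigns one marker class (P/TLS/TSS) per
  marker protein.
* **GA thresholds.**  Hits present in a table are assumed to have passed
  the profile gathering threshold (scans are expected to be run with
  `--cut_ga`).  For raw scans, `read_domtblout(..., assume_ga=False)` plus
  `apply_ga_table` re-flags hits against per-profile GA bitscores; profiles
  missing from the table fail closed.
* **Extension measurement.**  Extensions are measured from the MuF
  **envelope** end to the protein C-terminus.  Envelope coordinates are the
  defensible domain boundary available in `domtblout`; alignment
  coordinates would shift the boundary by a few residues, which the 100-aa
  cutoff absorbs (flagged for sensitivity analysis via
  `--ct-extension-min`).
* **Domain "in the extension".**  A toxin/Ct_MAD domain counts as inside
  the extension when its envelope **midpoint** lies after the MuF envelope
  end — robust to small envelope overlaps.  Catalogued domains found
  N-terminal of the MuF domain are reported (`stray_domains`) but never
  class-determining: the architecture classes are defined on the C-terminal
  region.
* **Multi-domain MuF proteins.**  A protein with two MuF envelopes is one
  protein with one family (from the best hit); a protein carrying both MuF
  and toxin/Ct_MAD hits is a single MuF protein whose non-MuF hits feed the
  architecture call.
* **Gene-rank distances.**  Distances are positional gene ranks
  (strand-agnostic, per replicon, no wrap-around unless `--circular`),
  signed as `d = marker_rank − muf_rank`; a tie between −k and +k resolves
  to +k.  Because the biological statement "the *muf* gene is at +1 of the
  portal gene" is transcription-oriented, the context table also reports
  `oriented_portal_offset` = −d on the + strand and +d on the − strand, so
  +1 always means "immediately downstream of the portal in transcription
  order" regardless of strand.
* **Region membership.**  A gene is inside a region when its midpoint is —
  this prevents double-assignment of boundary-spanning genes.  When
  overlapping regions of both size classes contain a gene, the largest
  wins (with a warning).
* **"Near packaging" in the remnant rule** reuses the only stated window
  (±10 genes); no separate radius is introduced.
* **Downstream ORF.**  "Immediately downstream" is the next annotated gene
  in the *muf* gene's transcription direction, regardless of the
  neighbour's own strand; co-orientation and the intergenic gap are
  recorded so users can filter, but neither is required (no max-gap rule).
* **Fisher's exact test** is implemented in-package by full enumeration of
  the hypergeometric support (log-space, `scipy.special.gammaln`), summing
  all tables whose probability does not exceed the observed one within a
  1e-7 relative tolerance — the two-sided dialect of R's `fisher.test`.
  Zero-margin tables return p = 1 with a warning.  The implementation is
  cross-checked in the tests against an independent pure-Python enumeration
  (exhaustively for all tables with N ≤ 30) and against
  `scipy.stats.fisher_exact`.
* **t test.**  `two_sample_t` defaults to Welch (Satterthwaite df), which
  is the default of R's `t.test`; the classical pooled-variance Student
  statistic is available with `welch=False`, and the report labels which
  was used.
* **Multiple testing.**  Raw p-values are reported; a Benjamini–Hochberg
  column is available (`adjust_report`) but off by default.

## The synthetic-data generator

`SyntheticSpec` defaults encode the study conditions the pipeline targets:
35% of tailed phages carry one *muf* gene (one per genome by default;
`p_extra_muf` exercises the rare multi-*muf* case), 25% of bacteria carry
one, 50% of bacteria are lysogens (the marginal rate; the decoy-prophage
rate is derived analytically so that *muf*-bearing prophages do not inflate
it), the architecture mix is 62.8% short / 12.6% toxin / 16.4% unknown /
8.2% Ct_MAD (Ct_MAD ≈ one third of the unknown extensions), small ORFs
follow toxin-class *muf* genes with probability 0.894 and short-class ones
with 0.255, 96% of bacterial *muf* genes are prophage-associated
(90% prophage / 3% remnant / 3% free-standing packaging cluster), and 70%
of *muf* genes sit at +1 of the portal gene (offsets +2…+4 carry the rest).

Gene lengths are log-normal (median 280 aa, σ = 0.45, clipped to
60–1800 aa); planted immunity ORFs are uniform on 50–149 aa and decoy
downstream genes on 150–400 aa, which makes the < 150 aa rule
discriminative by construction.  Planted hits have E-values in 10⁻⁶⁰…10⁻²⁵
(MuF), with a secondary MuF-family hit 3–8 orders of magnitude weaker on
30% of proteins so best-hit selection is exercised on real data paths;
spurious hits (rate `p_false_hit`, default 0) draw E-values in 10⁻⁴…1,
strictly above the planted range.  Packaging modules place TSS–TLS–portal
consecutively on one strand (25% of modules on the − strand), and decoy
prophages are planted in gene blocks disjoint from the *muf* site so they
can never change its context.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: nucleotide sequences and real HMM scores;
annotation noise (missed or mis-called CDS, wrong strands); operon
structure beyond the packaging module; phylogenetic correlation between
genomes (clades are i.i.d. labels); prophage-detector boundary errors; and
composition-dependent domain detection failure.  Recovery results on
synthetic data certify the bookkeeping and decision rules, not HMMER or
Phage Finder.

## Problem sizes and runtime

The test suite exercises exact noiseless recovery at 200 + 200 genomes,
parameter recovery at 1,000 + 1,000 genomes (all planted proportions within
3σ binomial bounds), and type-I behaviour of the four association tests
over 100 seeded replicates of 500 phage genomes; bacterial chromosomes are
scaled to ~250 genes as a deliberate choice — context decisions happen
within ±10 genes, so chromosome length beyond the window adds nothing.
`scripts/acceptance.py` runs the 1,000 + 1,000 configuration in a few
seconds on one CPU.

## Known limitations

* The screen consumes hit tables made with prebuilt profiles; profile
  construction (PSI-BLAST seeding, alignment, `hmmbuild`) and HMM–HMM
  comparison are out of scope, as are prophage detection and lifestyle
  prediction themselves (regions and labels are inputs).
* The immunity screen is purely positional; it does not verify homology to
  known immunity proteins.
* Evaluation of family/architecture/association classes is conditioned on
  detection (a missed protein shows up in the detection row, not in the
  downstream class rows).
* With `p_false_hit > 0`, a spurious marker hit near an isolated *muf* gene
  can legitimately flip it to NEAR_PACKAGING; exact-recovery guarantees
  hold only at `p_false_hit = 0`.
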
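"""All numeric decision thresholds of the pipeline, in one place.

Every stage reads its cutoffs from a :class:`Thresholds` instance so that a
sensitivity analysis can vary them in a single spot.  The defaults encode the
published decision rules: a C-terminal extension exists when >= 100 aa remain
after the MuF domain envelope; a candidate immunity ORF encodes < 150 aa; a
detected element is a prophage when strictly longer than 18 kb (and a remnant
otherwise); genomic context is scanned 10 genes either side of a muf gene;
and a toxin domain enters the association network only when carried by at
least five MuF proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class Thresholds:
    ct_extension_min: int = 100      # aa, inclusive (>= counts as extension)
    small_orf_max: int = 150         # aa, strict < counts as small
    prophage_min: int = 18_000       # bp, strict > counts as prophage
    context_window: int = 10         # genes either side of a muf gene
    network_min_support: int = 5     # MuF proteins per toxin domain

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")

    def to_dict(self) -> dict[str, int]:
        return asdict(self)


DEFAULT_THRESHOLDS = Thresholds()
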
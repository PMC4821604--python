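"""Core genomic data model.

All coordinates are 0-based, half-open, in base pairs. Positions reported
relative to a TSS use the convention "TSS = 0, downstream positive on the
gene's strand", so "+132" means 132 bp 3' of the TSS regardless of strand.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-", ".")

#: Allowed core-promoter element labels. DRE and the Ohler boxes mark
#: DREF/TRF2-type (housekeeping) promoters; TATA/INR/MTE/DPE/TCT mark
#: developmentally regulated and paused promoters.
PROMOTER_ELEMENTS = frozenset(
    {"DRE", "Ohler1", "Ohler5", "Ohler6", "Ohler7", "Ohler8",
     "TATA", "INR", "MTE", "DPE", "TCT"}
)


class ChromSizes(Mapping):
    """Chromosome name -> length (bp) map with validation."""

    def __init__(self, sizes: Mapping[str, int]):
        sizes = dict(sizes)
        for name, length in sizes.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._sizes = {str(k): int(v) for k, v in sizes.items()}

    def __getitem__(self, key):
        return self._sizes[key]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self):
        return len(self._sizes)

    def __repr__(self):
        return f"ChromSizes({self._sizes!r})"

    @property
    def genome_size(self) -> int:
        return sum(self._sizes.values())


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def within(self, chrom_sizes: ChromSizes) -> bool:
        return self.chrom in chrom_sizes and self.end <= chrom_sizes[self.chrom]


@dataclass
class GeneAnnotation:
    """A gene anchored by its TSS and TTS.

    For minus-strand genes ``tss > tts`` in genome coordinates; all anchored
    analyses flip the axis so that downstream of the TSS is positive.
    ``exon_blocks`` (absolute, sorted, half-open) and the UTR lengths are
    optional and only used for feature classification of shift regions.
    """

    gene_id: str
    chrom: str
    tss: int
    tts: int
    strand: str
    expression: float = 0.0
    active: bool | None = None
    promoter_elements: frozenset = field(default_factory=frozenset)
    exon_blocks: tuple[tuple[int, int], ...] | None = None
    utr5_len: int = 0
    utr3_len: int = 0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tts")
        if self.expression < 0:
            raise ValueError(f"gene {self.gene_id}: negative expression")
        bad = set(self.promoter_elements) - PROMOTER_ELEMENTS
        if bad:
            raise ValueError(f"gene {self.gene_id}: unknown promoter elements {sorted(bad)}")

    @property
    def body_start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def body_end(self) -> int:
        return max(self.tss, self.tts)

    @property
    def length(self) -> int:
        return self.body_end - self.body_start

    def oriented(self, offset: int) -> int:
        """Genome coordinate at a strand-oriented offset from the TSS."""
        return self.tss + offset if self.strand == "+" else self.tss - offset


@dataclass
class Site:
    """A point feature (TF motif hit or insulator summit).

    ``summit_reads`` maps a cofactor label (e.g. "CP190", "DREF") to the
    read count observed at the summit coordinate, used for stratification.
    """

    chrom: str
    summit: int
    factor: str
    summit_reads: dict[str, int] = field(default_factory=dict)
    site_id: str = ""

    def __post_init__(self):
        if self.summit < 0:
            raise ValueError(f"site {self.site_id or self.factor}: negative summit")
        for k, v in self.summit_reads.items():
            if v < 0:
                raise ValueError(f"site {self.site_id}: negative reads for {k}")


class SignalTrack:
    """Per-base-pair real-valued signal over a genome (dense arrays)."""

    def __init__(self, chrom_sizes: ChromSizes, label: str = "",
                 data: dict[str, np.ndarray] | None = None):
        self.chrom_sizes = chrom_sizes
        self.label = label
        if data is None:
            data = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
        else:
            for c, arr in data.items():
                if len(arr) != chrom_sizes[c]:
                    raise ValueError(f"track {label!r}: length mismatch on {c}")
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"track {label!r}: non-finite values on {c}")
        self.data = data

    def values(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def mean(self) -> float:
        n = sum(len(a) for a in self.data.values())
        return self.total() / n

    def copy(self, label: str | None = None) -> "SignalTrack":
        return SignalTrack(
            self.chrom_sizes,
            self.label if label is None else label,
            {c: a.copy() for c, a in self.data.items()},
        )
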
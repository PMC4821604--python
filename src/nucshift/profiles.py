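"""Anchored (metagene) averaging and ranking utilities.

Profiles are always strand-oriented: for a minus-strand anchor the offset
axis is flipped so that downstream of the anchor is positive. Heatmap-style
matrices keep one row per anchored region; averaged profiles are the
per-offset mean over rows with data at that offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Anchor:
    chrom: str
    pos: int
    strand: str = "+"
    name: str = ""


def tss_anchors(genes) -> list[Anchor]:
    return [Anchor(g.chrom, g.tss, g.strand, g.gene_id) for g in genes]


def tts_anchors(genes) -> list[Anchor]:
    # terminator profiles keep the gene's strand so downstream stays positive
    return [Anchor(g.chrom, g.tts, g.strand, g.gene_id) for g in genes]


def summit_anchors(sites) -> list[Anchor]:
    return [Anchor(s.chrom, s.summit, "+", s.site_id) for s in sites]


@dataclass
class AveragedProfile:
    offsets: np.ndarray
    values: np.ndarray
    n: np.ndarray       # rows contributing per offset

    def value_at(self, offset: int) -> float:
        i = int(offset - self.offsets[0])
        return float(self.values[i])


@dataclass
class ProfileMatrix:
    """Rows = anchored regions, columns = offsets (or scaled-body bins)."""

    data: np.ndarray          # float, NaN where missing
    offsets: np.ndarray
    row_names: list[str]

    def mean(self) -> AveragedProfile:
        with np.errstate(invalid="ignore"):
            values = np.nanmean(self.data, axis=0)
        n = np.sum(~np.isnan(self.data), axis=0)
        return AveragedProfile(self.offsets, values, n)

    def order_rows(self, key: np.ndarray) -> "ProfileMatrix":
        """Rows reordered by descending key (stable), for heatmaps."""
        order = np.argsort(-np.asarray(key, dtype=float), kind="stable")
        return ProfileMatrix(self.data[order], self.offsets,
                             [self.row_names[i] for i in order])


def _track_values(track, chrom):
    return track.values(chrom)


def anchored_matrix(track, anchors, L: int, strand_aware: bool = True) -> ProfileMatrix:
    """Signal in a ±L window around each anchor, strand-oriented.

    Cells outside the chromosome are NaN; anchors that are themselves off
    the chromosome drop their row with a warning.
    """
    if not anchors:
        raise ValueError("anchors must be nonempty")
    offsets = np.arange(-L, L + 1)
    rows, names = [], []
    n_dropped = 0
    for a in anchors:
        arr = _track_values(track, a.chrom)
        if not (0 <= a.pos < len(arr)):
            n_dropped += 1
            continue
        row = np.full(2 * L + 1, np.nan)
        lo = max(0, a.pos - L)
        hi = min(len(arr), a.pos + L + 1)
        row[lo - (a.pos - L):hi - (a.pos - L)] = arr[lo:hi]
        if strand_aware and a.strand == "-":
            row = row[::-1]
        rows.append(row)
        names.append(a.name)
    if n_dropped:
        logger.warning("anchored_matrix: dropped %d off-chromosome anchors", n_dropped)
    if not rows:
        raise ValueError("all anchors fell off the chromosome")
    return ProfileMatrix(np.vstack(rows), offsets, names)


def scaled_body_matrix(track, genes, body_length_target: int = 3000,
                       flank: int = 1000) -> ProfileMatrix:
    """Metagene matrix with unscaled flanks and the gene body linearly
    interpolated onto ``body_length_target`` coordinates."""
    rows, names = [], []
    offsets = np.arange(-flank, body_length_target + flank)
    for g in genes:
        if g.length < 2:
            continue
        arr = _track_values(track, g.chrom)
        sign = 1 if g.strand == "+" else -1
        up = [g.tss - sign * (flank - j) for j in range(flank)]
        body_pos = g.tss + sign * np.linspace(0, g.length - 1, body_length_target)
        down = [g.tts + sign * (j + 1) for j in range(flank)]
        coords = np.concatenate([up, body_pos, down])
        row = np.full(coords.shape, np.nan)
        ok = (coords >= 0) & (coords <= len(arr) - 1)
        row[ok] = np.interp(coords[ok], np.arange(len(arr)), arr)
        rows.append(row)
        names.append(g.gene_id)
    if not rows:
        raise ValueError("no gene long enough for a scaled-body profile")
    return ProfileMatrix(np.vstack(rows), offsets, names)


def rank_and_bin(items, key, n_bins: int) -> list[int]:
    """Descending rank by key -> as-equal-as-possible bins (1 = highest).

    Stable on input order for ties; when len(items) is not divisible by
    n_bins, earlier (higher-signal) bins take the remainder.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    items = list(items)
    key = np.asarray(list(key), dtype=float)
    if len(items) != len(key):
        raise ValueError("items and key must have equal length")
    if len(items) < n_bins:
        raise ValueError(f"fewer items ({len(items)}) than bins ({n_bins})")
    order = sorted(range(len(items)), key=lambda i: -key[i])  # stable
    base, rem = divmod(len(items), n_bins)
    sizes = [base + (1 if b < rem else 0) for b in range(n_bins)]
    bins = [0] * len(items)
    pos = 0
    for b, size in enumerate(sizes, start=1):
        for i in order[pos:pos + size]:
            bins[i] = b
        pos += size
    return bins


def classify_activity(genes, h3k4me3, window: int = 500,
                      multiplier: float = 2.0) -> dict[str, bool]:
    """Gene active iff its mean promoter H3K4me3 over [TSS, TSS+window]
    (strand-oriented) exceeds ``multiplier`` x the genome-wide mean.

    Scale-invariant: doubling the whole track leaves flags unchanged.
    """
    genome_mean = h3k4me3.mean()
    flags: dict[str, bool] = {}
    for g in genes:
        arr = h3k4me3.values(g.chrom)
        if g.strand == "+":
            lo, hi = g.tss, min(len(arr), g.tss + window)
        else:
            lo, hi = max(0, g.tss - window + 1), g.tss + 1
        mean = float(arr[lo:hi].mean()) if hi > lo else 0.0
        flags[g.gene_id] = mean > multiplier * genome_mean
    return flags


def stratify_by_cofactor(sites, cofactor: str, min_reads: int = 50):
    """Partition sites into (+cofactor, -cofactor) by summit read count.

    A site is +cofactor iff summit_reads[cofactor] >= min_reads (boundary
    inclusive: "at least" min_reads). Missing label on any site is an error.
    """
    plus, minus = [], []
    for s in sites:
        if cofactor not in s.summit_reads:
            raise ValueError(f"site {s.site_id or s.summit}: no summit read "
                             f"count for cofactor {cofactor!r}")
        (plus if s.summit_reads[cofactor] >= min_reads else minus).append(s)
    return plus, minus


def correlate_at_sites(track_a, track_b, sites, halfwidth: int = 250) -> float:
    """Pearson r of the two tracks' mean signals over summit ± halfwidth."""
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    xs, ys = [], []
    for s in sites:
        arr_a, arr_b = track_a.values(s.chrom), track_b.values(s.chrom)
        lo, hi = max(0, s.summit - halfwidth), min(len(arr_a), s.summit + halfwidth + 1)
        xs.append(float(arr_a[lo:hi].mean()))
        ys.append(float(arr_b[lo:hi].mean()))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("undefined correlation: zero variance in site summaries")
    return float(pearsonr(xs, ys).statistic)
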
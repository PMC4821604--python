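"""Window-based differential nucleosome-shift calling between two conditions.

Chromosomes are tiled into fixed-width windows (50 bp by default), dyad
counts per window are depth-normalized, and windows whose log2 fold change
exceeds a threshold are flagged as nucleosome shifts. Runs of shifted
windows merge into regions; their genomic distribution is summarized against
gene-feature classes and can be laid out on a Hilbert space-filling curve
for whole-chromosome visualization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binomtest, false_discovery_control

from .density import DyadCounts
from .genome import ChromSizes, GenomicInterval

DEFAULT_WINDOW = 50
DEFAULT_TAU = 2.0

FEATURE_CLASSES = ("upstream_1.5kb", "utr5", "utr3", "cds_exon", "intron",
                   "terminator_flank", "intergenic")
UPSTREAM_EXTENT = 1500
TERMINATOR_EXTENT = 500


def call_shifts(dyads_wt: DyadCounts, dyads_mut: DyadCounts,
                w: int = DEFAULT_WINDOW, tau: float = DEFAULT_TAU,
                step: int | None = None, one_sided: bool = False) -> pd.DataFrame:
    """Per-window shift statistics.

    Counts are depth-normalized to the geometric-mean library size (so the
    mutant/WT count ratio equals the total_wt/total_mut-scaled ratio, and
    swapping the conditions negates log2fc exactly); with a pseudocount of
    1, log2fc = log2((n_mut_norm + 1) / (n_wt_norm + 1)). A window is a
    shift when |log2fc| > tau (or log2fc > tau with ``one_sided``). Windows
    tile each chromosome without overlap by default (``step`` enables
    sliding windows); the last partial window is dropped.
    """
    if w <= 0:
        raise ValueError("window width must be > 0")
    step = w if step is None else step
    tot_wt, tot_mut = dyads_wt.total_dyads, dyads_mut.total_dyads
    if tot_wt == 0 or tot_mut == 0:
        raise ValueError("zero-total dyad library")
    depth = np.sqrt(tot_wt * tot_mut)
    scale_wt, scale_mut = depth / tot_wt, depth / tot_mut
    frames = []
    for chrom in dyads_wt.chrom_sizes:
        length = dyads_wt.chrom_sizes[chrom]
        starts = np.arange(0, length - w + 1, step)
        cum_wt = np.concatenate(([0], np.cumsum(dyads_wt.counts(chrom))))
        cum_mut = np.concatenate(([0], np.cumsum(dyads_mut.counts(chrom))))
        n_wt = cum_wt[starts + w] - cum_wt[starts]
        n_mut = cum_mut[starts + w] - cum_mut[starts]
        wt_norm = n_wt * scale_wt
        mut_norm = n_mut * scale_mut
        log2fc = np.log2((mut_norm + 1) / (wt_norm + 1))
        is_shift = (log2fc > tau) if one_sided else (np.abs(log2fc) > tau)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + w,
            "n_wt": n_wt, "n_mut": n_mut,
            "n_wt_norm": wt_norm, "n_mut_norm": mut_norm,
            "log2fc": log2fc, "is_shift": is_shift}))
    return pd.concat(frames, ignore_index=True)


def merge_shifts(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge maximal runs of consecutive shifted windows into regions."""
    shifted = windows[windows["is_shift"]].sort_values(["chrom", "start"])
    regions = []
    for chrom, grp in shifted.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        fc = grp["log2fc"].to_numpy()
        if len(starts) == 0:
            continue
        breaks = np.flatnonzero(starts[1:] != ends[:-1]) + 1
        for idx in np.split(np.arange(len(starts)), breaks):
            block_fc = fc[idx]
            regions.append({
                "chrom": chrom, "start": int(starts[idx[0]]),
                "end": int(ends[idx[-1]]), "n_windows": len(idx),
                "max_abs_log2fc": float(np.abs(block_fc).max()),
                "sign": int(np.sign(block_fc[np.abs(block_fc).argmax()]))})
    cols = ["chrom", "start", "end", "n_windows", "max_abs_log2fc", "sign"]
    return pd.DataFrame(regions, columns=cols)


def shift_fraction(n_regions: int, genome_size: float, nrl_genomewide: float) -> float:
    """Percent of genomic nucleosomes affected: 100 * n / (G / NRL)."""
    if n_regions < 0 or genome_size <= 0 or nrl_genomewide <= 0:
        raise ValueError("arguments must be positive")
    return 100.0 * n_regions / (genome_size / nrl_genomewide)


def _paint_feature_classes(annotations, chrom_sizes: ChromSizes) -> dict[str, np.ndarray]:
    """Per-bp feature class index, painted in increasing precedence order so
    higher-precedence classes overwrite lower ones."""
    idx = {c: i for i, c in enumerate(FEATURE_CLASSES)}
    paint = {c: np.full(n, idx["intergenic"], dtype=np.int8)
             for c, n in chrom_sizes.items()}

    def clip_span(chrom, a, b):
        return max(0, min(a, b)), min(chrom_sizes[chrom], max(a, b))

    for cls in ("terminator_flank", "intron", "cds_exon", "utr3", "utr5",
                "upstream_1.5kb"):
        for g in annotations:
            arr = paint[g.chrom]
            sign = 1 if g.strand == "+" else -1
            if cls == "terminator_flank":
                a, b = clip_span(g.chrom, g.tts, g.tts + sign * TERMINATOR_EXTENT)
                arr[a:b] = idx[cls]
            elif cls == "intron":
                a, b = g.body_start, g.body_end
                arr[a:b] = idx[cls]
            elif cls == "cds_exon":
                blocks = g.exon_blocks or ((g.body_start, g.body_end),)
                for s, e in blocks:
                    arr[s:e] = idx[cls]
            elif cls == "utr3" and g.utr3_len > 0:
                a, b = clip_span(g.chrom, g.tts, g.tts - sign * g.utr3_len)
                arr[a:b] = idx[cls]
            elif cls == "utr5" and g.utr5_len > 0:
                a, b = clip_span(g.chrom, g.tss, g.tss + sign * g.utr5_len)
                arr[a:b] = idx[cls]
            elif cls == "upstream_1.5kb":
                a, b = clip_span(g.chrom, g.tss, g.tss - sign * UPSTREAM_EXTENT)
                arr[a:b] = idx[cls]
    return paint


def feature_enrichment(regions: pd.DataFrame, annotations,
                       chrom_sizes: ChromSizes) -> pd.DataFrame:
    """Distribution of shift-region midpoints over gene-feature classes,
    compared with the fraction of the genome each class occupies.

    Each region is assigned to exactly one class by its midpoint, with
    precedence upstream > 5'UTR > 3'UTR > CDS exon > intron > terminator
    flank > intergenic. Per-class binomial test against the genome fraction,
    Benjamini-Hochberg adjusted.
    """
    if not annotations:
        raise ValueError("annotations must be nonempty")
    paint = _paint_feature_classes(annotations, chrom_sizes)
    genome_counts = np.zeros(len(FEATURE_CLASSES))
    for arr in paint.values():
        genome_counts += np.bincount(arr, minlength=len(FEATURE_CLASSES))
    genome_frac = genome_counts / genome_counts.sum()

    mids = ((regions["start"] + regions["end"]) // 2).to_numpy()
    chroms = regions["chrom"].to_numpy()
    assigned = np.array([paint[c][m] for c, m in zip(chroms, mids)], dtype=int)
    n = len(assigned)
    shift_counts = np.bincount(assigned, minlength=len(FEATURE_CLASSES))
    shift_frac = shift_counts / n if n else np.zeros(len(FEATURE_CLASSES))

    pvals = np.array([
        binomtest(int(k), n, p).pvalue if n and 0 < p < 1 else 1.0
        for k, p in zip(shift_counts, genome_frac)])
    padj = false_discovery_control(pvals, method="bh")
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(genome_frac > 0, shift_frac / genome_frac, np.nan)
    return pd.DataFrame({
        "feature": FEATURE_CLASSES, "n_regions": shift_counts,
        "shift_fraction": shift_frac, "genome_fraction": genome_frac,
        "fold_enrichment": fold, "pvalue": pvals, "padj": padj})


# --------------------------------------------------------------------------
# Hilbert curve layout

def hilbert_d2xy(order: int, d: int) -> tuple[int, int]:
    """Map distance d along the order-n Hilbert curve to (x, y)."""
    n = 1 << order
    x = y = 0
    t = d
    s = 1
    while s < n:
        rx = 1 & (t // 2)
        ry = 1 & (t ^ rx)
        if ry == 0:
            if rx == 1:
                x, y = s - 1 - x, s - 1 - y
            x, y = y, x
        x += s * rx
        y += s * ry
        t //= 4
        s *= 2
    return x, y


def hilbert_layout(regions: pd.DataFrame, chrom: str, chrom_sizes: ChromSizes,
                   order: int = 9) -> np.ndarray:
    """Counts of region midpoints in 4^order equal chromosome bins, laid out
    on the Hilbert curve as a (2^order, 2^order) matrix."""
    if order < 1:
        raise ValueError("order must be >= 1")
    n = 1 << order
    n_bins = n * n
    length = chrom_sizes[chrom]
    mat = np.zeros((n, n), dtype=np.int64)
    sel = regions[regions["chrom"] == chrom]
    mids = ((sel["start"] + sel["end"]) // 2).to_numpy()
    bins = np.minimum((mids * n_bins) // length, n_bins - 1)
    for b in bins:
        x, y = hilbert_d2xy(order, int(b))
        mat[y, x] += 1
    return mat


def regions_to_intervals(regions: pd.DataFrame) -> list[GenomicInterval]:
    return [GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in regions.itertuples(index=False)]
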
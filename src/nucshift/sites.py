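"""Classification of nucleosome organization around point sites.

Five archetypes of flanking nucleosome organization are distinguished from
the WT and mutant density tracks:

* I_occupied      — a remodeler-independent nucleosome on the site itself;
* II_adjacent     — a remodeler-dependent nucleosome immediately adjacent to
                    the site (dyad ~90-160 bp away), lost in the mutant;
* III_entry_exit  — the site sits in the nucleosome entry/exit DNA (dyad
                    ~50-90 bp away), position lost in the mutant;
* IV_depleted     — the site lies in an extended nucleosome-depleted domain
                    that gains nucleosomes in the mutant;
* V_barrier       — a depleted domain flanked by phased arrays that migrate
                    inward in the mutant (insulator-like barrier).

All scores are ratios of, or positions on, the density track, so the
classification is invariant under genome-wide rescaling. The category
cut-offs are this module's contract, chosen from nucleosome geometry
(dyad ± 73 bp core, ~185 bp repeat): see the thresholds dataclass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

CORE_HALFWIDTH = 73
FLANK_SPAN = 1000
PHASING_LAGS = (150, 200)


@dataclass(frozen=True)
class ClassifierThresholds:
    depleted_occupancy: float = 0.5    # occupancy_ratio below -> IV/V branch
    occupied_occupancy: float = 1.2    # above, with a near peak -> I
    phasing_min: float = 0.3           # phased flanks -> V rather than IV
    near_peak_dist: int = 40           # site-on-nucleosome distance, class I
    persist_dist: int = 20             # mutant peak within this of WT -> persists
    entry_exit_band: tuple = (50, 90)  # nearest-dyad distance band, class III
    adjacent_band: tuple = (90, 160)   # (exclusive, inclusive] band, class II
    lost_extra_dist: int = 30          # mutant nearest-peak drift -> lost
    lost_prominence_ratio: float = 0.5 # mutant prominence below half WT -> lost
    peak_prominence_frac: float = 0.2  # local peak gate, fraction of window max


@dataclass
class SiteScores:
    occupancy_ratio: float
    nearest_peak_distance: float       # inf when no qualifying peak
    nearest_peak_offset: float
    nearest_peak_prominence: float
    phasing_score: float
    phasing_lag: int | None
    flank_mean: float
    defined: bool = True


@dataclass
class SiteClassification:
    site_id: str
    category: str | None
    low_confidence: bool
    scores_wt: SiteScores
    scores_mut: SiteScores


def _phasing(flank_left: np.ndarray, flank_right: np.ndarray,
             lags=PHASING_LAGS) -> tuple[float, int | None]:
    """Max over lag in [150, 200] bp of the flank density autocorrelation
    (Pearson r between the flank and its lagged copy, averaged over the two
    flank sides)."""
    best, best_lag = -np.inf, None
    segs = [s - s.mean() for s in (flank_left, flank_right) if len(s) > lags[1] + 10]
    if not segs:
        return 0.0, None
    for lag in range(lags[0], lags[1] + 1):
        rs = []
        for seg in segs:
            a, b = seg[:-lag], seg[lag:]
            va, vb = a.std(), b.std()
            if va == 0 or vb == 0:
                continue
            rs.append(float(np.mean((a - a.mean()) * (b - b.mean())) / (va * vb)))
        if rs:
            r = float(np.mean(rs))
            if r > best:
                best, best_lag = r, lag
    if best_lag is None:
        return 0.0, None
    return best, best_lag


def site_scores(track, site, core_halfwidth: int = CORE_HALFWIDTH,
                flank_span: int = FLANK_SPAN,
                peak_prominence_frac: float = 0.2) -> SiteScores:
    """Occupancy, nearest-peak and phasing scores of one site on one track.

    occupancy_ratio = mean density over summit ± core_halfwidth divided by
    the mean over summit ± flank_span excluding the core.
    """
    if flank_span <= core_halfwidth:
        raise ValueError("flank_span must exceed core_halfwidth")
    arr = track.values(site.chrom)
    lo, hi = site.summit - flank_span, site.summit + flank_span + 1
    if lo < 0 or hi > len(arr):
        return SiteScores(np.nan, np.inf, np.nan, np.nan, 0.0, None, np.nan,
                          defined=False)
    window = np.asarray(arr[lo:hi], dtype=float)
    center = flank_span
    core = window[center - core_halfwidth:center + core_halfwidth + 1]
    flank_left = window[:center - core_halfwidth]
    flank_right = window[center + core_halfwidth + 1:]
    flank_mean = float(np.concatenate([flank_left, flank_right]).mean())
    if flank_mean <= 0:
        return SiteScores(np.nan, np.inf, np.nan, np.nan, 0.0, None, 0.0,
                          defined=False)
    occupancy_ratio = float(core.mean()) / flank_mean

    prominence = peak_prominence_frac * float(window.max())
    idx, props = find_peaks(window, prominence=max(prominence, 1e-300))
    if idx.size:
        offsets = idx - center
        nearest = int(np.argmin(np.abs(offsets)))
        near_dist = float(abs(offsets[nearest]))
        near_off = float(offsets[nearest])
        near_prom = float(props["prominences"][nearest])
    else:
        near_dist, near_off, near_prom = np.inf, np.nan, 0.0

    phasing, lag = _phasing(flank_left, flank_right)
    return SiteScores(occupancy_ratio, near_dist, near_off, near_prom,
                      phasing, lag, flank_mean)


def _position_lost(wt: SiteScores, mut: SiteScores,
                   thr: ClassifierThresholds) -> bool:
    """Mutant loses the WT-positioned nucleosome: its nearest peak drifts by
    more than ``lost_extra_dist`` bp or collapses below half the WT
    prominence."""
    if not np.isfinite(mut.nearest_peak_distance):
        return True
    drifted = mut.nearest_peak_distance > wt.nearest_peak_distance + thr.lost_extra_dist
    collapsed = mut.nearest_peak_prominence < (thr.lost_prominence_ratio
                                               * wt.nearest_peak_prominence)
    return bool(drifted or collapsed)


def classify_site(scores_wt: SiteScores, scores_mut: SiteScores, site_id: str = "",
                  thresholds: ClassifierThresholds = ClassifierThresholds()
                  ) -> SiteClassification:
    """Deterministic decision cascade over the WT/mutant score records."""
    thr = thresholds
    wt, mut = scores_wt, scores_mut
    if not (wt.defined and mut.defined):
        return SiteClassification(site_id, None, True, wt, mut)

    if wt.occupancy_ratio < thr.depleted_occupancy:
        # A barrier's flanking arrays persist in the mutant (they migrate
        # inward but stay phased); a depleted domain fills in and loses all
        # periodicity. Requiring phasing in both conditions makes the V/IV
        # split robust to per-site autocorrelation noise.
        cat = ("V_barrier" if (wt.phasing_score >= thr.phasing_min
                               and mut.phasing_score >= thr.phasing_min)
               else "IV_depleted")
        return SiteClassification(site_id, cat, False, wt, mut)

    lost = _position_lost(wt, mut, thr)
    persists = (np.isfinite(mut.nearest_peak_distance)
                and np.isfinite(wt.nearest_peak_distance)
                and abs(mut.nearest_peak_offset - wt.nearest_peak_offset)
                <= thr.persist_dist)
    if (wt.occupancy_ratio > thr.occupied_occupancy
            and wt.nearest_peak_distance <= thr.near_peak_dist and persists):
        return SiteClassification(site_id, "I_occupied", False, wt, mut)
    lo3, hi3 = thr.entry_exit_band
    if lo3 <= wt.nearest_peak_distance <= hi3 and lost:
        return SiteClassification(site_id, "III_entry_exit", False, wt, mut)
    lo2, hi2 = thr.adjacent_band
    if lo2 < wt.nearest_peak_distance <= hi2 and lost:
        return SiteClassification(site_id, "II_adjacent", False, wt, mut)
    return SiteClassification(site_id, "I_occupied", True, wt, mut)


def ndr_halfwidth(track, site, threshold_frac: float = 0.25,
                  flank_span: int = FLANK_SPAN, step: int = 10) -> float:
    """Half-width of the nucleosome-depleted region around a summit.

    Scans outward in ``step``-bp shells; the NDR extends while the mean
    density over the shells at ±w stays below threshold_frac x the flank
    reference (the mean over the outer 40% of the ±flank_span window).
    Returns 0 when the density at the summit itself is already above
    threshold.
    """
    if not (0 < threshold_frac < 1):
        raise ValueError("threshold_frac must be in (0, 1)")
    arr = track.values(site.chrom)
    lo, hi = site.summit - flank_span, site.summit + flank_span + 1
    if lo < 0 or hi > len(arr):
        raise ValueError(f"site {site.site_id}: flank span off chromosome")
    window = np.asarray(arr[lo:hi], dtype=float)
    center = flank_span
    band = int(0.6 * flank_span)
    ref = float(np.concatenate([window[:flank_span - band],
                                window[flank_span + band + 1:]]).mean())
    if ref <= 0:
        return 0.0
    w = 0
    while w + step <= flank_span:
        shell = np.concatenate([window[center + w:center + w + step],
                                window[center - w - step:center - w]])
        if shell.mean() >= threshold_frac * ref:
            break
        w += step
    return float(w)


def classify_all(track_wt, track_mut, sites, truth_labels: dict | None = None,
                 thresholds: ClassifierThresholds = ClassifierThresholds(),
                 core_halfwidth: int = CORE_HALFWIDTH,
                 flank_span: int = FLANK_SPAN):
    """One classification per site; confusion matrix when truth is supplied.

    Sites whose scores are undefined on either track (empty flanks, off the
    chromosome) are reported with category None; the rest are classified.
    Returns (DataFrame, confusion-DataFrame-or-None).
    """
    if not sites:
        raise ValueError("sites must be nonempty")
    rows = []
    for s in sites:
        wt = site_scores(track_wt, s, core_halfwidth, flank_span,
                         thresholds.peak_prominence_frac)
        mut = site_scores(track_mut, s, core_halfwidth, flank_span,
                          thresholds.peak_prominence_frac)
        cls = classify_site(wt, mut, site_id=s.site_id, thresholds=thresholds)
        rows.append({
            "site_id": s.site_id, "chrom": s.chrom, "summit": s.summit,
            "factor": s.factor, "category": cls.category,
            "low_confidence": cls.low_confidence,
            "occupancy_ratio_wt": wt.occupancy_ratio,
            "nearest_peak_distance_wt": wt.nearest_peak_distance,
            "phasing_score_wt": wt.phasing_score,
            "occupancy_ratio_mut": mut.occupancy_ratio,
            "nearest_peak_distance_mut": mut.nearest_peak_distance,
            "phasing_score_mut": mut.phasing_score,
            "truth": truth_labels.get(s.site_id) if truth_labels else None})
    table = pd.DataFrame(rows)
    confusion = None
    if truth_labels:
        scored = table.dropna(subset=["truth", "category"])
        # insulator sites are barrier-class architectures
        truth = scored["truth"].replace({"insulator": "V_barrier"})
        confusion = pd.crosstab(truth, scored["category"])
    return table, confusion
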
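"""Synthetic MNase mononucleosome-fragment generator.

Builds paired wild-type (WT) / remodeler-mutant fragment libraries over a toy
genome whose ground-truth chromatin architecture is fully parameterized:

* positioned nucleosome arrays downstream of active TSSs (a +1 nucleosome at a
  configurable dyad offset, a regular lattice with a given repeat length, and
  Gaussian positional fuzz),
* fuzzier arrays on inactive genes,
* nucleosome-depleted regions (NDRs) between TSS and +1,
* TF sites of five flanking-organization classes (occupied / adjacent /
  entry-exit / depleted / barrier) plus insulator sites with phased flanking
  arrays whose NDR narrows in the mutant,
* uniform background dyads.

Every dyad is drawn from an explicit emission component (a Gaussian anchored
on a lattice position, or a uniform rate), and the component list is retained
in the :class:`GroundTruth` so that expected per-window counts — and hence
true shifted windows — can be computed analytically, independently of the
sampled fragments.

Default parameters follow the printed estimates of the study conditions:
active genes +1 = +132 bp / NRL 175 bp in WT versus +123 bp / 170 bp in the
mutant; inactive genes NRL 185 bp in both; paused (INR/MTE/DPE) promoters
+142 bp; expression quintiles +125 bp (lowest) to +136 bp (highest); insulator
NDR half-width 200 bp (WT) narrowing to 125 bp (mutant) with 185 bp phased
flanks. A fragment around a dyad d has length L ~ Normal(147, 10) truncated
to [120, 180] and start d - floor(L/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import io as nio
from .genome import ChromSizes, GeneAnnotation, GenomicInterval, SignalTrack, Site

# --------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class NucleosomeArraySpec:
    """A phased nucleosome array downstream of a TSS.

    ``plus_one`` is the dyad of the first nucleosome, bp downstream of the
    TSS; nucleosome k (k = 0..n-1) is anchored at plus_one + k * nrl; each
    nucleosome emits ``occupancy`` dyads drawn Normal(anchor, fuzz_sd).
    """

    plus_one: float
    nrl: float
    n_nucleosomes: int = 8
    fuzz_sd: float = 15.0
    occupancy: int = 30

    def __post_init__(self):
        if self.nrl < 147:
            raise ValueError("nrl must be >= 147 bp (nucleosomes cannot overlap)")
        if self.fuzz_sd < 0:
            raise ValueError("fuzz_sd must be >= 0")
        if self.n_nucleosomes < 1:
            raise ValueError("n_nucleosomes must be >= 1")


@dataclass(frozen=True)
class SiteArchitectureSpec:
    """Per-condition nucleosome organization around a point site.

    The NDR spans summit ± ndr_halfwidth with zero array dyads; flanking
    nucleosome DNA abuts the NDR boundary, so the first flanking dyad sits at
    summit ± (ndr_halfwidth + 73). ``positioned_offset`` places a single
    well-positioned nucleosome dyad at that unsigned offset from the summit
    (None for no positioned nucleosome). ``ambient_rate`` is fuzzy local
    chromatin (dyads/bp over the whole ±span window); ``ndr_fill_rate`` adds
    uniform dyads inside the NDR (mutant fill-in); flanks are either "phased"
    lattices or "uniform" fuzzy coverage.
    """

    class_label: str
    positioned_offset: float | None = None
    positioned_occ: int = 30
    positioned_fuzz: float = 10.0
    ambient_rate: float = 0.0
    ndr_halfwidth: float = 0.0
    ndr_fill_rate: float = 0.0
    flank_mode: str = "none"          # none | phased | uniform
    flank_rate: float = 0.0           # dyads/bp, uniform mode
    flank_nrl: float = 185.0
    flank_n: int = 5
    flank_occ: int = 30
    flank_fuzz: float = 15.0
    span: float = 1000.0

    def __post_init__(self):
        if self.ndr_halfwidth < 0:
            raise ValueError("ndr_halfwidth must be >= 0")
        if self.flank_mode not in ("none", "phased", "uniform"):
            raise ValueError(f"unknown flank_mode {self.flank_mode!r}")


@dataclass
class GeneGroup:
    name: str
    n: int
    wt: NucleosomeArraySpec
    mut: NucleosomeArraySpec
    active: bool = True
    promoter_elements: frozenset = field(default_factory=frozenset)
    quintile: int | None = None
    expression_scale: float = 100.0


@dataclass
class SiteGroup:
    name: str
    n: int
    wt: SiteArchitectureSpec
    mut: SiteArchitectureSpec
    factor: str = "TF"
    #: cofactor label -> "high" (>= 50 summit reads) or "low" (< 50)
    cofactor_levels: dict = field(default_factory=dict)
    #: explicit summit coordinates; auto-layout when None
    summits: list[int] | None = None


@dataclass
class SimConfig:
    """Full description of one paired-condition simulation.

    The random seed fixes the complete output (fragments, tables, tracks).
    """

    gene_groups: list = field(default_factory=list)
    site_groups: list = field(default_factory=list)
    chrom_name: str = "chrS"
    frag_len_mean: float = 147.0
    frag_len_sd: float = 10.0
    frag_len_bounds: tuple[int, int] = (120, 180)
    background_frac: float = 0.05
    depth: float = 1.0
    seed: int = 0
    gene_spacing: int = 6000
    site_spacing: int = 4000
    margin: int = 5000
    gene_body_len: int = 4000
    tss_offset_in_slot: int = 1000

    def __post_init__(self):
        lo, hi = self.frag_len_bounds
        if not (100 <= lo <= hi <= 250):
            raise ValueError("fragment length bounds must lie within [100, 250]")
        if not (0 <= self.background_frac < 1):
            raise ValueError("background_frac must be in [0, 1)")


# --------------------------------------------------------------------------
# presets (study-condition parameters)

_GENE_PRESETS = {
    # name: (plus_one, nrl, fuzz_sd)
    "wt_active": (132.0, 175.0, 15.0),
    "mut_active": (123.0, 170.0, 15.0),
    "wt_inactive": (132.0, 185.0, 25.0),   # +1 not a recovery target; fuzzier array
    "mut_inactive": (132.0, 185.0, 25.0),  # identical lattice to wt_inactive
    "paused": (142.0, 175.0, 15.0),        # INR/MTE/DPE promoters, both conditions
}
# Expression quintiles: +1 interpolated from +136 (q1, highest) to +125 (q5).
_QUINTILE_PLUS_ONE = dict(zip(range(1, 6), np.linspace(136.0, 125.0, 5)))
for _q, _p1 in _QUINTILE_PLUS_ONE.items():
    _GENE_PRESETS[f"quintile_q{_q}"] = (float(_p1), 175.0, 15.0)

#: Positional shift of the +1 (and the whole lattice start) in the mutant on
#: remodeler-responsive genes, and the mutant repeat length.
MUTANT_PLUS_ONE_SHIFT = -9.0
MUTANT_NRL = 170.0

AMBIENT_RATE = 0.12        # dyads/bp, fuzzy chromatin at class I-III sites
FUZZY_FLANK_RATE = 30 / 185.0  # one 30-dyad nucleosome per 185 bp


def preset(name: str) -> NucleosomeArraySpec:
    """Named gene-array preset (e.g. ``wt_active`` -> +1 132, NRL 175)."""
    try:
        plus_one, nrl, fuzz = _GENE_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(_GENE_PRESETS)}")
    return NucleosomeArraySpec(plus_one=plus_one, nrl=nrl, fuzz_sd=fuzz)


def gene_group(name: str, n: int = 200) -> GeneGroup:
    """Paired WT/mutant gene group for a study condition."""
    if name == "active":
        return GeneGroup(name, n, preset("wt_active"), preset("mut_active"),
                         active=True, promoter_elements=frozenset({"DRE", "Ohler1"}),
                         expression_scale=100.0)
    if name == "inactive":
        return GeneGroup(name, n, preset("wt_inactive"), preset("mut_inactive"),
                         active=False, promoter_elements=frozenset(),
                         expression_scale=1.0)
    if name == "paused":
        spec = preset("paused")
        return GeneGroup(name, n, spec, spec, active=True,
                         promoter_elements=frozenset({"INR", "MTE", "DPE"}),
                         expression_scale=100.0)
    if name.startswith("quintile_q"):
        q = int(name[-1])
        wt = preset(name)
        mut = replace(wt, plus_one=wt.plus_one + MUTANT_PLUS_ONE_SHIFT, nrl=MUTANT_NRL)
        scale = {1: 1000.0, 2: 300.0, 3: 100.0, 4: 30.0, 5: 10.0}[q]
        return GeneGroup(name, n, wt, mut, active=True,
                         promoter_elements=frozenset({"DRE"}),
                         quintile=q, expression_scale=scale)
    raise ValueError(f"unknown gene group {name!r}")


SITE_CLASSES = ("I_occupied", "II_adjacent", "III_entry_exit",
                "IV_depleted", "V_barrier", "insulator")


def site_preset(class_label: str) -> tuple[SiteArchitectureSpec, SiteArchitectureSpec]:
    """Paired WT/mutant site architecture for one flanking-organization class."""
    if class_label == "I_occupied":
        wt = SiteArchitectureSpec(class_label, positioned_offset=0.0,
                                  ambient_rate=AMBIENT_RATE)
        return wt, wt
    if class_label == "II_adjacent":
        wt = SiteArchitectureSpec(class_label, positioned_offset=120.0,
                                  ambient_rate=AMBIENT_RATE)
        return wt, replace(wt, positioned_offset=None)
    if class_label == "III_entry_exit":
        wt = SiteArchitectureSpec(class_label, positioned_offset=70.0,
                                  ambient_rate=AMBIENT_RATE)
        return wt, replace(wt, positioned_offset=None)
    if class_label == "IV_depleted":
        wt = SiteArchitectureSpec(class_label, ndr_halfwidth=200.0,
                                  flank_mode="uniform", flank_rate=FUZZY_FLANK_RATE)
        return wt, replace(wt, ndr_fill_rate=FUZZY_FLANK_RATE)
    if class_label in ("V_barrier", "insulator"):
        wt = SiteArchitectureSpec(class_label, ndr_halfwidth=200.0,
                                  flank_mode="phased", flank_nrl=185.0,
                                  flank_n=5, flank_occ=30, flank_fuzz=15.0)
        return wt, replace(wt, ndr_halfwidth=125.0)
    raise ValueError(f"unknown site class {class_label!r}; known: {SITE_CLASSES}")


def site_group(class_label: str, n: int = 100, factor: str | None = None,
               cofactor_levels: dict | None = None) -> SiteGroup:
    wt, mut = site_preset(class_label)
    if factor is None:
        factor = {"IV_depleted": "Trl", "V_barrier": "Su(Hw)",
                  "insulator": "CTCF"}.get(class_label, "TF")
    if cofactor_levels is None:
        cofactor_levels = {"CP190": "high"} if class_label == "insulator" else {}
    return SiteGroup(class_label, n, wt, mut, factor=factor,
                     cofactor_levels=cofactor_levels)


def study_defaults_config(seed: int = 0, n_genes: int = 200,
                          n_sites: int = 100, depth: float = 1.0) -> SimConfig:
    """The full study-condition bundle: every gene preset and site class."""
    genes = [gene_group("active", n_genes), gene_group("inactive", n_genes),
             gene_group("paused", max(50, n_genes // 2))]
    genes += [gene_group(f"quintile_q{q}", max(50, n_genes // 2)) for q in range(1, 6)]
    sites = [site_group(lab, n_sites) for lab in SITE_CLASSES]
    return SimConfig(gene_groups=genes, site_groups=sites, seed=seed, depth=depth)


def single_gene_config(preset_group: str, n: int = 200, seed: int = 0,
                       depth: float = 1.0) -> SimConfig:
    """A focused bundle containing one gene group only (recovery runs)."""
    return SimConfig(gene_groups=[gene_group(preset_group, n)], seed=seed, depth=depth)


def sites_only_config(n_per_class: int = 100, seed: int = 0,
                      classes=SITE_CLASSES) -> SimConfig:
    return SimConfig(site_groups=[site_group(lab, n_per_class) for lab in classes],
                     seed=seed)


# --------------------------------------------------------------------------
# ground truth

@dataclass
class GroundTruth:
    """Oracle for recovery tests: one record per simulated gene and site,
    plus the analytic emission components of each condition."""

    genes: pd.DataFrame
    sites: pd.DataFrame
    components: dict            # condition -> list of emission components
    chrom_sizes: ChromSizes
    chrom: str

    def expected_window_counts(self, w: int = 50) -> pd.DataFrame:
        """Expected dyad count per w-bp window for both conditions."""
        length = self.chrom_sizes[self.chrom]
        m = length // w
        edges = np.arange(m + 1) * w
        out = {}
        for cond, comps in self.components.items():
            e = np.zeros(m)
            for comp in comps:
                kind = comp[0]
                if kind == "gauss":
                    _, anchor, sd, n = comp
                    if sd == 0:
                        idx = int(anchor) // w
                        if 0 <= idx < m:
                            e[idx] += n
                        continue
                    lo = max(0, int((anchor - 8 * sd) // w))
                    hi = min(m, int((anchor + 8 * sd) // w) + 1)
                    if lo >= hi:
                        continue
                    cdf = norm.cdf((edges[lo:hi + 1] - anchor) / sd)
                    e[lo:hi] += n * np.diff(cdf)
                else:  # uniform
                    _, s, t, n = comp
                    if t <= s:
                        continue
                    rate = n / (t - s)
                    ov = np.clip(np.minimum(edges[1:], t) - np.maximum(edges[:-1], s),
                                 0, None)
                    e += rate * ov
            out[cond] = e
        return pd.DataFrame({"chrom": self.chrom, "start": edges[:-1],
                             "e_wt": out["wt"], "e_mut": out["mut"]})

    def shifted_windows(self, w: int = 50, tau: float = 2.0) -> pd.DataFrame:
        """Analytically true shifted windows at the caller's own statistic."""
        df = self.expected_window_counts(w)
        tot_wt, tot_mut = df["e_wt"].sum(), df["e_mut"].sum()
        depth = np.sqrt(tot_wt * tot_mut)  # caller's geometric-mean scaling
        wt_n = df["e_wt"] * (depth / tot_wt)
        mut_n = df["e_mut"] * (depth / tot_mut)
        df["log2fc_expected"] = np.log2((mut_n + 1) / (wt_n + 1))
        df["is_shift"] = df["log2fc_expected"].abs() > tau
        return df


@dataclass
class SimBundle:
    config: SimConfig
    chrom_sizes: ChromSizes
    fragments: dict             # condition -> list[GenomicInterval]
    annotations: list
    sites: list
    tracks: dict                # label -> SignalTrack
    truth: GroundTruth

    def write(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for cond, frags in self.fragments.items():
            nio.write_fragments_bed(frags, out / f"fragments_{cond}.bed")
        nio.write_annotations(self.annotations, out / "annotations.tsv")
        nio.write_sites(self.sites, out / "sites.tsv")
        for label, track in self.tracks.items():
            nio.write_bedgraph(track, out / f"{label}.bedGraph")
        with open(out / "chrom.sizes", "w") as fh:
            for c, n in self.chrom_sizes.items():
                fh.write(f"{c}\t{n}\n")
        self.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        self.truth.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# generation

CONDITIONS = ("wt", "mut")
NUC_HALFWIDTH = 73  # bp from dyad to nucleosome DNA edge


def _truncnorm_lengths(rng, n, mean, sd, bounds):
    lo, hi = bounds
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError("degenerate fragment length outside bounds")
        return np.full(n, int(round(mean)), dtype=np.int64)
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return np.rint(out).astype(np.int64)


def generate(config: SimConfig) -> SimBundle:
    """Run the generator. Identical config (incl. seed) -> identical output."""
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom_name

    # ---- layout
    cursor = config.margin
    gene_slots = []
    for grp in config.gene_groups:
        if grp.n <= 0:
            raise ValueError(f"gene group {grp.name!r} enabled with zero genes")
        for i in range(grp.n):
            gene_slots.append((grp, cursor, i))
            cursor += config.gene_spacing
    site_slots = []
    for grp in config.site_groups:
        if grp.summits is not None:
            for i, summit in enumerate(grp.summits):
                site_slots.append((grp, int(summit), i))
        else:
            for i in range(grp.n):
                cursor += config.site_spacing
                site_slots.append((grp, cursor - config.site_spacing // 2, i))
    length = cursor + config.margin
    length = max(length, config.margin * 2 + 1000,
                 max((s + 2000 for _, s, _ in site_slots), default=0))
    chrom_sizes = ChromSizes({chrom: length})

    dyads: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    components: dict[str, list] = {c: [] for c in CONDITIONS}
    annotations: list[GeneAnnotation] = []
    sites: list[Site] = []
    gene_rows, site_rows = [], []
    h3k4me3 = SignalTrack(chrom_sizes, label="H3K4me3")
    cp190 = SignalTrack(chrom_sizes, label="CP190")

    def emit_gauss(cond, anchor, sd, n):
        n = int(round(n * config.depth))
        if n <= 0:
            return
        pos = np.full(n, anchor) if sd == 0 else rng.normal(anchor, sd, size=n)
        dyads[cond].append(np.rint(pos).astype(np.int64))
        components[cond].append(("gauss", float(anchor), float(sd) if sd else 1e-9, n))

    def emit_uniform(cond, s, t, n):
        n = int(round(n * config.depth))
        if n <= 0 or t <= s:
            return
        dyads[cond].append(rng.integers(int(s), int(t), size=n).astype(np.int64))
        components[cond].append(("uniform", float(s), float(t), n))

    # ---- genes
    for grp, slot_start, i in gene_slots:
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss = slot_start + config.tss_offset_in_slot
            tts = tss + config.gene_body_len
        else:
            tss = slot_start + config.tss_offset_in_slot + config.gene_body_len
            tts = tss - config.gene_body_len
        sign = 1 if strand == "+" else -1
        expression = float(grp.expression_scale * rng.lognormal(0.0, 0.25))
        # simple 3-exon gene model (transcript-oriented blocks, bp)
        t_blocks = [(0, 800), (1600, 2400), (3200, config.gene_body_len)]
        blocks = tuple(sorted(tuple(sorted((tss + sign * a, tss + sign * b)))
                              for a, b in t_blocks))
        annotations.append(GeneAnnotation(
            gene_id=f"{grp.name}_{i:04d}", chrom=chrom, tss=tss, tts=tts,
            strand=strand, expression=expression, active=grp.active,
            promoter_elements=grp.promoter_elements, exon_blocks=blocks,
            utr5_len=200, utr3_len=300))
        for cond, spec in (("wt", grp.wt), ("mut", grp.mut)):
            for k in range(spec.n_nucleosomes):
                anchor = tss + sign * (spec.plus_one + k * spec.nrl)
                emit_gauss(cond, anchor, spec.fuzz_sd, spec.occupancy)
        if grp.active:
            if strand == "+":
                h3k4me3.data[chrom][tss:tss + 500] = 1.0
            else:
                h3k4me3.data[chrom][tss - 499:tss + 1] = 1.0
        gene_rows.append({
            "gene_id": f"{grp.name}_{i:04d}", "group": grp.name, "chrom": chrom,
            "tss": tss, "tts": tts, "strand": strand, "active": grp.active,
            "quintile": grp.quintile, "expression": expression,
            "wt_plus_one": grp.wt.plus_one, "wt_nrl": grp.wt.nrl,
            "mut_plus_one": grp.mut.plus_one, "mut_nrl": grp.mut.nrl})

    # ---- sites
    for grp, summit, i in site_slots:
        side = int(rng.choice([-1, 1]))
        reads = {}
        for label, level in grp.cofactor_levels.items():
            if level == "high":
                reads[label] = int(rng.integers(60, 200))
            else:
                reads[label] = int(rng.integers(0, 50))
        site_id = f"{grp.name}_{i:04d}"
        sites.append(Site(chrom=chrom, summit=summit, factor=grp.factor,
                          summit_reads=reads, site_id=site_id))
        if "CP190" in reads:
            lo, hi = max(0, summit - 50), min(length, summit + 50)
            cp190.data[chrom][lo:hi] = float(reads["CP190"])
        for cond, spec in (("wt", grp.wt), ("mut", grp.mut)):
            span = spec.span
            if spec.positioned_offset is not None:
                emit_gauss(cond, summit + side * spec.positioned_offset,
                           spec.positioned_fuzz, spec.positioned_occ)
            if spec.ambient_rate > 0:
                emit_uniform(cond, summit - span, summit + span,
                             spec.ambient_rate * 2 * span)
            if spec.ndr_fill_rate > 0 and spec.ndr_halfwidth > 0:
                emit_uniform(cond, summit - spec.ndr_halfwidth,
                             summit + spec.ndr_halfwidth,
                             spec.ndr_fill_rate * 2 * spec.ndr_halfwidth)
            first = spec.ndr_halfwidth + NUC_HALFWIDTH
            if spec.flank_mode == "phased":
                for s in (-1, 1):
                    for k in range(spec.flank_n):
                        anchor = summit + s * (first + k * spec.flank_nrl)
                        emit_gauss(cond, anchor, spec.flank_fuzz, spec.flank_occ)
            elif spec.flank_mode == "uniform":
                for s in (-1, 1):
                    a = summit + (first if s > 0 else -span)
                    b = summit + (span if s > 0 else -first)
                    emit_uniform(cond, a, b, spec.flank_rate * (b - a))
        site_rows.append({
            "site_id": site_id, "group": grp.name, "chrom": chrom,
            "summit": summit, "class_label": grp.wt.class_label,
            "factor": grp.factor,
            "wt_ndr_halfwidth": grp.wt.ndr_halfwidth,
            "mut_ndr_halfwidth": grp.mut.ndr_halfwidth})

    # ---- genome-wide background (same expected count in both conditions)
    n_signal = int(np.mean([sum(a.size for a in dyads[c]) for c in CONDITIONS]))
    if config.background_frac > 0 and n_signal > 0:
        n_bg = int(round(config.background_frac / (1 - config.background_frac)
                         * n_signal))
        for cond in CONDITIONS:
            emit_uniform(cond, 0, length, n_bg / config.depth)

    # ---- dyads -> fragments
    fragments: dict[str, list[GenomicInterval]] = {}
    for cond in CONDITIONS:
        if dyads[cond]:
            d = np.concatenate(dyads[cond])
        else:
            d = np.zeros(0, dtype=np.int64)
        lens = _truncnorm_lengths(rng, d.size, config.frag_len_mean,
                                  config.frag_len_sd, config.frag_len_bounds)
        starts = d - lens // 2
        ends = starts + lens
        ok = (starts >= 0) & (ends <= length)
        fragments[cond] = [GenomicInterval(chrom, int(s), int(e))
                           for s, e in zip(starts[ok], ends[ok])]

    truth = GroundTruth(
        genes=pd.DataFrame(gene_rows), sites=pd.DataFrame(site_rows),
        components=components, chrom_sizes=chrom_sizes, chrom=chrom)
    return SimBundle(config=config, chrom_sizes=chrom_sizes, fragments=fragments,
                     annotations=annotations, sites=sites,
                     tracks={"H3K4me3": h3k4me3, "CP190": cp190}, truth=truth)
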
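"""Readers and writers for the plain-text formats the pipeline touches.

BED (fragments, shift regions), bedGraph (densities, ChIP signals) and TSV
(annotations, sites, reports). All downstream modules consume the in-memory
types from :mod:`nucshift.genome`; nothing else reads files directly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import (ChromSizes, GeneAnnotation, GenomicInterval,
                     PROMOTER_ELEMENTS, SignalTrack, Site)

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("gene_id", "chrom", "tss", "tts", "strand",
                      "expression", "promoter_elements")


def read_fragments_bed(path, chrom_sizes: ChromSizes,
                       on_unknown_chrom: str = "skip") -> list[GenomicInterval]:
    """Read 3+ column BED fragments, validated against ``chrom_sizes``.

    Malformed lines raise a parse error naming the line number. Records on
    unknown chromosomes are skipped with a warning (``on_unknown_chrom="skip"``)
    or raise (``"fail"``). Out-of-bounds records are rejected and counted.
    """
    if on_unknown_chrom not in ("skip", "fail"):
        raise ValueError("on_unknown_chrom must be 'skip' or 'fail'")
    intervals: list[GenomicInterval] = []
    n_unknown = n_oob = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            if chrom not in chrom_sizes:
                if on_unknown_chrom == "fail":
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                n_unknown += 1
                continue
            if end > chrom_sizes[chrom]:
                n_oob += 1
                continue
            intervals.append(GenomicInterval(chrom, start, end, strand))
    if n_unknown:
        log.warning("%s: skipped %d records on unknown chromosomes", path, n_unknown)
    if n_oob:
        log.warning("%s: rejected %d out-of-bounds records", path, n_oob)
    return intervals


def write_fragments_bed(fragments, path) -> None:
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\n")


def _parse_exon_blocks(text: str):
    if not text or text in (".", "nan"):
        return None
    blocks = []
    for part in text.split(";"):
        s, e = part.split("-")
        blocks.append((int(s), int(e)))
    return tuple(sorted(blocks))


def _format_exon_blocks(blocks) -> str:
    if not blocks:
        return "."
    return ";".join(f"{s}-{e}" for s, e in blocks)


def read_annotations(path) -> list[GeneAnnotation]:
    """Read the gene-annotation TSV.

    Required columns: gene_id, chrom, tss, tts, strand, expression,
    promoter_elements (comma-joined labels, empty allowed). Optional:
    active, exon_blocks ("start-end;start-end"), utr5_len, utr3_len.
    """
    df = pd.read_csv(path, sep="\t", dtype={"promoter_elements": str,
                                            "exon_blocks": str})
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    genes = []
    for row in df.itertuples(index=False):
        raw = getattr(row, "promoter_elements", "")
        raw = "" if (pd.isna(raw) or raw == ".") else str(raw)
        labels = frozenset(x for x in raw.split(",") if x)
        bad = labels - PROMOTER_ELEMENTS
        if bad:
            raise ValueError(f"{path}: gene {row.gene_id}: unknown promoter "
                             f"element(s) {sorted(bad)}")
        active = getattr(row, "active", None)
        if active is not None and not pd.isna(active):
            active = bool(int(active))
        else:
            active = None
        genes.append(GeneAnnotation(
            gene_id=str(row.gene_id), chrom=str(row.chrom),
            tss=int(row.tss), tts=int(row.tts), strand=str(row.strand),
            expression=float(row.expression), active=active,
            promoter_elements=labels,
            exon_blocks=_parse_exon_blocks(str(getattr(row, "exon_blocks", ""))),
            utr5_len=int(getattr(row, "utr5_len", 0) or 0),
            utr3_len=int(getattr(row, "utr3_len", 0) or 0),
        ))
    return genes


def write_annotations(genes, path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss, "tts": g.tts,
            "strand": g.strand, "expression": g.expression,
            "active": "" if g.active is None else int(g.active),
            "promoter_elements": ",".join(sorted(g.promoter_elements)),
            "exon_blocks": _format_exon_blocks(g.exon_blocks),
            "utr5_len": g.utr5_len, "utr3_len": g.utr3_len,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites(path) -> list[Site]:
    """Read a site TSV: site_id, chrom, summit, factor, plus reads_<label> columns."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "summit", "factor"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    read_cols = [c for c in df.columns if c.startswith("reads_")]
    sites = []
    for i, row in enumerate(df.itertuples(index=False)):
        reads = {c[len("reads_"):]: int(getattr(row, c)) for c in read_cols}
        sites.append(Site(chrom=str(row.chrom), summit=int(row.summit),
                          factor=str(row.factor), summit_reads=reads,
                          site_id=str(getattr(row, "site_id", i))))
    return sites


def write_sites(sites, path) -> None:
    labels = sorted({k for s in sites for k in s.summit_reads})
    rows = []
    for s in sites:
        row = {"site_id": s.site_id, "chrom": s.chrom, "summit": s.summit,
               "factor": s.factor}
        for lab in labels:
            row[f"reads_{lab}"] = s.summit_reads.get(lab, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bedgraph(path, chrom_sizes: ChromSizes, label: str = "") -> SignalTrack:
    """Read a bedGraph into a dense SignalTrack; uncovered bp are 0.

    Overlapping records are an error.
    """
    track = SignalTrack(chrom_sizes, label=label)
    covered: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or start >= end or end > chrom_sizes[chrom]:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            covered.setdefault(chrom, []).append((start, end))
            track.data[chrom][start:end] = value
    for chrom, spans in covered.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"{path}: overlapping records on {chrom} "
                                 f"({s1}-{e1} and {s2}-{e2})")
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a SignalTrack as bedGraph, run-length encoding equal values.

    Zero runs are omitted; values are printed with 17 significant digits so
    a read(write(t)) round trip is value-exact.
    """
    with open(path, "w") as fh:
        for chrom in track.chrom_sizes:
            arr = track.data[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")
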
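"""Genomic interval arithmetic and ChIP signal quantification.

All coordinates are 0-based, half-open (BED convention); GFF3 input is
converted on read.  A coverage track is a per-chromosome list of sorted,
non-overlapping scored intervals whose score is read depth per base under
the convention that one read contributes one score unit over one base, so
the integral of score over a region is a read count and reads-per-million
(RPM) / reads-per-kilobase-per-million (RPKM) normalizations apply
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import pdist

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "CoverageTrack",
    "promoter_windows",
    "intersect_intervals",
    "map_peaks_to_genes",
    "region_signal",
    "summit_matrix",
    "read_bed",
    "write_bed",
    "read_peaks",
    "write_peaks",
    "read_gff3_genes",
]

_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class Peak:
    """A peak interval with its summit as an offset from ``start``."""

    chrom: str
    start: int
    end: int
    summit: int  # offset within the interval
    name: str = ""
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid peak [{self.start}, {self.end})")
        if not (self.start <= self.start + self.summit < self.end):
            raise ValueError(
                f"summit offset {self.summit} outside peak [{self.start}, {self.end})"
            )

    @property
    def summit_pos(self) -> int:
        return self.start + self.summit


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...]

    @classmethod
    def build(cls, peaks: Iterable[Peak]) -> "PeakSet":
        return cls(tuple(sorted(peaks)))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def gene_symbols(self) -> set[str]:
        return {p.gene_symbol for p in self.peaks if p.gene_symbol}


class CoverageTrack:
    """Sorted non-overlapping scored intervals per chromosome plus a read total.

    ``data`` maps chrom -> (starts, ends, scores) arrays.  ``total_reads``
    normalizes RPM/RPKM; when not given it is inferred as the integral of
    score over all bases (exact for point-read tracks).
    """

    def __init__(
        self,
        data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_reads: float | None = None,
    ) -> None:
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        total_mass = 0.0
        for chrom in sorted(data):
            starts, ends, scores = (np.asarray(a, dtype=float) for a in data[chrom])
            order = np.argsort(starts, kind="stable")
            starts, ends, scores = starts[order], ends[order], scores[order]
            if np.any(scores < 0):
                raise ValueError(f"negative coverage scores on {chrom}")
            if np.any(starts >= ends):
                raise ValueError(f"empty or inverted coverage interval on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping coverage intervals on {chrom}")
            self.data[chrom] = (starts, ends, scores)
            total_mass += float(np.sum(scores * (ends - starts)))
        self.total_reads = float(total_reads) if total_reads is not None else total_mass

    @classmethod
    def from_reads(cls, positions: Mapping[str, Sequence[int]]) -> "CoverageTrack":
        """Build a track from per-chromosome 1-bp read positions."""
        data = {}
        n = 0
        for chrom, pos in positions.items():
            pos = np.asarray(pos, dtype=int)
            if pos.size == 0:
                continue
            uniq, counts = np.unique(pos, return_counts=True)
            data[chrom] = (uniq, uniq + 1, counts.astype(float))
            n += int(pos.size)
        return cls(data, total_reads=n)

    def _integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Score mass accumulated on ``chrom`` left of each position."""
        starts, ends, scores = self.data[chrom]
        seglen = ends - starts
        cum = np.concatenate([[0.0], np.cumsum(scores * seglen)])
        pos = np.asarray(pos, dtype=float)
        j = np.searchsorted(starts, pos, side="right")  # intervals with start < pos
        out = cum[np.maximum(j - 1, 0)]
        last = np.maximum(j - 1, 0)
        frac = np.clip(pos - starts[last], 0.0, seglen[last]) * scores[last]
        return np.where(j > 0, out + frac, 0.0)

    def raw_signal(self, chrom: str, start: float, end: float) -> float:
        if chrom not in self.data:
            return 0.0
        lo, hi = self._integral(chrom, np.array([start, end]))
        return float(hi - lo)

    def to_bedgraph(self, path: str | Path) -> None:
        lines = []
        for chrom in sorted(self.data):
            starts, ends, scores = self.data[chrom]
            for s, e, v in zip(starts, ends, scores):
                lines.append(f"{chrom}\t{int(s)}\t{int(e)}\t{v:g}")
        Path(path).write_text(
            "".join(s + "\n" for s in lines), encoding="utf-8", newline="\n"
        )

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, total_reads: float | None = None
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, v = line.split("\t")
            by_chrom.setdefault(chrom, []).append((int(s), int(e), float(v)))
        data = {
            chrom: tuple(np.array(col) for col in zip(*rows))
            for chrom, rows in by_chrom.items()
        }
        return cls(data, total_reads=total_reads)


def promoter_windows(
    genes: Iterable[GenomicInterval],
    upstream: int = 2000,
    downstream: int = 500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Strand-aware windows around each gene's transcription start site.

    For a + strand gene the TSS is ``start`` and the window is
    ``[tss - upstream, tss + downstream)``; for a - strand gene the TSS is
    ``end`` and upstream extends to the right.  Windows are clipped at 0
    and, when ``chrom_sizes`` is given, at the chromosome end.
    """
    if upstream < 0 or downstream < 0 or upstream + downstream <= 0:
        raise ValueError("window extents must be non-negative and non-empty")
    out = []
    for g in genes:
        if g.strand == "+":
            lo, hi = g.start - upstream, g.start + downstream
        elif g.strand == "-":
            lo, hi = g.end - downstream, g.end + upstream
        else:
            raise ValueError(f"gene {g.name!r} has no strand; promoter is undefined")
        lo = max(lo, 0)
        if chrom_sizes is not None and g.chrom in chrom_sizes:
            hi = min(hi, chrom_sizes[g.chrom])
        if hi > lo:
            out.append(GenomicInterval(g.chrom, lo, hi, g.strand, g.name))
    return sorted(out)


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All overlapping (a, b) pairs with their overlap lengths in bp.

    Half-open semantics: abutting intervals ([0,5) and [5,10)) do not
    overlap.  Sweep line over the sorted start/end events per chromosome;
    output sorted by (chrom, a.start, a.end, b.start, b.end).
    """
    a, b = list(a), list(b)
    by_chrom: dict[str, tuple[list, list]] = {}
    for which, ivs in ((0, a), (1, b)):
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, ([], []))[which].append(iv)
    pairs: list[tuple[GenomicInterval, GenomicInterval, int]] = []
    for chrom in sorted(by_chrom):
        ca, cb = by_chrom[chrom]
        # events: (pos, kind) with ends (kind 0) processed before starts (kind 1)
        events: list[tuple[int, int, int, int]] = []
        for idx, iv in enumerate(ca):
            events.append((iv.start, 1, 0, idx))
            events.append((iv.end, 0, 0, idx))
        for idx, iv in enumerate(cb):
            events.append((iv.start, 1, 1, idx))
            events.append((iv.end, 0, 1, idx))
        events.sort(key=lambda e: (e[0], e[1]))
        active: tuple[dict[int, GenomicInterval], dict[int, GenomicInterval]] = ({}, {})
        for pos, kind, which, idx in events:
            iv = (ca, cb)[which][idx]
            if kind == 0:
                active[which].pop(idx, None)
                continue
            for other in active[1 - which].values():
                ai, bi = (iv, other) if which == 0 else (other, iv)
                ov = min(ai.end, bi.end) - max(ai.start, bi.start)
                pairs.append((ai, bi, ov))
            active[which][idx] = iv
    pairs.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1].start, t[1].end,
                              t[0].name, t[1].name))
    return pairs


def map_peaks_to_genes(
    peaks: PeakSet,
    genes: Iterable[GenomicInterval],
    mode: str = "interval",
    upstream: int = 2000,
    downstream: int = 500,
) -> dict[str, list[Peak]]:
    """Assign peaks to genes, by annotated symbol or by summit position.

    ``symbol`` mode joins each peak's ``gene_symbol`` annotation to the
    gene names, case-normalized.  ``interval`` mode assigns a peak to every
    gene whose promoter window (strand-aware, ``upstream``/``downstream``
    around the TSS) contains the peak summit; overlapping windows all
    receive the peak — there is no tie-break.  Returns gene -> sorted
    peaks, genes in sorted order.
    """
    genes = list(genes)
    result: dict[str, list[Peak]] = {}
    if mode == "symbol":
        unannotated = [p for p in peaks if p.gene_symbol is None]
        if unannotated:
            raise ValueError(
                f"{len(unannotated)} peaks lack gene_symbol annotations; "
                "use mode='interval' to assign peaks by summit position"
            )
        by_symbol: dict[str, list[Peak]] = {}
        for p in peaks:
            by_symbol.setdefault(p.gene_symbol.strip().upper(), []).append(p)
        for g in genes:
            hit = by_symbol.get(g.name.strip().upper())
            if hit:
                result[g.name] = sorted(hit)
    elif mode == "interval":
        windows = promoter_windows(genes, upstream=upstream, downstream=downstream)
        summits = [
            GenomicInterval(p.chrom, p.summit_pos, p.summit_pos + 1, ".", str(i))
            for i, p in enumerate(peaks)
        ]
        for w, s, _ in intersect_intervals(windows, summits):
            result.setdefault(w.name, []).append(peaks.peaks[int(s.name)])
        for gname in result:
            result[gname] = sorted(set(result[gname]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return dict(sorted(result.items()))


def region_signal(
    track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    norm: str = "rpm",
) -> np.ndarray:
    """Per-region signal: raw read count, RPM, or RPKM.

    raw = integral of coverage score over the region; rpm = raw * 1e6 /
    total_reads; rpkm = rpm * 1e3 / region length.  A region on a
    chromosome absent from the track scores 0 with a warning.
    """
    if norm not in ("raw", "rpm", "rpkm"):
        raise ValueError(f"unknown normalization {norm!r}")
    if norm != "raw" and not track.total_reads > 0:
        raise ValueError("total_reads must be positive for rpm/rpkm")
    missing = sorted({r.chrom for r in regions if r.chrom not in track.data})
    if missing:
        warnings.warn(f"regions on chromosomes absent from the track: {missing}")
    vals = np.array([track.raw_signal(r.chrom, r.start, r.end) for r in regions])
    if norm == "raw":
        return vals
    rpm = vals * 1e6 / track.total_reads
    if norm == "rpm":
        return rpm
    lengths = np.array([len(r) for r in regions], dtype=float)
    return rpm * 1e3 / lengths


def summit_matrix(
    track: CoverageTrack,
    peaks: PeakSet,
    flank: int = 5000,
    n_bins: int = 100,
    norm: str = "rpkm",
    order: str = "none",
) -> tuple[np.ndarray, np.ndarray]:
    """Signal matrix over summit-centered windows (summit +/- flank, binned).

    Each row is one peak: the window ``[summit - flank, summit + flank)``
    split into ``n_bins`` equal bins, each normalized per ``norm`` (as in
    :func:`region_signal`, with the bin as the region).  Windows running
    off the chromosome are zero-padded with a warning.  ``order`` is
    ``none`` (input peak order) or ``hierarchical`` (average-linkage
    euclidean leaf order).  Returns (matrix, row_order) with rows already
    permuted into ``row_order``.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if n_bins < 1 or n_bins % 2:
        raise ValueError("n_bins must be a positive even number")
    if norm not in ("raw", "rpm", "rpkm"):
        raise ValueError(f"unknown normalization {norm!r}")
    bin_len = 2.0 * flank / n_bins
    mat = np.zeros((len(peaks), n_bins))
    clipped = 0
    for i, p in enumerate(peaks):
        lo = p.summit_pos - flank
        if lo < 0:
            clipped += 1
        if p.chrom not in track.data:
            continue
        edges = lo + bin_len * np.arange(n_bins + 1)
        cum = track._integral(p.chrom, np.clip(edges, 0, None))
        mat[i] = np.diff(cum)
    if clipped:
        warnings.warn(
            f"{clipped} summit windows extend past the chromosome start; zero-padded"
        )
    if norm in ("rpm", "rpkm"):
        if not track.total_reads > 0:
            raise ValueError("total_reads must be positive for rpm/rpkm")
        mat = mat * 1e6 / track.total_reads
        if norm == "rpkm":
            mat = mat * 1e3 / bin_len
    row_order = np.arange(len(peaks))
    if order == "hierarchical" and len(peaks) > 2:
        row_order = np.asarray(leaves_list(scipy_linkage(pdist(mat), method="average")))
    elif order not in ("none", "hierarchical"):
        raise ValueError(f"unknown row order {order!r}")
    return mat[row_order], row_order


# ---------------------------------------------------------------------------
# plain-text I/O: BED, BED6+summit, GFF3


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/6/12 intervals (name from column 4, strand from column 6)."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        name = f[3] if len(f) > 3 else ""
        strand = f[5] if len(f) > 5 else "."
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    lines = [
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}"
        for iv in intervals
    ]
    Path(path).write_text("".join(s + "\n" for s in lines), encoding="utf-8", newline="\n")


def read_peaks(path: str | Path) -> PeakSet:
    """Read BED6+summit peaks: column 7 = summit offset, column 8 = gene symbol."""
    peaks = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 7:
            raise ValueError("peak BED needs >= 7 columns (BED6 + summit offset)")
        symbol = f[7] if len(f) > 7 and f[7] not in (".", "") else None
        peaks.append(
            Peak(f[0], int(f[1]), int(f[2]), int(f[6]), name=f[3], gene_symbol=symbol)
        )
    return PeakSet.build(peaks)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    lines = [
        f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t0\t.\t{p.summit}"
        f"\t{p.gene_symbol or '.'}"
        for p in peaks
    ]
    Path(path).write_text("".join(s + "\n" for s in lines), encoding="utf-8", newline="\n")


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> list[GenomicInterval]:
    """Read gene records from GFF3, converting 1-based closed to 0-based half-open."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != feature_type:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        name = attrs.get("Name") or attrs.get("ID") or attrs.get("gene_id") or ""
        out.append(GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6], name))
    return out
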
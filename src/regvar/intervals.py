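"""Genomic interval model and arithmetic for regulatory tracks.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
A :class:`RegulatoryTrack` is a *merged* set of intervals for one regulatory
element type (promoter, enhancer, insulator, ...): after construction no two
intervals on the same chromosome overlap or abut, so ``total_length`` is the
size of the per-basepair union — the quantity that track-length and
track-overlap statistics are defined on.

The seven genomic region classes (coding exon, 5'UTR, 3'UTR, intron,
upstream/downstream flanks, intergenic) are derived from gene models by
:func:`build_genome_partition`.  The classes deliberately may overlap each
other (a bp can be exonic in one transcript and intronic in another);
only the intergenic class is defined by complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

GENOMIC_CLASSES = (
    "coding_exon",
    "utr5",
    "utr3",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)

DEFAULT_FLANK = 2000


class BedParseError(ValueError):
    """A malformed record in a BED-like file; carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def normalize_chrom(chrom: str, add_prefix: bool = True) -> str:
    """Normalise a chromosome name; by default add a ``chr`` prefix if absent."""
    chrom = chrom.strip()
    if add_prefix and not chrom.startswith("chr"):
        return "chr" + chrom
    return chrom


class RegulatoryTrack:
    """A named, merged, sorted set of genomic intervals.

    Internally stores per-chromosome sorted ``starts``/``ends`` arrays so that
    point-membership queries vectorise with ``searchsorted``.
    """

    def __init__(self, label: str, merged: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        # `merged` must already satisfy the merged-track invariant; use
        # `from_intervals` for arbitrary input.
        self.label = label
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in sorted(merged.items())
            if len(s)
        }

    # -- construction ------------------------------------------------------

    @classmethod
    def from_intervals(
        cls, label: str, intervals: Iterable[GenomicInterval]
    ) -> "RegulatoryTrack":
        """Build a merged track from arbitrary (possibly overlapping) intervals.

        Overlapping and abutting intervals are fused, so the resulting
        ``total_length`` equals the size of the per-bp union of the input.
        """
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            starts: list[int] = []
            ends: list[int] = []
            for s, e in spans:
                if ends and s <= ends[-1]:  # overlap or abutment
                    if e > ends[-1]:
                        ends[-1] = e
                else:
                    starts.append(s)
                    ends.append(e)
            merged[chrom] = (np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64))
        return cls(label, merged)

    @classmethod
    def empty(cls, label: str) -> "RegulatoryTrack":
        return cls(label, {})

    # -- accessors ---------------------------------------------------------

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._by_chrom)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (starts, ends) for one chromosome (empty arrays if absent)."""
        if chrom in self._by_chrom:
            return self._by_chrom[chrom]
        z = np.empty(0, dtype=np.int64)
        return z, z

    @property
    def intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom, (starts, ends) in self._by_chrom.items():
            out.extend(
                GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
            )
        return out

    @property
    def total_length(self) -> int:
        return int(
            sum((e - s).sum() for s, e in self._by_chrom.values())
        )

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self._by_chrom.values())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RegulatoryTrack({self.label!r}, n_intervals={len(self)}, "
            f"total_length={self.total_length})"
        )

    # -- queries -----------------------------------------------------------

    def contains_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised point membership for 0-based positions on one chromosome."""
        positions = np.asarray(positions, dtype=np.int64)
        starts, ends = self.arrays(chrom)
        if not len(starts):
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        member = np.zeros(positions.shape, dtype=bool)
        member[ok] = positions[ok] < ends[idx[ok]]
        return member

    def contains(self, chrom: str, position: int) -> bool:
        return bool(self.contains_positions(chrom, np.array([position]))[0])

    # -- output ------------------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        """Re-emit the merged track as BED3."""
        with open(path, "w") as fh:
            for chrom, (starts, ends) in self._by_chrom.items():
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\n")


@dataclass(frozen=True)
class GeneModel:
    """Minimal transcript-level gene model used to derive genomic classes.

    ``exons`` and ``cds`` are 0-based half-open spans on ``chrom``; ``cds``
    spans are contained in exons.  Unstranded records default to ``+``
    (a warning is logged by the reader).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("invalid gene span")


@dataclass
class GenomePartition:
    """The seven genomic region classes, each a merged track.

    Classes are *not* mutually exclusive; together they cover every bp of
    every chromosome (intergenic is the complement of gene spans plus flanks).
    """

    classes: dict[str, RegulatoryTrack]

    def __getitem__(self, name: str) -> RegulatoryTrack:
        return self.classes[name]

    def items(self):
        return self.classes.items()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path, add_chr_prefix: bool = True) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            sizes[normalize_chrom(parts[0], add_chr_prefix)] = int(parts[1])
    return sizes


def read_bed(
    path: str | Path, label: str | None = None, add_chr_prefix: bool = True
) -> RegulatoryTrack:
    """Read a BED3+ file into a merged, sorted :class:`RegulatoryTrack`.

    Records with ``end <= start`` are rejected with the offending line number.
    """
    path = Path(path)
    label = label if label is not None else path.stem
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: malformed coordinate: {exc}"
                ) from None
            if end <= start or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid span [{start}, {end})"
                )
            intervals.append(
                GenomicInterval(normalize_chrom(parts[0], add_chr_prefix), start, end)
            )
    return RegulatoryTrack.from_intervals(label, intervals)


def read_gene_models(path: str | Path, add_chr_prefix: bool = True) -> list[GeneModel]:
    """Read transcript gene models from GFF3 (via :mod:`gffutils`).

    One :class:`GeneModel` is produced per ``gene`` feature, with exons and
    CDS pooled over its transcripts.  Unstranded genes default to ``+`` with
    a logged warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        strand = g.strand if g.strand in ("+", "-") else None
        if strand is None:
            logger.warning("gene %s is unstranded; defaulting to + strand", g.id)
            strand = "+"
        exons = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(g, featuretype="exon")
            )
        )
        cds = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(g, featuretype="CDS")
            )
        )
        if not exons:  # gene without exon children: treat whole span as exonic
            exons = ((g.start - 1, g.end),)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=normalize_chrom(g.seqid, add_chr_prefix),
                start=g.start - 1,
                end=g.end,
                strand=strand,
                exons=exons,
                cds=cds,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------


def merge_track(
    intervals: Iterable[GenomicInterval], label: str = "merged"
) -> RegulatoryTrack:
    """Merge arbitrary intervals into a track (idempotent; abutting spans fuse)."""
    return RegulatoryTrack.from_intervals(label, intervals)


def _intersect_arrays(
    s1: np.ndarray, e1: np.ndarray, s2: np.ndarray, e2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Intersect two merged interval lists on one chromosome (two-pointer)."""
    out_s: list[int] = []
    out_e: list[int] = []
    i = j = 0
    while i < len(s1) and j < len(s2):
        lo = max(s1[i], s2[j])
        hi = min(e1[i], e2[j])
        if lo < hi:
            out_s.append(int(lo))
            out_e.append(int(hi))
        if e1[i] < e2[j]:
            i += 1
        else:
            j += 1
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def intersect_tracks(
    a: RegulatoryTrack, b: RegulatoryTrack, label: str | None = None
) -> RegulatoryTrack:
    """Per-bp intersection of two merged tracks, as a new merged track."""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in a.chroms:
        if chrom not in b.chroms:
            continue
        s1, e1 = a.arrays(chrom)
        s2, e2 = b.arrays(chrom)
        s, e = _intersect_arrays(s1, e1, s2, e2)
        if len(s):
            merged[chrom] = (s, e)
    return RegulatoryTrack(label or f"{a.label}&{b.label}", merged)


def overlap_length(a: RegulatoryTrack, b: RegulatoryTrack) -> int:
    """Total bp in the intersection of two merged tracks (symmetric)."""
    return intersect_tracks(a, b).total_length


def complement_track(
    track: RegulatoryTrack, chrom_sizes: Mapping[str, int], label: str = "complement"
) -> RegulatoryTrack:
    """Genome minus track, over the chromosomes in ``chrom_sizes``."""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, size in chrom_sizes.items():
        starts, ends = track.arrays(chrom)
        cs: list[int] = []
        ce: list[int] = []
        prev = 0
        for s, e in zip(starts, ends):
            s = int(s)
            if s > prev:
                cs.append(prev)
                ce.append(min(s, size))
            prev = max(prev, int(e))
        if prev < size:
            cs.append(prev)
            ce.append(size)
        if cs:
            merged[chrom] = (np.array(cs, dtype=np.int64), np.array(ce, dtype=np.int64))
    return RegulatoryTrack(label, merged)


def percent_overlap(overlap_bp: int, track_length: int, decimals: int = 2) -> float:
    """Overlap as a percentage of the track length, to ``decimals`` places."""
    if track_length <= 0:
        raise ValueError("track_length must be > 0 for a percentage")
    return round(100.0 * overlap_bp / track_length, decimals)


# ---------------------------------------------------------------------------
# genome partition
# ---------------------------------------------------------------------------


def build_genome_partition(
    gene_models: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    flank: int = DEFAULT_FLANK,
) -> GenomePartition:
    """Derive the seven genomic region classes from gene models.

    * ``upstream``/``downstream`` are strand-aware ``flank``-bp gene flanks,
      clipped at chromosome bounds.
    * ``intron`` is the transcript span minus its exons.
    * ``utr5``/``utr3`` are the exonic bp 5' / 3' of the CDS span
      (strand-aware); genes without CDS contribute no UTR or coding exon.
    * ``intergenic`` is the complement of gene spans plus both flanks.

    The non-intergenic classes are computed per gene independently and may
    overlap across (or within) genes; no precedence is applied.
    """
    buckets: dict[str, list[GenomicInterval]] = {name: [] for name in GENOMIC_CLASSES}
    footprint: list[GenomicInterval] = []  # gene spans with flanks, for complement

    def clip(chrom: str, s: int, e: int) -> tuple[int, int] | None:
        size = chrom_sizes.get(chrom)
        hi = size if size is not None else e
        s, e = max(0, s), min(e, hi)
        return (s, e) if s < e else None

    def add(name: str, chrom: str, s: int, e: int) -> None:
        span = clip(chrom, s, e)
        if span:
            buckets[name].append(GenomicInterval(chrom, *span))

    for g in gene_models:
        for s, e in g.cds:
            add("coding_exon", g.chrom, s, e)
        # introns: transcript span minus exon union
        exon_union = RegulatoryTrack.from_intervals(
            "x", [GenomicInterval(g.chrom, s, e) for s, e in g.exons]
        )
        prev = g.start
        for iv in exon_union.intervals:
            if iv.start > prev:
                add("intron", g.chrom, prev, iv.start)
            prev = max(prev, iv.end)
        if prev < g.end:
            add("intron", g.chrom, prev, g.end)
        # UTRs: exonic bp outside the CDS span, sided by strand
        if g.cds:
            cds_lo = min(s for s, _ in g.cds)
            cds_hi = max(e for _, e in g.cds)
            for s, e in g.exons:
                left = (s, min(e, cds_lo))
                right = (max(s, cds_hi), e)
                five, three = (left, right) if g.strand == "+" else (right, left)
                if five[0] < five[1]:
                    add("utr5", g.chrom, *five)
                if three[0] < three[1]:
                    add("utr3", g.chrom, *three)
        # flanks
        if g.strand == "+":
            add("upstream", g.chrom, g.start - flank, g.start)
            add("downstream", g.chrom, g.end, g.end + flank)
        else:
            add("upstream", g.chrom, g.end, g.end + flank)
            add("downstream", g.chrom, g.start - flank, g.start)
        span = clip(g.chrom, g.start - flank, g.end + flank)
        if span:
            footprint.append(GenomicInterval(g.chrom, *span))

    classes = {
        name: RegulatoryTrack.from_intervals(name, ivs)
        for name, ivs in buckets.items()
        if name != "intergenic"
    }
    classes["intergenic"] = complement_track(
        RegulatoryTrack.from_intervals("footprint", footprint),
        chrom_sizes,
        label="intergenic",
    )
    return GenomePartition(classes)
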
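"""Variant data model, readers, and set arithmetic.

A variant is a point substitution/indel keyed by ``(chrom, pos, ref, alt)``
with a disease-category label, optional alternate-allele frequency, optional
coding flag, optional Sequence Ontology consequence term, and a free-form
map of annotation scores (GWAVA, CADD, GERP, Mutation Assessor ... consumed
as inputs, never computed here).

Interval membership downstream is tested on the position alone (1-based
``pos`` converted to 0-based), treating every variant as a point.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .intervals import RegulatoryTrack, normalize_chrom

logger = logging.getLogger(__name__)

# canonical category labels; user-defined labels are also accepted
MENDELIAN = "mendelian"
COMPLEX = "complex"
CANCER_GERMLINE = "cancer_germline"
CANCER_SOMATIC = "cancer_somatic"
BACKGROUND = "background"
CANONICAL_CATEGORIES = (MENDELIAN, COMPLEX, CANCER_GERMLINE, CANCER_SOMATIC)

VariantKey = tuple[str, int, str, str]


class SchemaError(ValueError):
    """Input table is missing a mandatory column."""


@dataclass
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: str | None = None
    category: str = BACKGROUND
    af: float | None = None
    coding: bool | None = None
    consequence: str | None = None
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError(f"af must be in [0, 1], got {self.af}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def pos0(self) -> int:
        """0-based position for interval membership."""
        return self.pos - 1


class VariantSet:
    """A labelled collection of variants, unique by (chrom, pos, ref, alt)."""

    def __init__(self, label: str, variants: Iterable[Variant] = ()):
        self.label = label
        self._variants: dict[VariantKey, Variant] = {}
        self._dupes_dropped = 0
        for v in variants:
            self.add(v)
        self._pos_cache: dict[str, np.ndarray] | None = None

    def add(self, v: Variant) -> None:
        if v.key in self._variants:
            self._dupes_dropped += 1
        else:
            self._variants[v.key] = v
        self._pos_cache = None

    def size(self) -> int:
        return len(self._variants)

    def __len__(self) -> int:
        return len(self._variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self._variants.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._variants

    def __getitem__(self, key: VariantKey) -> Variant:
        return self._variants[key]

    def keys(self) -> set[VariantKey]:
        return set(self._variants)

    @property
    def duplicates_dropped(self) -> int:
        return self._dupes_dropped

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"VariantSet({self.label!r}, n={len(self)})"

    # -- bulk views --------------------------------------------------------

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        """0-based positions grouped by chromosome, one entry per variant.

        Variants sharing a position (different alleles) each contribute an
        entry, so membership counts are per-variant, not per-site.
        """
        if self._pos_cache is None:
            grouped: dict[str, list[int]] = {}
            for v in self._variants.values():
                grouped.setdefault(v.chrom, []).append(v.pos0)
            self._pos_cache = {
                c: np.asarray(p, dtype=np.int64) for c, p in grouped.items()
            }
        return self._pos_cache

    def afs(self) -> np.ndarray:
        """Allele frequencies as a float array with NaN for missing."""
        return np.array(
            [v.af if v.af is not None else np.nan for v in self._variants.values()],
            dtype=float,
        )

    def in_track_mask(self, track: RegulatoryTrack) -> np.ndarray:
        """Boolean per-variant membership in iteration order."""
        mask = np.zeros(len(self), dtype=bool)
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for i, v in enumerate(self._variants.values()):
            idx, pos = by_chrom.setdefault(v.chrom, ([], []))
            idx.append(i)
            pos.append(v.pos0)
        for chrom, (idx, pos) in by_chrom.items():
            mask[np.asarray(idx)] = track.contains_positions(
                chrom, np.asarray(pos, dtype=np.int64)
            )
        return mask

    def filter(self, predicate, label: str | None = None) -> "VariantSet":
        return VariantSet(label or self.label, (v for v in self if predicate(v)))

    def noncoding(self, label: str | None = None) -> "VariantSet":
        """Subset with coding flag explicitly False."""
        return self.filter(lambda v: v.coding is False, label or f"{self.label}_noncoding")

    # -- output ------------------------------------------------------------

    def to_tsv(self, path: str | Path, score_names: tuple[str, ...] | None = None) -> None:
        if score_names is None:  # auto-detect every score present in the set
            score_names = tuple(sorted({s for v in self for s in v.scores}))
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            header = ["chrom", "pos", "ref", "alt", "id", "category", "af",
                      "coding", "consequence", *score_names]
            w.writerow(header)
            for v in self:
                row = [
                    v.chrom, v.pos, v.ref, v.alt,
                    v.id or ".",
                    v.category,
                    "" if v.af is None else f"{v.af:.6g}",
                    "" if v.coding is None else int(v.coding),
                    v.consequence or "",
                ]
                row.extend(
                    "" if v.scores.get(s) is None else f"{v.scores[s]:.6g}"
                    for s in score_names
                )
                w.writerow(row)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_TSV_REQUIRED = ("chrom", "pos", "ref", "alt")
# `category` may appear in round-tripped files; the per-file label wins
_TSV_OPTIONAL = ("id", "af", "coding", "consequence", "category")


def _read_tsv(path: Path, category: str, add_chr_prefix: bool) -> Iterator[Variant]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        missing = [c for c in _TSV_REQUIRED if c not in cols]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
        score_cols = [c for c in cols if c not in _TSV_REQUIRED + _TSV_OPTIONAL]
        for lineno, row in enumerate(reader, 2):
            try:
                pos = int(row["pos"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}:{lineno}: non-numeric pos {row.get('pos')!r}"
                ) from None
            af = row.get("af")
            coding = row.get("coding")
            scores = {
                c: float(row[c]) for c in score_cols if row.get(c) not in (None, "", ".")
            }
            yield Variant(
                chrom=normalize_chrom(row["chrom"], add_chr_prefix),
                pos=pos,
                ref=row["ref"],
                alt=row["alt"],
                id=None if row.get("id") in (None, "", ".") else row["id"],
                category=category,
                af=None if af in (None, "", ".") else float(af),
                coding=None if coding in (None, "", ".") else bool(int(coding)),
                consequence=row.get("consequence") or None,
                scores=scores,
            )


def _read_vcf(
    path: Path, category: str, af_field: str, add_chr_prefix: bool
) -> Iterator[Variant]:
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            afs = rec.info.get(af_field)
            if afs is not None and not isinstance(afs, (tuple, list)):
                afs = (afs,)
            for i, alt in enumerate(rec.alts or ()):
                af = None
                if afs is not None and i < len(afs) and afs[i] is not None:
                    af = float(afs[i])
                yield Variant(
                    chrom=normalize_chrom(rec.chrom, add_chr_prefix),
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    id=rec.id,
                    category=category,
                    af=af,
                )


def read_variants(
    path: str | Path,
    format: str = "tsv",
    category: str = BACKGROUND,
    af_field: str = "AF",
    add_chr_prefix: bool = True,
) -> VariantSet:
    """Read a variant file into a :class:`VariantSet`.

    ``format='vcf'`` splits multi-allelic records into one variant per ALT and
    reads the allele frequency from the INFO field named ``af_field``.
    ``format='tsv'`` requires at least columns chrom, pos, ref, alt; extra
    numeric columns become annotation scores.  Duplicate keys are collapsed
    and the dropped count is logged.
    """
    path = Path(path)
    if format == "tsv":
        it = _read_tsv(path, category, add_chr_prefix)
    elif format == "vcf":
        it = _read_vcf(path, category, af_field, add_chr_prefix)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'vcf' or 'tsv')")
    vs = VariantSet(category, it)
    if vs.duplicates_dropped:
        logger.info(
            "%s: collapsed %d duplicate variant key(s)", path, vs.duplicates_dropped
        )
    return vs


# ---------------------------------------------------------------------------
# joins and set arithmetic
# ---------------------------------------------------------------------------


def join_allele_frequencies(
    vs: VariantSet, af_table: Mapping[VariantKey, float]
) -> VariantSet:
    """Attach allele frequencies by variant key; unmatched keep af missing."""
    matched = 0
    out = VariantSet(vs.label)
    for v in vs:
        af = af_table.get(v.key)
        if af is not None:
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency {af} outside [0, 1] for {v.key}")
            matched += 1
        out.add(
            Variant(
                v.chrom, v.pos, v.ref, v.alt, v.id, v.category,
                af if af is not None else v.af, v.coding, v.consequence,
                dict(v.scores),
            )
        )
    logger.info(
        "AF join on %s: %d matched, %d unmatched", vs.label, matched, len(vs) - matched
    )
    return out


def subtract(
    background: VariantSet, disease_sets: Iterable[VariantSet], label: str | None = None
) -> VariantSet:
    """Background minus the union of disease keys (the genome variant background).

    Mirrors the construction of a control panel as the full SNP catalogue with
    all disease-associated variants removed; inputs are not modified.
    """
    remove: set[VariantKey] = set()
    for ds in disease_sets:
        remove |= ds.keys()
    return VariantSet(
        label or background.label, (v for v in background if v.key not in remove)
    )


def flag_coding(vs: VariantSet, coding_track: RegulatoryTrack) -> VariantSet:
    """Set each variant's coding flag by membership in a coding-exon track."""
    mask = vs.in_track_mask(coding_track)
    out = VariantSet(vs.label)
    for v, coding in zip(vs, mask):
        out.add(
            Variant(
                v.chrom, v.pos, v.ref, v.alt, v.id, v.category, v.af,
                bool(coding), v.consequence, dict(v.scores),
            )
        )
    return out
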
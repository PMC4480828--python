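"""Variant densities and the regulatory × genomic-region overlap matrix.

DVPM — disease variants per one million base pairs of a regulatory track —
is ``1e6 * unique_variant_count / track_length``.  The overlap matrix gives,
for each regulatory track, the bp (and percentage of track length) shared
with each of the seven genomic region classes; rows can sum to more than
100% because the classes overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import math

import pandas as pd

from .intervals import (
    GENOMIC_CLASSES,
    GenomePartition,
    RegulatoryTrack,
    intersect_tracks,
    overlap_length,
    percent_overlap,
)
from .variants import VariantSet


@dataclass
class DensityResult:
    """One density-table row: per-class counts, unique total and DVPM for a track."""

    track_label: str
    per_class_variant_counts: dict[str, int]
    total_unique_variants: int
    track_length: int
    dvpm: float

    @property
    def dvpm_int(self) -> int:
        """Cosmetic integer DVPM (round half away from zero); float is canonical."""
        return int(math.floor(self.dvpm + 0.5)) if self.dvpm >= 0 else -int(
            math.floor(-self.dvpm + 0.5)
        )


@dataclass
class OverlapMatrix:
    rows: list[str]
    cols: list[str]
    bp: pd.DataFrame  # index=rows, columns=cols, int bp
    pct: pd.DataFrame  # same shape, percent of row track length

    def to_tsv(self, path: str | Path) -> None:
        combined = self.bp.astype(str) + " (" + self.pct.round(2).astype(str) + "%)"
        combined.to_csv(path, sep="\t", index_label="track")


def count_variants_in_track(vs: VariantSet, track: RegulatoryTrack) -> int:
    """Number of unique variants whose position lies inside the merged track."""
    total = 0
    for chrom, pos in vs.positions_by_chrom().items():
        total += int(track.contains_positions(chrom, pos).sum())
    return total


def dvpm(unique_count: int, track_length: int) -> float:
    """Disease variants per one million bp of track; track_length must be > 0."""
    if track_length <= 0:
        raise ValueError("track_length must be > 0 for a density")
    return 1e6 * unique_count / track_length


def round_half_away(x: float) -> int:
    """Integer DVPM reporting convention: round half away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def density_table(
    disease_sets: Sequence[VariantSet],
    tracks: Sequence[RegulatoryTrack],
    partition: GenomePartition,
) -> list[DensityResult]:
    """Per-track variant counts stratified by genomic class, plus DVPM.

    Per-class cells count variants lying in (track ∩ class); the total column
    deduplicates, counting each variant once even when it sits in several
    overlapping classes.  Disease sets are pooled over categories (a variant
    present in two sets under the same key counts once).
    """
    pooled = VariantSet("pooled_disease")
    for ds in disease_sets:
        for v in ds:
            if v.key not in pooled:
                pooled.add(v)

    out: list[DensityResult] = []
    for track in tracks:
        per_class: dict[str, int] = {}
        for name, cls_track in partition.items():
            per_class[name] = count_variants_in_track(
                pooled, intersect_tracks(track, cls_track)
            )
        total = count_variants_in_track(pooled, track)
        out.append(
            DensityResult(
                track_label=track.label,
                per_class_variant_counts=per_class,
                total_unique_variants=total,
                track_length=track.total_length,
                dvpm=dvpm(total, track.total_length) if track.total_length else 0.0,
            )
        )
    return out


def density_table_frame(results: Sequence[DensityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"track": r.track_label}
        row.update(r.per_class_variant_counts)
        row["total_unique"] = r.total_unique_variants
        row["track_length_bp"] = r.track_length
        row["dvpm"] = r.dvpm
        row["dvpm_int"] = round_half_away(r.dvpm)
        rows.append(row)
    return pd.DataFrame(rows)


def overlap_matrix(
    tracks: Sequence[RegulatoryTrack],
    partition: GenomePartition,
    cols: Sequence[str] = GENOMIC_CLASSES,
) -> OverlapMatrix:
    """bp and percent-of-track overlap for every (track, genomic class) pair."""
    row_labels = [t.label for t in tracks]
    bp_rows = []
    pct_rows = []
    for t in tracks:
        if t.total_length == 0:
            raise ValueError(f"track {t.label!r} has zero length")
        bps = {c: overlap_length(t, partition[c]) for c in cols}
        bp_rows.append(bps)
        pct_rows.append(
            {c: percent_overlap(bps[c], t.total_length, decimals=4) for c in cols}
        )
    return OverlapMatrix(
        rows=row_labels,
        cols=list(cols),
        bp=pd.DataFrame(bp_rows, index=row_labels),
        pct=pd.DataFrame(pct_rows, index=row_labels),
    )
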
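"""Allele-frequency-matched resampling null for enrichment odds ratios.

For each disease category: bin the disease set's allele frequencies, draw N
control sets from the background pool with *exactly* the same per-bin counts
(so each control group has the same size and AF distribution as the disease
set), compute the within/outside-track odds ratio and Pearson chi-squared p
for disease vs every control set, and summarise with the median OR, the
fraction of replicates significant at ``alpha``, and a Benjamini–Hochberg
q-value over the replicate p-values.

Variants with missing AF form their own matching stratum rather than being
dropped, which preserves the equal-size property of the control groups.

Reproducibility: one root seed; replicate ``i`` uses the numpy generator
seeded with the sequence ``[seed, i]``, so any replicate is reproducible in
isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .enrichment import chi2_batch
from .intervals import RegulatoryTrack
from .variants import Variant, VariantSet

#: Default AF bin edges: dense at the rare end, reflecting the rare-skewed
#: site-frequency spectra of disease variant sets.  A missing-AF stratum is
#: always added on top of these.
DEFAULT_AF_BIN_EDGES = (0.0, 0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 1.0)

MISSING_BIN = -1  # stratum index for variants without an AF


class CapacityError(ValueError):
    """The pool cannot supply a matched draw for some AF bin."""


@dataclass(frozen=True)
class AFHistogram:
    """Binned allele-frequency distribution plus a missing-AF stratum.

    Bin ``j`` covers ``[edges[j], edges[j+1])`` except the last, which is
    closed at 1.0 so an AF of exactly 1 is counted.
    """

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    missing: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing, length >= 2")
        if len(self.counts) != len(edges) - 1:
            raise ValueError("need one count per bin")

    @property
    def total(self) -> int:
        return int(sum(self.counts) + self.missing)


def _bin_indices(afs: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    """Bin index per AF (NaN → MISSING_BIN); AF == last edge goes in last bin."""
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, afs, side="right") - 1
    idx = np.where(np.asarray(afs) == edges[-1], len(edges) - 2, idx)
    idx = np.where(np.isnan(afs), MISSING_BIN, idx)
    out_of_range = (~np.isnan(afs)) & ((idx < 0) | (idx > len(edges) - 2))
    if np.any(out_of_range):
        bad = np.asarray(afs)[out_of_range][0]
        raise ValueError(f"allele frequency {bad} outside bin range {edges[0]}..{edges[-1]}")
    return idx.astype(np.int64)


def af_histogram(
    vs: VariantSet, edges: Sequence[float] = DEFAULT_AF_BIN_EDGES
) -> AFHistogram:
    """Histogram a set's allele frequencies; missing AFs get their own stratum."""
    afs = vs.afs()
    idx = _bin_indices(afs, edges)
    nbins = len(edges) - 1
    counts = np.bincount(idx[idx >= 0], minlength=nbins)
    return AFHistogram(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        missing=int((idx == MISSING_BIN).sum()),
    )


def _pool_bins(
    pool: VariantSet, edges: Sequence[float]
) -> tuple[list[Variant], dict[int, np.ndarray]]:
    """Pool variants in a stable order plus per-bin index arrays."""
    variants = list(pool)
    afs = np.array(
        [v.af if v.af is not None else np.nan for v in variants], dtype=float
    )
    idx = _bin_indices(afs, edges)
    by_bin = {
        int(b): np.flatnonzero(idx == b)
        for b in np.unique(idx)
    }
    return variants, by_bin


def _check_capacity(
    target: AFHistogram, by_bin: dict[int, np.ndarray]
) -> None:
    wanted = {MISSING_BIN: target.missing}
    wanted.update({j: c for j, c in enumerate(target.counts)})
    for b, need in wanted.items():
        have = len(by_bin.get(b, ()))
        if need > have:
            lo = "missing-AF" if b == MISSING_BIN else (
                f"[{target.bin_edges[b]}, {target.bin_edges[b + 1]})"
            )
            raise CapacityError(
                f"AF bin {lo}: need {need} control variants, pool has {have} "
                f"(shortfall {need - have})"
            )


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng([seed, replicate])


def _sample_indices(
    target: AFHistogram,
    by_bin: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """One matched draw: per-bin exact-quota sampling without replacement."""
    chunks = []
    quotas = [(MISSING_BIN, target.missing)] + [
        (j, c) for j, c in enumerate(target.counts)
    ]
    for b, need in quotas:
        if need == 0:
            continue
        chunks.append(rng.choice(by_bin[b], size=need, replace=False))
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(chunks)


def sample_matched_controls(
    pool: VariantSet,
    target: AFHistogram,
    n_sets: int,
    seed: int,
) -> Iterator[VariantSet]:
    """Yield ``n_sets`` AF-matched control sets drawn from ``pool``.

    Each set matches ``target`` bin-for-bin exactly (hence equal total size);
    sampling is without replacement within a set and independent across sets.
    Fully reproducible from ``seed``.
    """
    variants, by_bin = _pool_bins(pool, target.bin_edges)
    _check_capacity(target, by_bin)
    for i in range(n_sets):
        idx = _sample_indices(target, by_bin, _replicate_rng(seed, i))
        yield VariantSet(f"{pool.label}_matched_{i}", (variants[j] for j in idx))


@dataclass
class MatchedNullResult:
    """Summary of one disease set vs N matched control sets on one track."""

    track_label: str
    category_label: str
    n_replicates: int
    replicate_ors: list[float]
    replicate_ps: list[float]
    median_or: float  # median over finite replicate ORs (NaN if none finite)
    q: float
    significant_fraction: float
    n_nonfinite: int
    seed: int
    alpha: float = 0.05
    table_disease: tuple[int, int] = (0, 0)  # (dmw, dmo), fixed across replicates
    q_method: str = field(
        default="BH over replicate p-values; q = max adjusted p among "
        "replicates with raw p < alpha, 1 if none"
    )


def q_value(ps: Sequence[float], alpha: float = 0.05) -> float:
    """Scalar q over replicate p-values.

    Benjamini–Hochberg adjusts the full list; the reported q is the largest
    adjusted value among replicates significant at ``alpha`` (raw p), or 1.0
    when no replicate is significant.  This is one declared interpretation of
    a replicate-wise q summary — monotone and conservative.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValueError("empty p-value list")
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = bh_adjust(ps)
    sig = ps < alpha
    if not sig.any():
        return 1.0
    return float(adjusted[sig].max())


def bh_adjust(ps: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (via statsmodels)."""
    return multipletests(np.asarray(ps, dtype=float), method="fdr_bh")[1]


def matched_enrichment(
    disease: VariantSet,
    pool: VariantSet,
    track: RegulatoryTrack,
    n_sets: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    bin_edges: Sequence[float] = DEFAULT_AF_BIN_EDGES,
) -> MatchedNullResult:
    """Matched-null enrichment of one disease set on one track.

    The disease within/outside counts are fixed; each replicate contributes
    the control counts of one matched draw.  Pool and disease must be
    key-disjoint (build the pool with :func:`regvar.variants.subtract`).
    """
    shared = disease.keys() & pool.keys()
    if shared:
        raise ValueError(
            f"pool shares {len(shared)} key(s) with the disease set; subtract first"
        )
    target = af_histogram(disease, bin_edges)
    variants, by_bin = _pool_bins(pool, bin_edges)
    _check_capacity(target, by_bin)

    # fixed disease margin
    dmask = disease.in_track_mask(track)
    dmw = int(dmask.sum())
    dmo = len(disease) - dmw

    # per-pool-variant membership, computed once
    pool_vs = VariantSet(pool.label, variants)  # stable order matches `variants`
    pmask = pool_vs.in_track_mask(track)

    dcw = np.empty(n_sets, dtype=np.int64)
    for i in range(n_sets):
        idx = _sample_indices(target, by_bin, _replicate_rng(seed, i))
        dcw[i] = int(pmask[idx].sum())
    n_ctrl = target.total
    dco = n_ctrl - dcw

    with np.errstate(divide="ignore", invalid="ignore"):
        ors = (dmw * dco.astype(float)) / (dmo * dcw.astype(float))
    _, ps = chi2_batch(
        np.full(n_sets, dmw), np.full(n_sets, dmo), dcw, dco
    )

    finite = np.isfinite(ors)
    median_or = float(np.median(ors[finite])) if finite.any() else math.nan
    return MatchedNullResult(
        track_label=track.label,
        category_label=disease.label,
        n_replicates=n_sets,
        replicate_ors=[float(x) for x in ors],
        replicate_ps=[float(x) for x in ps],
        median_or=median_or,
        q=q_value(ps, alpha),
        significant_fraction=float((ps < alpha).mean()),
        n_nonfinite=int((~finite).sum()),
        seed=seed,
        alpha=alpha,
        table_disease=(dmw, dmo),
    )
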
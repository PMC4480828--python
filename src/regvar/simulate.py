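"""Synthetic toy genomes with planted regulatory enrichment.

Generates everything the pipeline consumes — chromosome sizes, gene models
with exon/CDS structure, merged regulatory tracks covering configurable
genome fractions, a background variant pool with a configurable allele
frequency distribution, and disease variant sets with a *planted*
fold-enrichment λ in a chosen track.

Planting is calibrated so the population odds ratio of the within/outside
2×2 table is exactly λ: with track coverage ``c`` (fraction of the genome),
each disease variant falls inside the track with probability

    p = λc / (λc + 1 − c)

and uniformly within the chosen side, while background variants are uniform
(in-track probability ``c``).  Then ``(p/(1−p)) / (c/(1−c)) = λ`` exactly,
so estimators downstream can be checked against the ground truth.

Determinism: every generator draws from ``numpy.random.default_rng([seed,
component_key])`` with fixed component keys (genome 0, pool 1, tracks 10+i,
disease sets 100+i), so each piece is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .consequences import SeverityRanking
from .intervals import (
    GeneModel,
    GenomicInterval,
    RegulatoryTrack,
    complement_track,
)
from .variants import Variant, VariantSet

_BASES = np.array(list("ACGT"))


class GenomeCapacityError(ValueError):
    """Requested structure cannot fit on the toy genome."""


@dataclass(frozen=True)
class TrackSpec:
    label: str
    fraction: float  # target genome fraction covered, in (0, 1)
    mean_interval_length: int = 800

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction < 1.0):
            raise ValueError("track fraction must be in (0, 1)")
        if self.mean_interval_length < 10:
            raise ValueError("mean interval length too small")


@dataclass(frozen=True)
class DiseaseSpec:
    category: str
    n_variants: int
    planted_track: str
    fold: float  # λ > 0; 1 = no enrichment
    af_model: tuple | None = None  # falls back to the config-wide model

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise ValueError("n_variants must be > 0")
        if self.fold <= 0:
            raise ValueError("fold λ must be > 0")


# The default scenario mirrors the real study's structure at toy scale:
# nine regulatory tracks at the genome fractions reported for the real
# FANTOM5/ENCODE tracks, four disease categories at one tenth of the curated
# set sizes, planted in the tracks where the strongest matched-null
# enrichments were observed (promoter 22x for Mendelian, ~11x for somatic,
# histone 26.5x for germline cancer; complex variants near-flat).
DEFAULT_TRACK_SPECS = (
    TrackSpec("promoter", 0.0012, 400),
    TrackSpec("enhancer", 0.0038, 300),
    TrackSpec("insulator", 0.0352, 1500),
    TrackSpec("methylation", 0.0060, 500),
    TrackSpec("histone", 0.8700, 5000),
    TrackSpec("chromatin_interaction", 0.3983, 4000),
    TrackSpec("dna_binding", 0.1176, 1000),
    TrackSpec("dnase", 0.1197, 1000),
    TrackSpec("faire", 0.1387, 1000),
)

DEFAULT_DISEASE_SPECS = (
    DiseaseSpec("mendelian", 2756, "promoter", 22.0),
    DiseaseSpec("complex", 2096, "enhancer", 1.5),
    DiseaseSpec("cancer_germline", 581, "histone", 26.5),
    DiseaseSpec("cancer_somatic", 4336, "promoter", 10.87),
)


@dataclass
class SyntheticConfig:
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 3_000_000}
    )
    n_genes: int = 150
    track_specs: tuple[TrackSpec, ...] = DEFAULT_TRACK_SPECS
    pool_size: int = 100_000
    af_model: tuple = ("beta", 0.2, 2.0)
    disease_specs: tuple[DiseaseSpec, ...] = DEFAULT_DISEASE_SPECS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size <= 0 or self.n_genes < 0:
            raise ValueError("counts must be positive")
        labels = [t.label for t in self.track_specs]
        if len(set(labels)) != len(labels):
            raise ValueError("track labels must be unique")
        for d in self.disease_specs:
            if d.planted_track not in labels:
                raise ValueError(
                    f"disease spec {d.category!r} plants into unknown track "
                    f"{d.planted_track!r}"
                )

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass
class SyntheticScenario:
    """Fully materialised toy study: genome, tracks, pool and disease sets."""

    config: SyntheticConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    tracks: dict[str, RegulatoryTrack]
    pool: VariantSet
    disease_sets: dict[str, VariantSet]


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng([seed, component])


# ---------------------------------------------------------------------------
# genome / gene models
# ---------------------------------------------------------------------------


def _make_gene(
    gene_id: str, chrom: str, start: int, end: int, strand: str,
    rng: np.random.Generator,
) -> GeneModel:
    """Random exon/CDS structure over a fixed transcript span."""
    length = end - start
    n_exons = int(rng.integers(1, 5))
    # 2*n_exons ordered cut points; first/last pinned to the span bounds
    if n_exons == 1:
        cuts = [0, length]
    else:
        inner = np.sort(rng.choice(np.arange(1, length), 2 * n_exons - 2, replace=False))
        cuts = [0, *inner.tolist(), length]
    exons = [
        (start + cuts[2 * i], start + cuts[2 * i + 1])
        for i in range(n_exons)
        if cuts[2 * i] < cuts[2 * i + 1]
    ]
    # CDS: exonic bp minus short UTRs trimmed from each end in transcript order
    exonic = sum(e - s for s, e in exons)
    utr5 = int(rng.integers(0, max(1, exonic // 5)))
    utr3 = int(rng.integers(0, max(1, exonic // 5)))
    if utr5 + utr3 >= exonic:
        utr5 = utr3 = 0
    ordered = exons if strand == "+" else [(s, e) for s, e in reversed(exons)]
    cds: list[tuple[int, int]] = []
    skip_head, keep = utr5, exonic - utr5 - utr3
    for s, e in ordered:
        seg = e - s
        cut_lo = min(skip_head, seg)
        skip_head -= cut_lo
        take = min(keep, seg - cut_lo)
        if take > 0:
            if strand == "+":
                cds.append((s + cut_lo, s + cut_lo + take))
            else:
                cds.append((e - cut_lo - take, e - cut_lo))
            keep -= take
    cds.sort()
    return GeneModel(
        gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
        exons=tuple(exons), cds=tuple(cds),
    )


def generate_genome(cfg: SyntheticConfig) -> tuple[dict[str, int], list[GeneModel]]:
    """Place ``n_genes`` non-overlapping genes with exon/CDS structure."""
    rng = _rng(cfg.seed, 0)
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    max_attempts = 200 * max(1, cfg.n_genes)
    while len(genes) < cfg.n_genes:
        if attempts > max_attempts:
            raise GenomeCapacityError(
                f"could not place {cfg.n_genes} genes after {attempts} attempts"
            )
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
        size = cfg.chrom_sizes[chrom]
        length = int(rng.integers(2_000, 8_001))
        if length + 2 >= size:
            continue
        start = int(rng.integers(0, size - length))
        end = start + length
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            _make_gene(f"gene{len(genes) + 1}", chrom, start, end, strand, rng)
        )
        occupied[chrom].append((start, end))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return dict(cfg.chrom_sizes), genes


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def generate_track(
    spec: TrackSpec,
    chrom_sizes: Mapping[str, int],
    seed: int,
    component: int = 10,
) -> RegulatoryTrack:
    """Random merged track whose union length hits ``fraction`` of the genome.

    Intervals with exponentially distributed lengths are thrown down
    uniformly and merged until the union reaches the target; the final
    interval is trimmed so the total length is exact (hence always within
    the 5% tolerance of the target).
    """
    rng = _rng(seed, component)
    genome = sum(chrom_sizes.values())
    target = int(round(spec.fraction * genome))
    if target <= 0:
        raise ValueError("target coverage is empty")
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()

    intervals: list[GenomicInterval] = []
    union = 0
    while union < target:
        missing = target - union
        k = max(1, int(np.ceil(missing / spec.mean_interval_length)))
        k = min(k, 20_000)
        picks = rng.choice(len(chroms), size=k, p=probs)
        lengths = np.maximum(
            20, rng.exponential(spec.mean_interval_length, size=k).astype(np.int64)
        )
        for ci, ln in zip(picks, lengths):
            size = int(sizes[ci])
            ln = int(min(ln, size))
            s = int(rng.integers(0, size - ln + 1))
            intervals.append(GenomicInterval(chroms[ci], s, s + ln))
        union = RegulatoryTrack.from_intervals(spec.label, intervals).total_length

    # trim the merged union down to the exact target length
    merged = RegulatoryTrack.from_intervals(spec.label, intervals)
    kept: list[GenomicInterval] = []
    acc = 0
    for iv in merged.intervals:
        if acc >= target:
            break
        take = min(len(iv), target - acc)
        kept.append(GenomicInterval(iv.chrom, iv.start, iv.start + take))
        acc += take
    return RegulatoryTrack.from_intervals(spec.label, kept)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


def _draw_afs(af_model: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    name = af_model[0]
    if name == "beta":
        _, a, b = af_model
        return rng.beta(a, b, size=n)
    if name == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    if name == "missing":
        return np.full(n, np.nan)
    raise ValueError(f"unknown AF model {af_model!r}")


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref], _BASES[alt]


class _TrackSampler:
    """Uniform sampling of 0-based positions over the bp of a merged track."""

    def __init__(self, track: RegulatoryTrack):
        chroms: list[str] = []
        starts: list[np.ndarray] = []
        lengths: list[np.ndarray] = []
        for chrom in track.chroms:
            s, e = track.arrays(chrom)
            chroms.extend([chrom] * len(s))
            starts.append(s)
            lengths.append(e - s)
        self._chroms = chroms
        self._starts = (
            np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
        )
        lens = np.concatenate(lengths) if lengths else np.empty(0, dtype=np.int64)
        self._cum = np.concatenate([[0], np.cumsum(lens)])
        self.total = int(self._cum[-1])

    def draw(self, n: int, rng: np.random.Generator) -> list[tuple[str, int]]:
        if self.total == 0:
            raise ValueError("cannot sample positions from an empty track")
        offsets = rng.integers(0, self.total, size=n)
        which = np.searchsorted(self._cum, offsets, side="right") - 1
        pos = self._starts[which] + (offsets - self._cum[which])
        return [(self._chroms[w], int(p)) for w, p in zip(which, pos)]


def generate_pool(
    cfg: SyntheticConfig,
    chrom_sizes: Mapping[str, int] | None = None,
    component: int = 1,
) -> VariantSet:
    """Uniform background variant panel with i.i.d. allele frequencies.

    Stands in for a genome-wide SNP catalogue; positions are uniform over the
    genome with no two variants sharing an identical (chrom, pos, ref, alt)
    key.
    """
    chrom_sizes = chrom_sizes or cfg.chrom_sizes
    rng = _rng(cfg.seed, component)
    genome = sum(chrom_sizes.values())
    if cfg.pool_size > genome:
        raise ValueError("pool_size exceeds genome size")
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()

    vs = VariantSet("background")
    afs = _draw_afs(cfg.af_model, cfg.pool_size, rng)
    i = 0
    while len(vs) < cfg.pool_size:
        need = cfg.pool_size - len(vs)
        picks = rng.choice(len(chroms), size=need, p=probs)
        ref, alt = _random_alleles(rng, need)
        for j in range(need):
            chrom = chroms[picks[j]]
            pos = int(rng.integers(1, chrom_sizes[chrom] + 1))
            v = Variant(
                chrom, pos, str(ref[j]), str(alt[j]),
                id=f"bg{i + 1}", category="background",
                af=float(afs[min(i, cfg.pool_size - 1)])
                if not np.isnan(afs[min(i, cfg.pool_size - 1)]) else None,
            )
            if v.key not in vs:
                vs.add(v)
                i += 1
    return vs


def planting_probability(fold: float, coverage: float) -> float:
    """In-track placement probability giving a population odds ratio of λ.

    ``p = λc / (λc + 1 − c)``; the identity ``(p/(1−p))/(c/(1−c)) = λ`` holds
    exactly for any coverage c in (0, 1).
    """
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must be in (0, 1)")
    return fold * coverage / (fold * coverage + 1.0 - coverage)


def plant_disease_set(
    spec: DiseaseSpec,
    chrom_sizes: Mapping[str, int],
    track: RegulatoryTrack,
    seed: int,
    component: int = 100,
    af_model: tuple = ("beta", 0.2, 2.0),
) -> VariantSet:
    """Disease set with planted fold-enrichment λ in ``track``.

    Each variant lands inside the track with probability
    ``p = λc/(λc + 1 − c)`` and uniformly within the chosen side, making the
    population odds ratio against a uniform background exactly λ.
    """
    rng = _rng(seed, component)
    genome = sum(chrom_sizes.values())
    coverage = track.total_length / genome
    p = planting_probability(spec.fold, coverage)
    inside_sampler = _TrackSampler(track)
    outside_sampler = _TrackSampler(
        complement_track(track, chrom_sizes, label="outside")
    )

    model = spec.af_model or af_model
    afs = _draw_afs(model, spec.n_variants, rng)
    vs = VariantSet(spec.category)
    i = 0
    while len(vs) < spec.n_variants:
        need = spec.n_variants - len(vs)
        inside = rng.random(need) < p
        positions: list[tuple[str, int]] = []
        for flag in inside:  # one draw per variant keeps the two streams aligned
            sampler = inside_sampler if flag else outside_sampler
            positions.extend(sampler.draw(1, rng))
        ref, alt = _random_alleles(rng, need)
        for j, (chrom, pos0) in enumerate(positions):
            v = Variant(
                chrom, pos0 + 1, str(ref[j]), str(alt[j]),
                id=f"dz_{spec.category}_{i + 1}", category=spec.category,
                af=None if np.isnan(afs[min(i, spec.n_variants - 1)])
                else float(afs[min(i, spec.n_variants - 1)]),
            )
            if v.key not in vs:
                vs.add(v)
                i += 1
    return vs


# ---------------------------------------------------------------------------
# whole scenarios, annotation, file emission
# ---------------------------------------------------------------------------


def generate_scenario(cfg: SyntheticConfig) -> SyntheticScenario:
    """Materialise a full toy study from one config (deterministic in seed)."""
    chrom_sizes, genes = generate_genome(cfg)
    tracks = {
        spec.label: generate_track(spec, chrom_sizes, cfg.seed, component=10 + i)
        for i, spec in enumerate(cfg.track_specs)
    }
    pool = generate_pool(cfg, chrom_sizes)
    disease_sets = {
        spec.category: plant_disease_set(
            spec, chrom_sizes, tracks[spec.planted_track], cfg.seed,
            component=100 + i, af_model=cfg.af_model,
        )
        for i, spec in enumerate(cfg.disease_specs)
    }
    return SyntheticScenario(cfg, chrom_sizes, genes, tracks, pool, disease_sets)


# category-tilted consequence severity used by the annotation helper: the
# share of variants drawn from the top-11 severe terms, loosely following the
# ordering seen across real disease categories (germline cancer and Mendelian
# most severe, complex least).
DEFAULT_SEVERE_SHARE = {
    "mendelian": 0.31,
    "cancer_germline": 0.32,
    "cancer_somatic": 0.32,
    "complex": 0.02,
    "background": 0.01,
}


def annotate_consequences(
    vs: VariantSet,
    seed: int,
    severe_share: float | None = None,
    ranking: SeverityRanking | None = None,
    component: int = 500,
) -> VariantSet:
    """Attach synthetic consequence terms and functional scores to a set.

    Purely a test/demo surrogate for upstream annotation tools: terms are
    drawn from the 34-term severity ranking with probability ``severe_share``
    of landing in the top 11, and Mutation-Assessor-like / GERP-like scores
    are drawn from category-shifted normals.
    """
    ranking = ranking or SeverityRanking.default()
    if severe_share is None:
        severe_share = DEFAULT_SEVERE_SHARE.get(vs.label, 0.1)
    rng = _rng(seed, component)
    top = ranking.ordered_terms[:11]
    rest = ranking.ordered_terms[11:]
    shift = 2.0 * severe_share  # crude coupling of score level to severity
    out = VariantSet(vs.label)
    for v in vs:
        severe = rng.random() < severe_share
        term = str(rng.choice(top if severe else rest))
        scores = dict(v.scores)
        scores["mutation_assessor"] = float(rng.normal(0.8 + 2.5 * shift, 1.0))
        scores["gerp"] = float(rng.normal(-0.5 + 4.0 * shift, 2.0))
        out.add(
            Variant(
                v.chrom, v.pos, v.ref, v.alt, v.id, v.category, v.af,
                v.coding, term, scores,
            )
        )
    return out


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tregvar\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tregvar\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tregvar\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Write a scenario to standard files (chrom sizes, GFF3, BED, TSV).

    Returns a map of logical names to paths, suitable for building a run
    config for the file-based pipeline.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = outdir / "chrom.sizes"
    with open(p, "w") as fh:
        for chrom, size in scenario.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    paths["chrom_sizes"] = p

    p = outdir / "genes.gff3"
    write_gff3(scenario.genes, p)
    paths["gene_models"] = p

    trackdir = outdir / "tracks"
    trackdir.mkdir(exist_ok=True)
    for label, track in scenario.tracks.items():
        p = trackdir / f"{label}.bed"
        track.to_bed(p)
        paths[f"track:{label}"] = p

    p = outdir / "background.tsv"
    scenario.pool.to_tsv(p)
    paths["background"] = p
    for category, vs in scenario.disease_sets.items():
        p = outdir / f"{category}.tsv"
        vs.to_tsv(p)
        paths[f"variants:{category}"] = p
    return paths
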
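"""File-based orchestration of the analyses over one run configuration.

A :class:`RunConfig` (usually loaded from YAML) names the input files —
regulatory tracks as BED, gene models as GFF3, variant tables with category
labels, a background panel — plus the enrichment options (alpha, number of
matched control sets, AF bin edges, seed, zero-cell policy).  The ``run_*``
functions load the inputs, call the library, and write deterministic TSV
reports plus a JSON run manifest into the output directory:

* :func:`run_density`   — track × genomic-class overlap matrix and the
  per-track variant density table (counts and DVPM).
* :func:`run_enrichment` — odds-ratio enrichment of every disease category
  against the subtracted genome-variant background, per track (lnOR and SE
  columns support forest-style plotting); optionally on the noncoding
  subset only.
* :func:`run_matched_null` — the allele-frequency-matched resampling null
  with median OR, q and significant fraction per category × track.
* :func:`run_consequences` — severity-ranked consequence profiles and
  score-threshold summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .consequences import SeverityRanking, consequence_profile, score_threshold_summary
from .density import density_table, density_table_frame, overlap_matrix
from .enrichment import enrichment_result
from .intervals import (
    GenomePartition,
    RegulatoryTrack,
    build_genome_partition,
    read_bed,
    read_chrom_sizes,
    read_gene_models,
)
from .matched_null import DEFAULT_AF_BIN_EDGES, matched_enrichment
from .variants import VariantSet, read_variants, subtract

logger = logging.getLogger(__name__)


@dataclass
class VariantFileSpec:
    path: str
    category: str
    format: str = "tsv"  # or "vcf"


@dataclass
class RunConfig:
    chrom_sizes: str
    gene_models: str | None
    tracks: dict[str, str]  # label -> BED path
    variants: list[VariantFileSpec]
    background: VariantFileSpec | None = None
    out_dir: str = "results/run"
    seed: int = 0
    alpha: float = 0.05
    n_sets: int = 1000
    af_bin_edges: tuple[float, ...] = DEFAULT_AF_BIN_EDGES
    haldane: bool = False
    af_field: str = "AF"
    flank: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["variants"] = [VariantFileSpec(**v) for v in raw.get("variants", [])]
        if raw.get("background"):
            raw["background"] = VariantFileSpec(**raw["background"])
        if "af_bin_edges" in raw:
            raw["af_bin_edges"] = tuple(raw["af_bin_edges"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in [self.chrom_sizes, self.gene_models, *self.tracks.values(),
                  *(v.path for v in self.variants),
                  *( [self.background.path] if self.background else [] )]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


@dataclass
class LoadedInputs:
    chrom_sizes: dict[str, int]
    partition: GenomePartition | None
    tracks: list[RegulatoryTrack]
    disease_sets: list[VariantSet]
    background: VariantSet | None
    control: VariantSet | None = None  # background minus all disease keys


def load_inputs(cfg: RunConfig) -> LoadedInputs:
    chrom_sizes = read_chrom_sizes(cfg.chrom_sizes)
    partition = None
    if cfg.gene_models:
        genes = read_gene_models(cfg.gene_models)
        partition = build_genome_partition(genes, chrom_sizes, flank=cfg.flank)
    tracks = [read_bed(path, label=label) for label, path in cfg.tracks.items()]
    disease_sets = [
        read_variants(v.path, format=v.format, category=v.category,
                      af_field=cfg.af_field)
        for v in cfg.variants
    ]
    background = control = None
    if cfg.background:
        background = read_variants(
            cfg.background.path, format=cfg.background.format,
            category=cfg.background.category, af_field=cfg.af_field,
        )
        control = subtract(background, disease_sets, label="control")
    for vs in disease_sets:
        logger.info("loaded %s: %d variants", vs.label, len(vs))
    if background is not None:
        logger.info(
            "background: %d variants (%d after subtracting disease sets)",
            len(background), len(control),
        )
    return LoadedInputs(chrom_sizes, partition, tracks, disease_sets,
                        background, control)


def _write_manifest(cfg: RunConfig, outdir: Path, analysis: str,
                    extra: dict | None = None) -> None:
    manifest = {
        "analysis": analysis,
        "regvar_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "n_sets": cfg.n_sets,
        "af_bin_edges": list(cfg.af_bin_edges),
        "haldane": cfg.haldane,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
    }
    if extra:
        manifest.update(extra)
    with open(outdir / f"manifest_{analysis}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_density(cfg: RunConfig, inputs: LoadedInputs | None = None) -> dict[str, Path]:
    """Overlap matrix (bp and %) and per-track density/DVPM table."""
    inputs = inputs or load_inputs(cfg)
    if inputs.partition is None:
        raise ValueError("density analysis requires gene models")
    out = _outdir(cfg)
    mat = overlap_matrix(inputs.tracks, inputs.partition)
    bp_path = out / "overlap_matrix_bp.tsv"
    pct_path = out / "overlap_matrix_pct.tsv"
    mat.bp.to_csv(bp_path, sep="\t", index_label="track")
    mat.pct.round(4).to_csv(pct_path, sep="\t", index_label="track")

    dens = density_table(inputs.disease_sets, inputs.tracks, inputs.partition)
    dens_path = out / "density.tsv"
    density_table_frame(dens).to_csv(dens_path, sep="\t", index=False,
                                     float_format="%.6g")
    _write_manifest(cfg, out, "density")
    return {"overlap_bp": bp_path, "overlap_pct": pct_path, "density": dens_path}


def run_enrichment(
    cfg: RunConfig,
    inputs: LoadedInputs | None = None,
    noncoding_only: bool = False,
) -> dict[str, Path]:
    """Background enrichment: OR/lnOR/SE/chi²/p per (category, track)."""
    inputs = inputs or load_inputs(cfg)
    if inputs.control is None:
        raise ValueError("enrichment analysis requires a background variant panel")
    out = _outdir(cfg)
    control = inputs.control
    disease_sets = inputs.disease_sets
    if noncoding_only:
        disease_sets = [ds.noncoding(ds.label) for ds in disease_sets]
        control = control.noncoding("control")
        for ds in disease_sets:
            if len(ds) == 0:
                raise ValueError(
                    f"category {ds.label!r} has no variants with coding flag False"
                )
    rows = []
    for ds in disease_sets:
        for track in inputs.tracks:
            r = enrichment_result(ds, control, track, haldane=cfg.haldane)
            rows.append({
                "category": r.category_label,
                "track": r.track_label,
                "dmw": r.table.dmw, "dmo": r.table.dmo,
                "dcw": r.table.dcw, "dco": r.table.dco,
                "odds_ratio": r.odds_ratio, "log_or": r.log_or, "se": r.se,
                "chi2": r.chi2, "p": r.p,
            })
    name = "enrichment_noncoding.tsv" if noncoding_only else "enrichment.tsv"
    path = out / name
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    _write_manifest(cfg, out, "enrichment",
                    {"noncoding_only": noncoding_only})
    return {"enrichment": path}


def run_matched_null(
    cfg: RunConfig,
    inputs: LoadedInputs | None = None,
    write_replicates: bool = False,
    tracks: Sequence[str] | None = None,
) -> dict[str, Path]:
    """AF-matched resampling null per (category, track)."""
    inputs = inputs or load_inputs(cfg)
    if inputs.control is None:
        raise ValueError("matched-null analysis requires a background variant panel")
    out = _outdir(cfg)
    selected = [
        t for t in inputs.tracks if tracks is None or t.label in tracks
    ]
    rows = []
    rep_rows = []
    for ds in inputs.disease_sets:
        for track in selected:
            res = matched_enrichment(
                ds, inputs.control, track,
                n_sets=cfg.n_sets, seed=cfg.seed, alpha=cfg.alpha,
                bin_edges=cfg.af_bin_edges,
            )
            rows.append({
                "category": res.category_label,
                "track": res.track_label,
                "n_replicates": res.n_replicates,
                "median_or": res.median_or,
                "q": res.q,
                "significant_fraction": res.significant_fraction,
                "n_nonfinite_or": res.n_nonfinite,
                "dmw": res.table_disease[0], "dmo": res.table_disease[1],
                "seed": res.seed,
                "q_method": res.q_method,
            })
            if write_replicates:
                rep_rows.extend(
                    {"category": res.category_label, "track": res.track_label,
                     "replicate": i, "odds_ratio": o, "p": p}
                    for i, (o, p) in enumerate(
                        zip(res.replicate_ors, res.replicate_ps)
                    )
                )
    path = out / "matched_null.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    written = {"matched_null": path}
    if write_replicates:
        rep_path = out / "matched_null_replicates.tsv"
        pd.DataFrame(rep_rows).to_csv(rep_path, sep="\t", index=False,
                                      float_format="%.6g")
        written["replicates"] = rep_path
    _write_manifest(cfg, out, "matched_null")
    return written


def run_consequences(
    cfg: RunConfig,
    inputs: LoadedInputs | None = None,
    top_k: int = 11,
    score_thresholds: dict[str, tuple[float, str]] | None = None,
) -> dict[str, Path]:
    """Severity-ranked consequence profiles and score-threshold summaries.

    ``score_thresholds`` maps a score column to (threshold, direction);
    defaults to Mutation Assessor >= 1.9 and GERP > 0.
    """
    inputs = inputs or load_inputs(cfg)
    out = _outdir(cfg)
    ranking = SeverityRanking.default()
    if score_thresholds is None:
        score_thresholds = {"mutation_assessor": (1.9, "ge"), "gerp": (0.0, "gt")}

    prof_rows = []
    score_rows = []
    for ds in inputs.disease_sets:
        prof = consequence_profile(ds, ranking, k=top_k)
        for term, frac in sorted(
            prof.per_term_fraction.items(), key=lambda kv: ranking.rank(kv[0])
        ):
            prof_rows.append({
                "category": prof.category_label, "consequence": term,
                "rank": ranking.rank(term), "fraction": frac,
            })
        prof_rows.append({
            "category": prof.category_label, "consequence": f"top_{top_k}_severe",
            "rank": 0, "fraction": prof.top_k_fraction,
        })
        for score, (thr, direction) in score_thresholds.items():
            try:
                frac, n_scored, n_unscored = score_threshold_summary(
                    ds, score, thr, direction
                )
            except ValueError:
                continue  # score absent from this category's annotations
            score_rows.append({
                "category": ds.label, "score": score, "threshold": thr,
                "direction": direction, "fraction": frac,
                "n_scored": n_scored, "n_unscored": n_unscored,
            })
    prof_path = out / "consequence_profile.tsv"
    pd.DataFrame(prof_rows).to_csv(prof_path, sep="\t", index=False,
                                   float_format="%.6g")
    score_path = out / "score_summary.tsv"
    pd.DataFrame(score_rows).to_csv(score_path, sep="\t", index=False,
                                    float_format="%.6g")
    _write_manifest(cfg, out, "consequences")
    return {"profile": prof_path, "scores": score_path}
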
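"""End-to-end orchestration: annotate -> filter -> mask -> enrich
(-> profile when a hit table is supplied), with a machine-readable run
manifest.

Every stage writes its table under the output directory; the manifest
records the configuration, MD5 fingerprints of the inputs, and the
headline statistics (contingency counts, chi-square, enrichment fold,
per-residue profile path, coverage table path), so a rerun with identical
inputs and configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cast_bias import CastConfig, mask_fasta, total_scores_by_residue
from .disease_enrichment import (
    FilterConfig,
    aa_frequencies,
    build_contingency,
    chi_square_2x2,
    enrichment_fold,
    filter_transcripts,
    normalized_bias_profile,
)
from .phylo_profile import (
    ProfileConfig,
    build_profile,
    cluster_order,
    filter_significant,
    parse_hit_table,
    resolve_proteome,
    scale_rows,
)
from .sequence_io import annotate_with_doids, read_association_table, read_fasta, write_fasta

__all__ = ["PipelineConfig", "PipelineConfigError", "run_pipeline"]

logger = logging.getLogger("compbias")


class PipelineConfigError(ValueError):
    """Raised before any computation when the configuration is unusable."""


@dataclass
class PipelineConfig:
    fasta: Path
    associations: Path
    output_dir: Path
    hits: Path | None = None
    cast: CastConfig = field(default_factory=CastConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.fasta = Path(self.fasta)
        self.associations = Path(self.associations)
        self.output_dir = Path(self.output_dir)
        if self.hits is not None:
            self.hits = Path(self.hits)


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written as JSON)."""
    for path in filter(None, [config.fasta, config.associations, config.hits]):
        if not Path(path).exists():
            raise PipelineConfigError(f"input file not found: {path}")
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config": {
            "fasta": str(config.fasta),
            "associations": str(config.associations),
            "hits": str(config.hits) if config.hits else None,
            "cast_threshold": config.cast.threshold,
            "min_length": config.filter.min_length,
            "max_evalue": config.profile.max_evalue,
            "min_identity": config.profile.min_identity,
            "alpha": config.alpha,
            "seed": config.seed,
        },
        "input_fingerprints": {
            "fasta": _md5(config.fasta),
            "associations": _md5(config.associations),
            **({"hits": _md5(config.hits)} if config.hits else {}),
        },
        "stages": {},
    }

    logger.info("annotate: reading %s", config.fasta)
    records = read_fasta(config.fasta)
    associations = read_association_table(config.associations)
    records = annotate_with_doids(records, associations)
    annotated_path = out / "annotated.fasta"
    write_fasta(records, annotated_path)
    manifest["stages"]["annotate"] = {
        "n_records": len(records),
        "n_disease_records": sum(1 for r in records if r.doids),
        "output": str(annotated_path),
    }

    logger.info("filter: min_length=%d", config.filter.min_length)
    filtered = filter_transcripts(records, config.filter)
    manifest["stages"]["filter"] = {
        "n_kept": len(filtered),
        "n_removed": len(records) - len(filtered),
    }

    logger.info("mask: threshold=%d over %d records", config.cast.threshold, len(filtered))
    biased, clean = mask_fasta(filtered, config.cast)
    regions_path = out / "regions.tsv"
    region_rows = [
        {
            "record_id": result.record_id,
            "bias_residue": region.bias_residue,
            "start": region.start,
            "end": region.end,
            "score": region.score,
            "iteration": region.iteration,
        }
        for _, result in biased
        for region in result.regions
    ]
    pd.DataFrame(
        region_rows,
        columns=["record_id", "bias_residue", "start", "end", "score", "iteration"],
    ).to_csv(regions_path, sep="\t", index=False)
    write_fasta([rec for rec, _ in biased], out / "biased.fasta")
    write_fasta(clean, out / "clean.fasta")
    manifest["stages"]["mask"] = {
        "n_biased": len(biased),
        "n_clean": len(clean),
        "n_regions": len(region_rows),
        "regions": str(regions_path),
    }

    logger.info("enrich: alpha=%g", config.alpha)
    lc_flags = {rec.id: True for rec, _ in biased}
    lc_flags.update({rec.id: False for rec in clean})
    table = build_contingency(filtered, lc_flags)
    chi = chi_square_2x2(table, alpha=config.alpha)
    fold = enrichment_fold(table) if table.n_disease_hc and table.n_nondisease_hc and table.n_nondisease_lc else None
    table.to_frame().to_csv(out / "contingency.tsv", sep="\t")
    pd.DataFrame(
        [{
            "statistic": chi.statistic,
            "df": chi.df,
            "p_value": chi.p_value,
            "significant": chi.significant,
            "alpha": chi.alpha,
            "enrichment_fold": fold,
        }]
    ).to_csv(out / "chi_square.tsv", sep="\t", index=False)
    totals = total_scores_by_residue([result for _, result in biased])
    freqs = aa_frequencies(filtered)
    profile = normalized_bias_profile(totals, freqs)
    profile.to_frame().to_csv(out / "aa_profile.tsv", sep="\t")
    manifest["stages"]["enrich"] = {
        "contingency": {
            "n_nondisease_lc": table.n_nondisease_lc,
            "n_nondisease_hc": table.n_nondisease_hc,
            "n_disease_lc": table.n_disease_lc,
            "n_disease_hc": table.n_disease_hc,
        },
        "chi_square": chi.statistic,
        "p_value": chi.p_value,
        "significant": chi.significant,
        "enrichment_fold": fold,
        "aa_profile": str(out / "aa_profile.tsv"),
    }

    if config.hits is not None:
        logger.info("profile: parsing %s", config.hits)
        hits = parse_hit_table(config.hits)
        significant = filter_significant(hits, config.profile)
        queries = sorted({h.query_id for h in significant})
        proteomes = sorted({resolve_proteome(h.subject_id) for h in significant})
        matrix = build_profile(significant, queries, proteomes)
        matrix.counts.to_csv(out / "profile_counts.tsv", sep="\t")
        scaled = scale_rows(matrix)
        if len(queries) > 1:
            order = cluster_order(scaled, axis="rows")
            scaled = scaled.iloc[order]
        scaled.to_csv(out / "profile_scaled.tsv", sep="\t")
        manifest["stages"]["profile"] = {
            "n_hits": len(hits),
            "n_significant": len(significant),
            "n_queries": len(queries),
            "n_proteomes": len(proteomes),
            "counts": str(out / "profile_counts.tsv"),
            "scaled": str(out / "profile_scaled.tsv"),
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("manifest written to %s", manifest_path)
    return manifest
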
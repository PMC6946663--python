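"""End-to-end pipeline: read -> filter -> screen -> normalize -> rollup ->
compare -> enrich -> image, driven by one YAML config.

Every intermediate is a flat TSV under the output directory, the run log
echoes parameters and per-stage row counts, and ``summary.json`` collects
the machine-readable tallies. Outputs carry no timestamps, so identical
config + seed reproduce byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .matrices import check_samples_match
from .normalize import normalize
from .outliers import correlation_screen, pav_metrics, rmd_pav
from .qc import EligibilityConfig, eligibility_table, filter_min_observations
from .rollup import rrollup
from .stats import compare_groups
from .enrich import go_enrichment
from .imaging import build_voxel_image, cv_summary, export_gallery

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    peptide_table: str
    metadata: str
    out_dir: str
    dialect: str = "generic"
    intensity_prefix: str = "Intensity"
    go_map: str | None = None
    go_map_format: str = "tsv"
    min_obs: int = 2
    min_anova_obs: int = 2
    min_gtest_n: int = 3
    rmd_alpha: float = 0.001
    rmd_metrics: list[str] | None = None
    corr_k: float = 1.5
    rip_alpha: float = 0.2
    min_peptides_per_protein: int = 1
    alpha_sig: float = 0.05
    min_cat: int = 2
    seed: int = 0
    make_images: bool = True
    max_images: int = 50
    image_scale: str = "minmax"
    colormap: str = "viridis"
    cv_bin_width: float = 0.05
    replicate_cv: bool = False        # treat all samples as replicate runs for CV
    stages: dict = field(default_factory=dict)   # stage toggles, e.g. {"enrich": False}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        for p in (cfg.peptide_table, cfg.metadata, cfg.go_map):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory.

    Any stage failure writes a ``FAILED`` marker naming the stage (partial
    outputs are retained) and re-raises.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config: {json.dumps(asdict(cfg), sort_keys=True)}"]
    summary: dict = {"stages": {}}
    stage = "setup"

    def note(stage_name: str, **counts) -> None:
        summary["stages"][stage_name] = counts
        log_lines.append(f"{stage_name}: {json.dumps(counts, sort_keys=True)}")

    try:
        stage = "read"
        m = vio.read_peptide_table(cfg.peptide_table, cfg.dialect, cfg.intensity_prefix)
        meta = vio.read_sample_metadata(cfg.metadata)
        check_samples_match(m, meta)
        note("read", n_peptides=m.n_peptides, n_samples=m.n_samples)

        stage = "filter_contaminants_reverse"
        m, rep = vio.filter_contaminants_reverse(m)
        note(stage, **rep)

        stage = "filter_min_observations"
        m, rep = filter_min_observations(m, cfg.min_obs)
        vio.write_peptide_table_long(m, out / "peptides_filtered.tsv")
        note(stage, **rep)

        stage = "outlier_screen"
        metrics = pav_metrics(m)
        report = rmd_pav(
            metrics,
            alpha=cfg.rmd_alpha,
            subset=tuple(cfg.rmd_metrics) if cfg.rmd_metrics else None,
            seed=cfg.seed,
        )
        report.table.to_csv(out / "outlier_report.tsv", sep="\t")
        correlation_screen(metrics, cfg.corr_k).to_csv(out / "correlation_screen.tsv", sep="\t")
        if report.flagged:
            keep = [s for s in m.sample_ids if s not in set(report.flagged)]
            m = m.with_abundance(m.abundance[keep])
            meta_df = meta.table.loc[keep].reset_index(drop=True)
            from .matrices import SampleMetadata

            meta = SampleMetadata(meta_df)
        note(stage, n_flagged=len(report.flagged), estimator=report.estimator)

        stage = "normalize"
        norm = normalize(m, meta, cfg.rip_alpha)
        norm.shift.to_csv(out / "normalization_shifts.tsv", sep="\t")
        m = norm.normalized
        note(stage, n_rank_invariant=len(norm.selected_peptides), n_peptides=m.n_peptides)

        stage = "rollup"
        prot = rrollup(m, cfg.min_peptides_per_protein)
        vio.write_matrix_tsv(prot.abundance, out / "proteins.tsv", "protein_id")
        prot.provenance.to_csv(out / "rollup_provenance.tsv", sep="\t")
        note(stage, n_proteins=prot.n_proteins)

        gene_of_protein = (
            m.gene_symbol.groupby(m.protein_id).first().reindex(prot.protein_ids).fillna("")
        )

        n_groups = meta.groups.nunique()
        comparison = None
        if n_groups >= 2:
            stage = "eligibility"
            ecfg = EligibilityConfig(cfg.min_obs, cfg.min_anova_obs, cfg.min_gtest_n)
            elig = eligibility_table(prot, meta, ecfg)
            elig.to_csv(out / "eligibility.tsv", sep="\t")
            note(stage, **elig["eligibility"].value_counts().to_dict())

            stage = "compare"
            comparison = compare_groups(prot, meta, elig, cfg.alpha_sig)
            comparison.results.to_csv(out / "comparisons.tsv", sep="\t", index=False)
            comparison.counts.to_csv(out / "significant_counts.tsv", sep="\t", index=False)
            sig_counts = {
                f"{r['pair']}|{r['direction']}": int(r["n_significant"])
                for _, r in comparison.counts.iterrows()
                if r["test"] == "anova"
            }
            summary["significant_anova"] = sig_counts
            note(stage, n_comparisons=len(comparison.results),
                 n_significant=int(comparison.results["significant"].sum()))
        else:
            log_lines.append("compare: skipped (single group)")

        if cfg.go_map and cfg.stages.get("enrich", True) and comparison is not None:
            stage = "enrich"
            annot = vio.read_annotation_map(cfg.go_map, cfg.go_map_format)
            background = sorted(set(gene_of_protein) - {""})
            n_rows = 0
            for pair in comparison.results["pair"].unique():
                res_pair = comparison.results[comparison.results["pair"] == pair]
                for direction in ("up_in_A", "up_in_B"):
                    prot_ids = res_pair.loc[
                        res_pair["significant"] & (res_pair["direction"] == direction),
                        "protein_id",
                    ]
                    genes = sorted(
                        {g for g in gene_of_protein.loc[prot_ids] if g}
                    )
                    table = go_enrichment(genes, background, annot, cfg.min_cat)
                    tag = pair.replace("|", "_vs_") + "_" + direction
                    table.to_csv(out / f"enrichment_{tag}.tsv", sep="\t", index=False)
                    n_rows += len(table)
            note(stage, n_rows=n_rows)
        else:
            log_lines.append("enrich: skipped (no GO map or toggled off)")

        if cfg.replicate_cv or n_groups == 1:
            stage = "cv_summary"
            cv = cv_summary(prot, bin_width=cfg.cv_bin_width)
            cv["table"].to_csv(out / "protein_cv.tsv", sep="\t")
            summary["median_cv"] = cv["median_cv"]
            note(stage, n_proteins=len(cv["table"]),
                 median_cv=round(cv["median_cv"], 6))

        if cfg.make_images and cfg.stages.get("imaging", True):
            stage = "imaging"
            ids = list(prot.protein_ids[: cfg.max_images])
            images = {
                pid: build_voxel_image(prot.abundance.loc[pid], meta, pid) for pid in ids
            }
            gallery = export_gallery(
                images,
                out / "gallery",
                gene_symbols={pid: gene_of_protein[pid] for pid in ids},
                scaling=cfg.image_scale,
                colormap=cfg.colormap,
            )
            note(stage, n_panels=gallery["n_panels"])

        stage = "summary"
        (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2))
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        (out / "run_log.txt").write_text("\n".join(log_lines) + f"\nFAILED at {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
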
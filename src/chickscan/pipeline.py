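"""Orchestration: one config drives QC -> clustering -> phenotype prep ->
association scan -> PCA scan -> region reporting, with a structured run log
and deterministic outputs, plus overlap of result regions with a
user-supplied file of known intervals (e.g. published QTL).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

from . import assoc, cluster, pcasel, pheno, qc
from .dataio import (
    DataError,
    GenomicRegion,
    GenotypeDataset,
    TraitTable,
    read_genotypes,
    read_intervals,
    read_phenotypes,
    write_regions,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for a full pipeline run."""

    genotypes: str
    phenotypes: str
    samples: str
    output_dir: str
    genotype_format: str = "dosage_table"
    marker_map: str | None = None
    known_intervals: str | None = None
    call_rate_min: float = 0.95
    maf_min: float = 0.05
    min_class: int = 10
    fdr_threshold: float = 0.05
    fdr_strict: float = 0.01
    r2_min: float = 0.5
    bonferroni_alpha: float = 0.05
    max_gap: int = 2_000_000
    component: int = 1
    clusters_k: int | None = None
    reference_sex: str = "female"
    welch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("call_rate_min", 0, 1), ("maf_min", 0, 0.5), ("fdr_threshold", 0, 1),
            ("fdr_strict", 0, 1), ("r2_min", 0, 1), ("bonferroni_alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_class < 0 or self.max_gap < 0:
            raise ValueError("min_class and max_gap must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RunResult:
    """Outputs of :func:`run_all`, both in memory and on disk."""

    output_dir: Path
    qc_reports: list[qc.QcReport]
    outliers: list[str]
    comparisons: pd.DataFrame
    scan_tables: dict[str, pd.DataFrame]
    scan_summaries: dict[str, assoc.ScanSummary]
    assoc_regions: list[GenomicRegion]
    pca_regions: list[GenomicRegion]
    pc_trait: pd.DataFrame
    overlap: pd.DataFrame | None = None


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA", **kw)


def significant_markers(table: pd.DataFrame, fdr_threshold: float, fdr_strict: float) -> pd.DataFrame:
    """Markers passing the FDR screen for region building.

    The primary screen is q < ``fdr_threshold``; when more than 100 markers
    pass, the stricter q < ``fdr_strict`` screen is applied first (the
    treatment the study gives its marker-dense trait) and used if nonempty.
    """
    sig = table[table["q_value"] < fdr_threshold]
    if len(sig) > 100:
        strict = table[table["q_value"] < fdr_strict]
        if len(strict):
            return strict
    return sig


def run_pipeline(
    ds: GenotypeDataset, traits: TraitTable, config: RunConfig
) -> RunResult:
    """Run every analysis stage on in-memory inputs; write outputs to disk.

    Stage order: filter cascade -> clustering (on the filtered set) ->
    genotype-class masking -> sex correction + type comparisons ->
    per-trait association scan with LD region merging -> complete-case
    reduction -> PCA contribution scan with distance merging -> optional
    overlap with known intervals.  Identical inputs and config produce
    byte-identical output files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("chickscan")
    root.addHandler(handler)
    reports: list[qc.QcReport] = []
    try:
        logger.info("input: %d samples x %d markers", ds.n_samples, ds.n_markers)

        filtered, rep = qc.filter_markers(ds, config.call_rate_min, config.maf_min)
        reports.append(rep)
        logger.info("filter cascade: %d -> %d markers", rep.input_markers, rep.survivors)

        dist = cluster.genotype_distance(filtered)
        tree = cluster.complete_linkage(dist)
        outliers = cluster.flag_outliers(tree, filtered.samples, k=config.clusters_k)
        (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
        k = config.clusters_k or filtered.samples["breed"].nunique()
        assign = pd.DataFrame(
            {
                "sample_id": tree.sample_ids,
                "cluster": tree.cut(k),
                "outlier": [int(s in set(outliers)) for s in tree.sample_ids],
            }
        )
        _write_tsv(assign, out / "clusters.tsv")
        logger.info("clustering: %d outliers at k=%d", len(outliers), k)

        masked, rep = qc.mask_small_genotype_classes(
            filtered, config.min_class, config.call_rate_min, config.maf_min
        )
        reports.append(rep)
        logger.info("class masking: %d entries masked, %d -> %d markers",
                    rep.masked_entries, rep.input_markers, rep.survivors)

        traits = pheno.sex_correct(traits, ds.samples, reference_sex=config.reference_sex)
        comparisons = pheno.comparisons_to_frame(
            pheno.compare_types(traits, ds.samples, welch=config.welch)
        )
        _write_tsv(comparisons, out / "type_comparisons.tsv")
        traits.corrected.to_csv(out / "phenotypes_corrected.tsv", sep="\t",
                                float_format=FLOAT_FORMAT, na_rep="NA")

        scan_tables: dict[str, pd.DataFrame] = {}
        summaries: dict[str, assoc.ScanSummary] = {}
        assoc_regions: list[GenomicRegion] = []
        for trait in traits.raw.columns:
            table, summary = assoc.assoc_scan(masked, traits, trait)
            scan_tables[trait] = table
            summaries[trait] = summary
            _write_tsv(table, out / f"assoc_{trait}.tsv")
            sig = significant_markers(table, config.fdr_threshold, config.fdr_strict)
            regions = assoc.merge_ld_regions(sig, masked, r2_min=config.r2_min,
                                             source=f"assoc:{trait}")
            assoc_regions.extend(regions)
            logger.info("assoc %s: lambda=%.3f, %d significant (FDR<%g), %d regions",
                        trait, summary.inflation_lambda, len(sig),
                        config.fdr_threshold, len(regions))
        write_regions(assoc_regions, out / "assoc_regions.bed")

        complete, rep = qc.complete_case_markers(masked)
        reports.append(rep)
        logger.info("complete cases: %d -> %d markers", rep.input_markers, rep.survivors)

        model = pcasel.run_pca(complete)
        contrib = pcasel.contributions(model, component=config.component)
        contrib = pcasel.pcadobs_significance(contrib, model, component=config.component,
                                              alpha=config.bonferroni_alpha)
        contrib.insert(1, "chromosome", complete.markers["chromosome"].to_numpy())
        contrib.insert(2, "position_bp", complete.markers["position_bp"].to_numpy())
        _write_tsv(contrib, out / "pca_contributions.tsv")
        scores = pd.DataFrame(model.scores[:, : min(10, model.n_components)],
                              index=model.sample_ids,
                              columns=[f"PC{i+1}" for i in range(min(10, model.n_components))])
        scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format=FLOAT_FORMAT)
        pca_regions = pcasel.merge_distance_regions(
            contrib[contrib["selected"]], max_gap=config.max_gap,
            source=f"pca:PC{config.component}")
        write_regions(pca_regions, out / "pca_regions.bed")
        pc_trait = pcasel.pc_trait_correlation(model, config.component, traits)
        _write_tsv(pc_trait, out / "pc_trait_correlation.tsv")
        logger.info("pca: PC%d explains %.1f%%, %d markers selected, %d regions",
                    config.component, 100 * model.explained[config.component - 1],
                    int(contrib["selected"].sum()), len(pca_regions))

        overlap_df = None
        if config.known_intervals:
            known = read_intervals(config.known_intervals)
            overlap_df = overlap_regions(assoc_regions + pca_regions, known)
            _write_tsv(overlap_df, out / "region_overlap.tsv")

        qc_df = pd.DataFrame([vars(r) for r in reports])
        _write_tsv(qc_df, out / "qc_report.tsv")
        pd.DataFrame([vars(s) for s in summaries.values()]).pipe(
            _write_tsv, out / "scan_summaries.tsv")
        return RunResult(
            output_dir=out,
            qc_reports=reports,
            outliers=outliers,
            comparisons=comparisons,
            scan_tables=scan_tables,
            scan_summaries=summaries,
            assoc_regions=assoc_regions,
            pca_regions=pca_regions,
            pc_trait=pc_trait,
            overlap=overlap_df,
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def run_all(config: RunConfig) -> RunResult:
    """Load inputs from the paths in ``config`` and run the full pipeline."""
    ds = read_genotypes(
        config.genotypes,
        format=config.genotype_format,
        markers_path=config.marker_map,
        samples_path=config.samples,
    )
    traits = read_phenotypes(config.phenotypes)
    return run_pipeline(ds, traits, config)


def overlap_regions(regions: list[GenomicRegion], known: pd.DataFrame) -> pd.DataFrame:
    """Every (result region, known interval) pair sharing >= 1 bp.

    ``known`` is the frame from :func:`chickscan.dataio.read_intervals`
    (1-based inclusive bounds plus a label).  Overlap lengths are in bp on
    the 1-based inclusive convention.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, row in known.iterrows():
        # half-open tree interval [start, end+1) over 1-based inclusive bounds
        trees.setdefault(str(row["chromosome"]), IntervalTree()).addi(
            int(row["start_bp"]), int(row["end_bp"]) + 1, (idx, row["label"])
        )
    rows = []
    for r in regions:
        tree = trees.get(str(r.chromosome))
        if tree is None:
            continue
        for hit in sorted(tree.overlap(r.start_bp, r.end_bp + 1)):
            idx, label = hit.data
            ov = min(r.end_bp, hit.end - 1) - max(r.start_bp, hit.begin) + 1
            rows.append(
                (r.source, r.chromosome, r.start_bp, r.end_bp, r.top_marker,
                 label, hit.begin, hit.end - 1, ov)
            )
    return pd.DataFrame(
        rows,
        columns=["source", "chromosome", "region_start_bp", "region_end_bp",
                 "top_marker", "known_label", "known_start_bp", "known_end_bp",
                 "overlap_bp"],
    )
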
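"""End-to-end orchestration: read inputs, run every stage, write provenance-stamped outputs.

The pipeline runs, in dependency order: gene-level CNA calling →
clonal/subclonal classification (with tree mapping) → cohort summary for
the focus gene → genome-wide frequency track, permutation null and
recurrent regions → association statistics (expression screen,
driver-status × clonality chi-squared, clonal vs subclonal segment-size
rank test) → FISH core scoring.  Optional inputs switch their stages off.

Every output TSV carries a comment line with the tool version, a hash of
the full configuration and the seed; ``manifest.json`` lists all outputs
with SHA-256 checksums, so a rerun with the same config is verifiably
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__, io_formats
from .association_stats import chi_squared_test, cna_expression_screen, wilcoxon_rank_test
from .clonality import STATUS_CLONAL, STATUS_SUBCLONAL, classify_cohort, summarize_cohort
from .cna_calling import Thresholds, call_genes
from .errors import ValidationError
from .fish_scoring import score_cores, summarize_tma
from .genome import GenomeModel, default_genome, hg38_genome
from .recurrence import call_recurrent_regions, gain_loss_frequency, permutation_null

log = logging.getLogger("clonecna")

__all__ = ["PipelineConfig", "run_pipeline", "read_trees_file", "config_hash"]


@dataclasses.dataclass
class PipelineConfig:
    """Inputs, thresholds and switches for one pipeline run."""

    segments: str = ""
    region_meta: str = ""
    genes: str = ""
    trees: str | None = None
    expression: str | None = None
    driver_status: str | None = None
    fish_cells: str | None = None
    out_dir: str = "clonecna_out"

    genome: str = "infer"  # "infer" | "default" | "hg38"
    segment_dialect: str = io_formats.SEG_1BASED_INCLUSIVE
    gain_log_ratio: float = Thresholds().gain_log_ratio
    high_gain_log_ratio: float = Thresholds().high_gain_log_ratio
    loss_log_ratio: float = Thresholds().loss_log_ratio
    focal_max_len: int = Thresholds().focal_max_len
    bin_size: int = 1_000_000
    permutations: int = 1_000
    seed: int = 17
    focus_gene: str = "MCL1"
    fish_min_cells: int = 20

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"config: unknown key(s) {', '.join(sorted(bad))}")
        return cls(**raw)

    def thresholds(self) -> Thresholds:
        return Thresholds(self.gain_log_ratio, self.high_gain_log_ratio,
                          self.loss_log_ratio, self.focal_max_len)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _infer_genome(segments: pd.DataFrame) -> GenomeModel:
    lengths = segments.groupby("chromosome", sort=True)["end"].max()
    return GenomeModel(tuple(lengths.index), tuple(int(v) for v in lengths))


def resolve_genome(name: str, segments: pd.DataFrame | None = None) -> GenomeModel:
    if name == "default":
        return default_genome()
    if name == "hg38":
        return hg38_genome()
    if name == "infer":
        if segments is None or segments.empty:
            raise ValidationError("genome=infer needs a non-empty segment table")
        return _infer_genome(segments)
    raise ValidationError(f"unknown genome {name!r} (expected infer, default or hg38)")


def read_trees_file(path: str, meta: pd.DataFrame) -> dict:
    """Read a file of newick trees (one per line); assign each to its tumour.

    The tumour is identified from the leaf labels, which must be region ids
    of exactly one tumour, and must be that tumour's full region set.
    """
    tumour_of = meta.set_index("region_id")["tumour_id"]
    regions_of = meta.groupby("tumour_id")["region_id"].apply(set)
    trees = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tree = io_formats.read_tree(line)
            leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
            tumours = {tumour_of.get(l) for l in leaves}
            if None in tumours or len(tumours) != 1:
                raise ValidationError(f"trees: line {lineno}: leaves map to {len(tumours)} tumours")
            (tumour,) = tumours
            if leaves != regions_of[tumour]:
                missing = sorted(regions_of[tumour] - leaves)
                raise ValidationError(
                    f"trees: line {lineno}: tree for {tumour} missing regions {', '.join(missing)}"
                )
            trees[tumour] = tree
    return trees


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the in-memory result bundle.

    The bundle maps stage names to DataFrames / result objects; everything
    is also written under ``config.out_dir``.
    """
    t0 = time.monotonic()
    os.makedirs(config.out_dir, exist_ok=True)
    chash = config_hash(config)
    th = config.thresholds()
    results: dict = {}
    outputs: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame, index=False):
        path = os.path.join(config.out_dir, name)
        io_formats.write_table(df, path, config_hash=chash, seed=config.seed, index=index)
        outputs[name] = path

    def stage(name):
        log.info("stage %-12s t=%.2fs", name, time.monotonic() - t0)

    stage("read")
    segments = io_formats.read_segment_table(config.segments, dialect=config.segment_dialect)
    if segments.empty:
        raise ValidationError(f"io_formats: segment table {config.segments!r} has no rows")
    meta = io_formats.read_region_meta(config.region_meta)
    genome = resolve_genome(config.genome, segments)
    loci = io_formats.read_gene_loci(config.genes, genome=genome)

    stage("call")
    gene_calls = call_genes(segments, meta, loci, th)
    emit("gene_calls.tsv", gene_calls)
    results["gene_calls"] = gene_calls

    stage("clonality")
    trees = read_trees_file(config.trees, meta) if config.trees else None
    clon = classify_cohort(gene_calls, trees)
    emit("clonality.tsv", clon)
    results["clonality"] = clon
    if (clon["gene"] == config.focus_gene).any():
        summary = summarize_cohort(clon, config.focus_gene)
        emit("cohort_summary.tsv", summary.to_frame())
        results["cohort_summary"] = summary

    stage("recurrence")
    track = gain_loss_frequency(segments, meta, genome, config.bin_size, th)
    null = permutation_null(segments, meta, genome, config.bin_size,
                            B=config.permutations, seed=config.seed, thresholds=th)
    regions = call_recurrent_regions(track, null)
    emit("frequency_track.tsv", track.to_frame())
    emit("recurrence_thresholds.tsv", pd.DataFrame([{
        "gain_threshold": null.gain_threshold, "loss_threshold": null.loss_threshold,
        "permutations": null.B, "bin_size": null.bin_size, "seed": null.seed,
    }]))
    emit("recurrent_regions.tsv", regions)
    results.update(track=track, null=null, recurrent_regions=regions)

    stage("associate")
    if config.expression:
        expr = io_formats.read_expression_table(config.expression)
        screen = cna_expression_screen(gene_calls, expr)
        emit("expression_screen.tsv", screen)
        results["expression_screen"] = screen
    if config.driver_status:
        driver = io_formats.read_driver_status(config.driver_status)
        assoc = driver_clonality_association(clon, driver, config.focus_gene)
        emit("driver_association.tsv", assoc)
        results["driver_association"] = assoc
    sizes = segment_size_comparison(clon, gene_calls, config.focus_gene)
    if sizes is not None:
        emit("segment_size_test.tsv", sizes)
        results["segment_size_test"] = sizes

    if config.fish_cells:
        stage("fish")
        cells = io_formats.read_fish_cells(config.fish_cells)
        calls = score_cores(cells, min_cells=config.fish_min_cells)
        emit("fish_calls.tsv", calls)
        emit("fish_summary.tsv", summarize_tma(calls).to_frame())
        results["fish_calls"] = calls
        results["fish_summary"] = summarize_tma(calls)

    manifest = {
        "tool": "clonecna", "version": __version__, "config_hash": chash,
        "seed": config.seed, "config": config.to_dict(),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    io_formats.atomic_write(os.path.join(config.out_dir, "manifest.json"),
                            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    stage("done")
    return results


def driver_clonality_association(clonality: pd.DataFrame, driver: pd.DataFrame,
                                 focus_gene: str) -> pd.DataFrame:
    """Driver status × focus-gene clonality contingency table and chi-squared test.

    Rows are driver statuses, columns the gain categories absent /
    subclonal / clonal; the Pearson chi-squared test (with continuity
    correction where defined, i.e. 2 × 2) is reported alongside the table.
    """
    clon = clonality[clonality["gene"] == focus_gene][["tumour_id", "status"]]
    merged = clon.merge(driver[["tumour_id", "status"]].rename(columns={"status": "driver"}),
                        on="tumour_id", how="inner")
    if merged.empty:
        raise ValidationError("driver association: no tumours shared between tables")
    table = pd.crosstab(merged["driver"], merged["status"])
    for col in ("absent", "subclonal", "clonal"):
        if col not in table.columns:
            table[col] = 0
    table = table[[c for c in ("absent", "subclonal", "clonal") if c in table.columns]]
    table = table.loc[:, table.sum(axis=0) > 0]
    res = chi_squared_test(table.to_numpy(), continuity=True)
    out = table.reset_index().rename(columns={"driver": "driver_status"})
    out["chi2"] = res.chi2
    out["df"] = res.df
    out["p_value"] = res.p_value
    out["continuity_corrected"] = res.continuity_corrected
    return out


def segment_size_comparison(clonality: pd.DataFrame, gene_calls: pd.DataFrame,
                            focus_gene: str):
    """Two-sided rank test of supporting-segment sizes, clonal vs subclonal gains.

    Uses each gained region's supporting-segment length for the focus gene.
    Returns None when either group is empty.
    """
    clon = clonality[clonality["gene"] == focus_gene]
    status_of = clon.set_index("tumour_id")["status"]
    calls = gene_calls[(gene_calls["gene"] == focus_gene)
                       & gene_calls["state"].isin(("gain", "high_gain"))].copy()
    calls["status"] = status_of.reindex(calls["tumour_id"]).to_numpy()
    sizes = calls["seg_end"] - calls["seg_start"]
    clonal = sizes[calls["status"] == STATUS_CLONAL].to_numpy(dtype=float)
    subclonal = sizes[calls["status"] == STATUS_SUBCLONAL].to_numpy(dtype=float)
    if clonal.size == 0 or subclonal.size == 0:
        return None
    res = wilcoxon_rank_test(clonal, subclonal, alternative="two_sided")
    return pd.DataFrame([{
        "gene": focus_gene, "n_clonal_segments": res.n1, "n_subclonal_segments": res.n2,
        "W": res.statistic, "p_value": res.p_value, "method": res.method,
        "median_clonal": float(np.median(clonal)), "median_subclonal": float(np.median(subclonal)),
    }])
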
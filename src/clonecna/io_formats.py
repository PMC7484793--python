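"""Readers and writers for every external file the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is **0-based half-open** so that length is always
``end - start``.  Segment tables (SEG dialect) default to 1-based inclusive
coordinates on disk, the convention of the SEG format; BED files are 0-based
half-open.  The dialect is explicit in every read/write call — nothing is
guessed from file content.

Chromosome names are taken verbatim: ``"1"`` and ``"chr1"`` are different
chromosomes unless the caller supplies a ``chrom_aliases`` mapping.

All tables written by this module carry a single comment line recording the
tool version, a configuration hash and the seed, so that any output file can
be traced back to the run that produced it.  Readers skip ``#`` comment
lines.
"""

from __future__ import annotations

import io
import os
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError, ValidationError
from .genome import GenomeModel

__all__ = [
    "SEG_1BASED_INCLUSIVE",
    "BED_0BASED_HALFOPEN",
    "read_segment_table",
    "write_segment_table",
    "read_region_meta",
    "write_region_meta",
    "read_gene_loci",
    "write_gene_loci",
    "read_expression_table",
    "write_expression_table",
    "read_driver_status",
    "write_driver_status",
    "read_fish_cells",
    "write_fish_cells",
    "read_tree",
    "write_table",
    "provenance_header",
    "atomic_write",
]

SEG_1BASED_INCLUSIVE = "seg_1based_inclusive"
BED_0BASED_HALFOPEN = "bed_0based_halfopen"
_DIALECTS = (SEG_1BASED_INCLUSIVE, BED_0BASED_HALFOPEN)

SEGMENT_COLUMNS = ["region_id", "chromosome", "start", "end", "total_cn"]
# "sample" is the customary first-column name of SEG files.
_REGION_ALIASES = {"sample": "region_id", "region": "region_id", "id": "region_id"}

DRIVER_STATUSES = ("wild_type", "clonal_mutant", "subclonal_mutant")


# ---------------------------------------------------------------------------
# provenance / atomic writing


def provenance_header(config_hash: str = "-", seed: int | str = "-") -> str:
    return f"# clonecna={__version__}\tconfig_hash={config_hash}\tseed={seed}"


def atomic_write(path: str | os.PathLike, text: str) -> None:
    """Write-then-rename so a failed run never leaves a truncated output."""
    path = os.fspath(path)
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def write_table(
    df: pd.DataFrame,
    path: str | os.PathLike,
    *,
    config_hash: str = "-",
    seed: int | str = "-",
    index: bool = False,
    float_format: str = "%.6g",
) -> None:
    """Write a TSV with the standard provenance comment line."""
    buf = io.StringIO()
    buf.write(provenance_header(config_hash, seed) + "\n")
    df.to_csv(buf, sep="\t", index=index, float_format=float_format)
    atomic_write(path, buf.getvalue())


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


# ---------------------------------------------------------------------------
# segment tables


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {', '.join(missing)}")


def read_segment_table(
    path: str | os.PathLike,
    dialect: str = SEG_1BASED_INCLUSIVE,
    genome: GenomeModel | None = None,
    chrom_aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read per-region absolute copy-number segments.

    Returns a DataFrame with columns ``region_id, chromosome, start, end,
    total_cn`` in internal 0-based half-open coordinates, sorted by
    (region_id, chromosome, start).  Overlapping segments within one region
    are an error: a region's segments are expected to partition (a subset
    of) the genome.
    """
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown coordinate dialect {dialect!r}")
    df = _read_tsv(path)
    df = df.rename(columns={c: _REGION_ALIASES.get(c.lower(), c) for c in df.columns})
    _require_columns(df, SEGMENT_COLUMNS, "segment table")
    df = df[SEGMENT_COLUMNS].copy()
    df["region_id"] = df["region_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    if chrom_aliases:
        df["chromosome"] = df["chromosome"].map(lambda c: chrom_aliases.get(c, c))
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["total_cn"] = df["total_cn"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"segment table: non-numeric coordinate or copy number ({exc})")
    if dialect == SEG_1BASED_INCLUSIVE:
        df["start"] = df["start"] - 1  # end stays: 1-based inclusive end == half-open end
    return validate_segments(df, genome)


def validate_segments(df: pd.DataFrame, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Validate internal-coordinate segments; returns them sorted."""
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValidationError(f"segment table: start >= end after normalisation at row {bad[0]}")
    if (df["total_cn"] < 0).any():
        row = df.index[df["total_cn"] < 0][0]
        raise ValidationError(f"segment table: negative total_cn at row {row}")
    if genome is not None:
        unknown = sorted(set(df["chromosome"]) - set(genome.names))
        if unknown:
            raise ValidationError(f"segment table: unknown chromosome(s) {', '.join(unknown)}")
        for chrom, sub in df.groupby("chromosome", sort=False):
            if (sub["end"] > genome.length_of(str(chrom))).any():
                raise ValidationError(f"segment table: segment beyond end of {chrom}")
    df = df.sort_values(["region_id", "chromosome", "start"], kind="mergesort").reset_index(drop=True)
    same = (df["region_id"] == df["region_id"].shift()) & (df["chromosome"] == df["chromosome"].shift())
    overlap = same & (df["start"] < df["end"].shift())
    if overlap.any():
        i = int(np.flatnonzero(overlap)[0])
        r = df.iloc[i]
        raise ValidationError(
            f"segment table: overlapping segments in region {r.region_id!r} on "
            f"{r.chromosome} near position {int(r.start)}"
        )
    return df


def write_segment_table(
    df: pd.DataFrame,
    path: str | os.PathLike,
    dialect: str = SEG_1BASED_INCLUSIVE,
    *,
    config_hash: str = "-",
    seed: int | str = "-",
) -> None:
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown coordinate dialect {dialect!r}")
    out = df[SEGMENT_COLUMNS].copy()
    if dialect == SEG_1BASED_INCLUSIVE:
        out["start"] = out["start"] + 1
    write_table(out, path, config_hash=config_hash, seed=seed)


# ---------------------------------------------------------------------------
# region metadata


def read_region_meta(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_tsv(path)
    df = df.rename(columns={c: _REGION_ALIASES.get(c.lower(), c) for c in df.columns})
    _require_columns(df, ["region_id", "tumour_id", "ploidy"], "region metadata")
    df = df[["region_id", "tumour_id", "ploidy"]].copy()
    df["region_id"] = df["region_id"].astype(str)
    df["tumour_id"] = df["tumour_id"].astype(str)
    df["ploidy"] = df["ploidy"].astype(float)
    if (df["ploidy"] <= 0).any():
        raise ValidationError("region metadata: ploidy must be > 0")
    if df["region_id"].duplicated().any():
        dup = df.loc[df["region_id"].duplicated(), "region_id"].iloc[0]
        raise ValidationError(f"region metadata: duplicated region_id {dup!r}")
    return df.reset_index(drop=True)


def write_region_meta(df: pd.DataFrame, path, **kw) -> None:
    write_table(df[["region_id", "tumour_id", "ploidy"]], path, **kw)


# ---------------------------------------------------------------------------
# gene loci (BED4)


def read_gene_loci(path: str | os.PathLike, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Read a ≥4-column BED (0-based half-open) of gene loci."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"gene loci: line {lineno}: expected >=4 BED columns, got {len(parts)}")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"gene loci: line {lineno}: non-integer coordinates")
            if start_i >= end_i:
                raise ValidationError(f"gene loci: line {lineno}: start >= end")
            rows.append((name, chrom, start_i, end_i))
    loci = pd.DataFrame(rows, columns=["name", "chromosome", "start", "end"])
    if loci["name"].duplicated().any():
        dup = loci.loc[loci["name"].duplicated(), "name"].iloc[0]
        raise ValidationError(f"gene loci: duplicated gene name {dup!r}")
    if genome is not None:
        for r in loci.itertuples():
            genome.validate_interval(r.chromosome, r.start, r.end)
    return loci


def write_gene_loci(loci: pd.DataFrame, path) -> None:
    out = loci[["chromosome", "start", "end", "name"]]
    atomic_write(path, out.to_csv(sep="\t", index=False, header=False))


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample/region × gene TPM matrix; empty cells stay NaN (absent)."""
    with open(path) as fh:
        header = ""
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n")
                break
    cols = header.split("\t")[1:]
    dups = {c for c in cols if cols.count(c) > 1}
    if dups:
        raise FormatError(f"expression table: duplicated gene column {sorted(dups)[0]!r}")
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"expression table: duplicated sample row {dup!r}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"expression table: non-numeric value ({exc})")
    if (df < 0).any().any():
        raise ValidationError("expression table: negative TPM value")
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return df


def write_expression_table(df: pd.DataFrame, path, **kw) -> None:
    write_table(df, path, index=True, **kw)


# ---------------------------------------------------------------------------
# driver status


def read_driver_status(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ["tumour_id", "gene", "status"], "driver status")
    df = df[["tumour_id", "gene", "status"]].astype(str)
    df["status"] = df["status"].str.replace("-", "_").str.replace(" ", "_")
    bad = sorted(set(df["status"]) - set(DRIVER_STATUSES))
    if bad:
        raise ValidationError(
            f"driver status: unknown status value(s) {', '.join(bad)}; "
            f"expected one of {', '.join(DRIVER_STATUSES)}"
        )
    return df.reset_index(drop=True)


def write_driver_status(df: pd.DataFrame, path, **kw) -> None:
    write_table(df[["tumour_id", "gene", "status"]], path, **kw)


# ---------------------------------------------------------------------------
# FISH per-cell counts


def read_fish_cells(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ["core_id", "cell_id", "target_signals", "reference_signals"], "FISH cells")
    df = df[["core_id", "cell_id", "target_signals", "reference_signals"]].copy()
    df["core_id"] = df["core_id"].astype(str)
    try:
        df["target_signals"] = df["target_signals"].astype(np.int64)
        df["reference_signals"] = df["reference_signals"].astype(np.int64)
    except (TypeError, ValueError):
        raise FormatError("FISH cells: signal counts must be integers")
    if (df[["target_signals", "reference_signals"]] < 0).any().any():
        raise ValidationError("FISH cells: negative signal count")
    return df.reset_index(drop=True)


def write_fish_cells(df: pd.DataFrame, path, **kw) -> None:
    write_table(df[["core_id", "cell_id", "target_signals", "reference_signals"]], path, **kw)


# ---------------------------------------------------------------------------
# phylogenies


def read_tree(
    path_or_newick: str | os.PathLike,
    expected_regions: Iterable[str] | None = None,
) -> dendropy.Tree:
    """Read a rooted newick tree whose leaf labels are region ids.

    ``path_or_newick`` may be a file path or a literal newick string (ending
    in ``;``).  When ``expected_regions`` is given the leaf set must equal it
    exactly; the error message lists the offending labels on either side.
    """
    s = os.fspath(path_or_newick)
    if s.strip().endswith(";"):
        src = {"data": s}
    else:
        src = {"path": s}
    try:
        tree = dendropy.Tree.get(**src, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises its own hierarchy
        raise FormatError(f"tree: cannot parse newick ({exc})")
    tree.is_rooted = True
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if expected_regions is not None:
        expected = set(map(str, expected_regions))
        extra, missing = sorted(leaves - expected), sorted(expected - leaves)
        if extra or missing:
            raise ValidationError(
                "tree: leaf labels do not match regions"
                + (f"; unexpected leaves: {', '.join(extra)}" if extra else "")
                + (f"; missing regions: {', '.join(missing)}" if missing else "")
            )
    return tree
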
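"""Seeded synthetic multi-region cohorts with a planted ground-truth ledger.

The generator emulates the statistical structure the analysis assumes:

* per tumour, a small number of sequenced regions related by a (caterpillar)
  phylogeny;
* gene-anchored copy-number gain events that are either *truncal* (present
  in every region) or *branch* (present exactly in the leaves below one
  randomly chosen non-trunk edge), with focal (exponential, mean 5 Mb) or
  broad (arm-scale) lengths and integer copy numbers;
* optional coupling of the focus gene's *subclonal* gain probability to a
  driver gene's mutation status (e.g. elevated subclonal-gain probability
  in TP53-mutant tumours);
* dosage-coupled expression: ``log2 TPM = log2(baseline) + beta *
  log2(cn / ploidy) + Normal(0, sigma)``;
* per-cell dual-colour FISH signal counts, Poisson per cell with core-level
  means set by the planted category.

Everything is driven by one :class:`numpy.random.Generator`; identical
config + seed give byte-identical output files.  The *truth ledger* records,
for every tumour × gene, the planted status, gain level, focality and tree
edge, which is what lets the test-suite check that the pipeline recovers
100% of planted labels on noise-free cohorts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io_formats
from .cna_calling import STATE_HIGH_GAIN, Thresholds, classify_state
from .clonality import TRUNK
from .errors import ValidationError
from .genome import GenomeModel, default_genome

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_uniform_gain_cohort",
    "simulate_fish_cores",
    "make_fixture",
    "FIXTURES",
    "default_loci",
]


def default_loci() -> pd.DataFrame:
    """Three gene loci, one per chromosome of the desk-scale genome.

    One gene per chromosome keeps planted events for different genes from
    overlapping, so the truth ledger stays exact.
    """
    return pd.DataFrame({
        "name": ["MCL1", "GENE_B", "GENE_C"],
        "chromosome": ["chr1", "chr2", "chr3"],
        "start": [50_000_000, 40_000_000, 30_000_000],
        "end": [50_005_000, 40_005_000, 30_005_000],
    })


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    ``regions_per_tumour`` is an int or an inclusive (min, max) range.
    When ``subclonal_gain_prob_mutant``/``_wildtype`` are both set, they
    replace ``branch_gain_prob`` for the focus gene according to the
    tumour's driver status.
    """

    seed: int = 0
    n_tumours: int = 30
    regions_per_tumour: int | tuple[int, int] = (2, 5)
    ploidy: float = 2.0
    truncal_gain_prob: float = 0.5
    branch_gain_prob: float = 0.2
    gain_copy_numbers: tuple[int, ...] = (3, 4, 5, 6)
    loss_prob: float = 0.3
    loss_copy_number: int = 1
    loss_len_mean: float = 10e6
    focal_fraction: float = 0.7
    focal_len_mean: float = 5e6
    focus_gene: str = "MCL1"
    driver_gene: str = "TP53"
    driver_mutant_prob: float = 0.5
    subclonal_gain_prob_mutant: float | None = None
    subclonal_gain_prob_wildtype: float | None = None
    tpm_baseline: float = 50.0
    dosage_slope: float = 1.0
    expression_sigma: float = 0.5
    with_expression: bool = True
    with_fish: bool = True
    polysomy_prob: float = 0.1
    fish_cells_range: tuple[int, int] = (20, 60)
    genome: GenomeModel = field(default_factory=default_genome)

    def validate(self, loci: pd.DataFrame) -> None:
        for p in (self.truncal_gain_prob, self.branch_gain_prob, self.loss_prob,
                  self.driver_mutant_prob, self.focal_fraction, self.polysomy_prob):
            if not 0 <= p <= 1:
                raise ValidationError("sim config: probabilities must be in [0, 1]")
        if self.ploidy <= 0:
            raise ValidationError("sim config: ploidy must be > 0")
        if self.expression_sigma <= 0:
            raise ValidationError("sim config: expression_sigma must be > 0")
        lo, hi = self._region_range()
        if lo < 1:
            raise ValidationError("sim config: tumours need at least one region")
        if hi < 2 and (self.branch_gain_prob > 0 or self.subclonal_gain_prob_mutant):
            raise ValidationError("sim config: branch events need >= 2 regions per tumour")
        if (self.subclonal_gain_prob_mutant is None) != (self.subclonal_gain_prob_wildtype is None):
            raise ValidationError("sim config: set both driver-coupling probabilities or neither")
        if not any(cn / self.ploidy > 2.5 / 2 for cn in self.gain_copy_numbers):
            raise ValidationError("sim config: no gain copy number exceeds the gain threshold at this ploidy")
        for r in loci.itertuples(index=False):
            self.genome.validate_interval(r.chromosome, r.start, r.end)
        min_chrom = min(self.genome.lengths)
        if self.focal_len_mean >= min_chrom:
            raise ValidationError("sim config: focal length mean exceeds a chromosome length")

    def _region_range(self) -> tuple[int, int]:
        if isinstance(self.regions_per_tumour, int):
            return self.regions_per_tumour, self.regions_per_tumour
        lo, hi = self.regions_per_tumour
        return int(lo), int(hi)


def _caterpillar_newick(regions: list[str]) -> str:
    if len(regions) == 1:
        return f"({regions[0]});"
    node = f"({regions[0]},{regions[1]})"
    for r in regions[2:]:
        node = f"({node},{r})"
    return node + ";"


def _branch_edges(regions: list[str]) -> list[tuple[str, ...]]:
    """Leaf sets below every non-trunk edge of the caterpillar tree."""
    edges: list[tuple[str, ...]] = [(r,) for r in regions]
    for k in range(2, len(regions)):
        edges.append(tuple(regions[:k]))
    return edges


def _edge_label(leafset: tuple[str, ...], all_regions: list[str]) -> str:
    if set(leafset) == set(all_regions):
        return TRUNK
    if len(leafset) == 1:
        return leafset[0]
    return "|".join(sorted(leafset))


def _piecewise(chrom_len: int, base_cn: float, gains, losses):
    """Partition [0, chrom_len) into segments: gains override losses override base."""
    pts = {0, chrom_len}
    for s, e, _ in gains:
        pts.update((s, e))
    for s, e, _ in losses:
        pts.update((s, e))
    pts = sorted(p for p in pts if 0 <= p <= chrom_len)
    segs: list[list] = []
    for a, b in zip(pts, pts[1:]):
        cn = base_cn
        for s, e, c in losses:
            if s <= a and b <= e:
                cn = c
        for s, e, c in gains:
            if s <= a and b <= e:
                cn = max(cn, c) if cn != base_cn else c
        if segs and segs[-1][2] == cn:
            segs[-1][1] = b
        else:
            segs.append([a, b, cn])
    return [(int(a), int(b), float(c)) for a, b, c in segs]


def _draw_event_interval(rng, cfg: SimConfig, locus, focal: bool) -> tuple[int, int]:
    """An interval covering the locus, of focal (exp mean) or broad (arm-scale) length."""
    chrom_len = cfg.genome.length_of(locus.chromosome)
    gene_len = locus.end - locus.start
    if focal:
        max_len = min(int(Thresholds().focal_max_len) - 1, chrom_len)
        length = int(rng.exponential(cfg.focal_len_mean))
        length = int(np.clip(length, gene_len + 2, max_len))
    else:
        lo = min(int(Thresholds().focal_max_len), chrom_len)
        length = int(rng.integers(lo, chrom_len + 1))
    lo_start = max(0, locus.end - length)
    hi_start = min(locus.start, chrom_len - length)
    if hi_start < lo_start:  # length >= chrom_len: cover everything
        return 0, chrom_len
    start = int(rng.integers(lo_start, hi_start + 1))
    return start, start + length


@dataclass
class SimulatedCohort:
    """All generated tables plus the planted-truth ledger."""

    config: SimConfig
    loci: pd.DataFrame
    segments: pd.DataFrame  # internal 0-based half-open
    meta: pd.DataFrame
    trees: dict[str, str]  # tumour_id -> newick
    truth: pd.DataFrame
    expression: pd.DataFrame | None = None
    driver_status: pd.DataFrame | None = None
    fish_cells: pd.DataFrame | None = None
    fish_truth: pd.DataFrame | None = None

    @property
    def genome(self) -> GenomeModel:
        return self.config.genome

    def tree_objects(self) -> dict:
        regions_of = self.meta.groupby("tumour_id")["region_id"].apply(list)
        return {
            t: io_formats.read_tree(nwk, expected_regions=regions_of[t])
            for t, nwk in self.trees.items()
        }

    def write(self, out_dir: str | os.PathLike, config_hash: str = "-") -> dict[str, str]:
        """Write every table in the formats the readers expect; returns path map."""
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        seed = self.config.seed
        paths = {}

        def p(name):
            paths[name] = os.path.join(out_dir, name)
            return paths[name]

        io_formats.write_segment_table(self.segments, p("segments.seg.tsv"),
                                       config_hash=config_hash, seed=seed)
        io_formats.write_region_meta(self.meta, p("region_meta.tsv"),
                                     config_hash=config_hash, seed=seed)
        io_formats.write_gene_loci(self.loci, p("genes.bed"))
        io_formats.atomic_write(
            p("trees.nwk"),
            "".join(self.trees[t] + "\n" for t in sorted(self.trees)),
        )
        if self.expression is not None:
            io_formats.write_expression_table(self.expression, p("expression.tsv"),
                                              config_hash=config_hash, seed=seed)
        if self.driver_status is not None:
            io_formats.write_driver_status(self.driver_status, p("driver_status.tsv"),
                                           config_hash=config_hash, seed=seed)
        if self.fish_cells is not None:
            io_formats.write_fish_cells(self.fish_cells, p("fish_cells.tsv"),
                                        config_hash=config_hash, seed=seed)
        io_formats.write_table(self.truth, p("truth.tsv"), config_hash=config_hash, seed=seed)
        return paths


def simulate_cohort(config: SimConfig = SimConfig(), loci: pd.DataFrame | None = None) -> SimulatedCohort:
    """Generate a full multi-region cohort under ``config``; see module docstring."""
    loci = default_loci() if loci is None else loci.reset_index(drop=True)
    config.validate(loci)
    rng = np.random.default_rng(config.seed)
    th = Thresholds()
    lo_r, hi_r = config._region_range()
    base_cn = float(round(config.ploidy))
    usable_cns = [cn for cn in config.gain_copy_numbers if cn / config.ploidy > 2.5 / 2]

    seg_rows, meta_rows, truth_rows, expr_rows, driver_rows = [], [], [], [], []
    trees: dict[str, str] = {}
    focus_level_by_tumour: dict[str, str] = {}

    for t_i in range(config.n_tumours):
        tumour = f"T{t_i + 1:03d}"
        n_regions = int(rng.integers(lo_r, hi_r + 1)) if lo_r != hi_r else lo_r
        regions = [f"{tumour}_R{j + 1}" for j in range(n_regions)]
        trees[tumour] = _caterpillar_newick(regions)
        for r in regions:
            meta_rows.append((r, tumour, config.ploidy))

        mutant = bool(rng.random() < config.driver_mutant_prob)
        driver_rows.append((tumour, config.driver_gene,
                            "clonal_mutant" if mutant else "wild_type"))

        # decide per-gene events
        gains_by_region: dict[str, dict[str, list]] = {r: {} for r in regions}  # region -> chrom -> [(s,e,cn)]
        gene_cn_by_region: dict[tuple[str, str], float] = {}
        tumour_gain_ivs: list[tuple[str, int, int]] = []
        edges = _branch_edges(regions)
        for locus in loci.itertuples(index=False):
            p_branch = config.branch_gain_prob
            if locus.name == config.focus_gene and config.subclonal_gain_prob_mutant is not None:
                p_branch = (config.subclonal_gain_prob_mutant if mutant
                            else config.subclonal_gain_prob_wildtype)
            status, level, focality, edge_label = "absent", "none", "", ""
            ev = None
            if rng.random() < config.truncal_gain_prob:
                ev_regions = list(regions)
                edge_label = TRUNK if n_regions > 1 else TRUNK
                status = "clonal"
                ev = True
            elif n_regions >= 2 and rng.random() < p_branch:
                leafset = edges[int(rng.integers(len(edges)))]
                ev_regions = list(leafset)
                edge_label = _edge_label(leafset, regions)
                status = "subclonal"
                ev = True
            if ev:
                cn = float(usable_cns[int(rng.integers(len(usable_cns)))])
                focal = bool(rng.random() < config.focal_fraction)
                s, e = _draw_event_interval(rng, config, locus, focal)
                focality = "focal" if (e - s) < th.focal_max_len else "broad"
                state = classify_state(np.log2(cn / config.ploidy), th)
                level = "high" if state == STATE_HIGH_GAIN else "low"
                tumour_gain_ivs.append((locus.chromosome, s, e))
                for r in ev_regions:
                    gains_by_region[r].setdefault(locus.chromosome, []).append((s, e, cn))
                    gene_cn_by_region[(r, locus.name)] = cn
            for r in regions:
                gene_cn_by_region.setdefault((r, locus.name), base_cn)
            truth_rows.append({
                "tumour_id": tumour, "gene": locus.name, "status": status,
                "level": level, "focality": focality, "tree_edge": edge_label,
            })
            if locus.name == config.focus_gene:
                focus_level_by_tumour[tumour] = level

        # one optional truncal loss per tumour, kept clear of gene loci and gains
        losses: list[tuple[str, int, int]] = []
        if rng.random() < config.loss_prob:
            for _ in range(50):
                ci = int(rng.integers(len(config.genome.names)))
                chrom = config.genome.names[ci]
                chrom_len = config.genome.lengths[ci]
                length = int(np.clip(int(rng.exponential(config.loss_len_mean)), 1_000_000, chrom_len))
                start = int(rng.integers(0, chrom_len - length + 1))
                iv = (chrom, start, start + length)
                blocked = [(l.chromosome, l.start, l.end) for l in loci.itertuples(index=False)]
                blocked += tumour_gain_ivs
                if not any(c == chrom and start < e and (start + length) > s for c, s, e in blocked):
                    losses.append(iv)
                    break

        for r in regions:
            for ci, chrom in enumerate(config.genome.names):
                gains = gains_by_region[r].get(chrom, [])
                loss_ivs = [(s, e, float(config.loss_copy_number))
                            for c, s, e in losses if c == chrom]
                for s, e, cn in _piecewise(config.genome.lengths[ci], base_cn, gains, loss_ivs):
                    seg_rows.append((r, chrom, s, e, cn))

        if config.with_expression:
            for r in regions:
                row = {"sample": r}
                for locus in loci.itertuples(index=False):
                    cn = gene_cn_by_region[(r, locus.name)]
                    lr = np.log2(cn / config.ploidy)
                    log2tpm = (np.log2(config.tpm_baseline) + config.dosage_slope * lr
                               + rng.normal(0.0, config.expression_sigma))
                    row[locus.name] = float(2.0 ** log2tpm)
                expr_rows.append(row)

    segments = pd.DataFrame(seg_rows, columns=["region_id", "chromosome", "start", "end", "total_cn"])
    segments = io_formats.validate_segments(segments, config.genome)
    meta = pd.DataFrame(meta_rows, columns=["region_id", "tumour_id", "ploidy"])
    truth = pd.DataFrame(truth_rows)
    expression = None
    if config.with_expression:
        expression = pd.DataFrame(expr_rows).set_index("sample")
    driver_status = pd.DataFrame(driver_rows, columns=["tumour_id", "gene", "status"])

    fish_cells = fish_truth = None
    if config.with_fish:
        categories = []
        for tumour in sorted(focus_level_by_tumour):
            level = focus_level_by_tumour[tumour]
            if level == "high":
                cat = "high_level_gain"
            elif level == "low":
                cat = "low_level_gain"
            elif rng.random() < config.polysomy_prob:
                cat = "polysomy"
            else:
                cat = "no_gain"
            categories.append(cat)
        fish_cells, fish_truth = simulate_fish_cores(
            categories, rng=rng, cells_range=config.fish_cells_range,
            core_ids=[f"core_{t}" for t in sorted(focus_level_by_tumour)],
        )

    return SimulatedCohort(
        config=config, loci=loci, segments=segments, meta=meta, trees=trees,
        truth=truth, expression=expression, driver_status=driver_status,
        fish_cells=fish_cells, fish_truth=fish_truth,
    )


# core-level (target mean, reference mean) per planted FISH category; means
# sit at the centre of each ratio category (no_gain ~1, LLG ~3, HLG ~5) so
# Poisson noise over >=20 cells rarely crosses a boundary
_FISH_MEANS = {
    "high_level_gain": (10.0, 2.0),
    "low_level_gain": (6.0, 2.0),
    "polysomy": (3.8, 3.5),
    "no_gain": (2.0, 2.0),
}


def simulate_fish_cores(categories, seed: int | None = None, rng=None,
                        cells_range=(20, 60), core_ids=None):
    """Per-cell Poisson signal counts for cores with planted categories.

    Returns ``(cells, truth)`` where cells matches the FISH per-cell input
    format and truth records the planted category per core.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows, truth = [], []
    for i, cat in enumerate(categories):
        if cat not in _FISH_MEANS:
            raise ValidationError(f"unknown FISH category {cat!r}")
        core = core_ids[i] if core_ids else f"core_{i + 1:03d}"
        n_cells = int(rng.integers(cells_range[0], cells_range[1] + 1))
        mt, mr = _FISH_MEANS[cat]
        t = rng.poisson(mt, n_cells)
        r = np.maximum(rng.poisson(mr, n_cells), 1)  # a scorable nucleus shows >=1 reference signal
        for j in range(n_cells):
            rows.append((core, f"cell_{j + 1}", int(t[j]), int(r[j])))
        truth.append({"core_id": core, "category": cat, "n_cells": n_cells})
    cells = pd.DataFrame(rows, columns=["core_id", "cell_id", "target_signals", "reference_signals"])
    return cells, pd.DataFrame(truth)


def simulate_uniform_gain_cohort(
    n_tumours: int = 30,
    genome: GenomeModel | None = None,
    gains_per_tumour: tuple[int, int] = (3, 8),
    gain_len_mean: float = 5e6,
    gain_len_range: tuple[float, float] = (5e5, 4e7),
    gain_cn: float = 3.0,
    seed: int = 0,
    planted_interval: tuple[str, int, int] | None = None,
    planted_fraction: float = 0.0,
):
    """Single-region tumours whose gains are placed uniformly along the genome.

    This is the null-model cohort for checking permutation-threshold
    calibration: the observed frequencies are themselves draws from the
    relocation null.  Optionally a fixed ``planted_interval`` is gained in
    the first ``planted_fraction`` of tumours (for power checks).

    Returns ``(segments, meta)`` ready for the frequency/permutation stage.
    """
    genome = genome or default_genome()
    rng = np.random.default_rng(seed)
    chrom_lens = np.asarray(genome.lengths, dtype=np.int64)
    probs = chrom_lens / chrom_lens.sum()
    n_planted = int(np.ceil(planted_fraction * n_tumours))
    seg_rows, meta_rows = [], []
    for i in range(n_tumours):
        tumour = f"U{i + 1:03d}"
        region = f"{tumour}_R1"
        meta_rows.append((region, tumour, 2.0))
        ivs: dict[str, list] = {}
        n_gains = int(rng.integers(gains_per_tumour[0], gains_per_tumour[1] + 1))
        for _ in range(n_gains):
            length = int(np.clip(rng.exponential(gain_len_mean), *gain_len_range))
            while True:
                ci = int(rng.choice(len(chrom_lens), p=probs))
                if length <= chrom_lens[ci]:
                    break
            start = int(rng.integers(0, chrom_lens[ci] - length + 1))
            ivs.setdefault(genome.names[ci], []).append((start, start + length, gain_cn))
        if planted_interval is not None and i < n_planted:
            c, s, e = planted_interval
            ivs.setdefault(c, []).append((int(s), int(e), gain_cn))
        for ci, chrom in enumerate(genome.names):
            gains = ivs.get(chrom, [])
            for s, e, cn in _piecewise(genome.lengths[ci], 2.0, gains, []):
                seg_rows.append((region, chrom, s, e, cn))
    segments = pd.DataFrame(seg_rows, columns=["region_id", "chromosome", "start", "end", "total_cn"])
    meta = pd.DataFrame(meta_rows, columns=["region_id", "tumour_id", "ploidy"])
    return io_formats.validate_segments(segments, genome), meta


# ---------------------------------------------------------------------------
# named fixtures


def _planted_cohort(
    n_clonal: int,
    n_subclonal: int,
    n_absent: int,
    n_high: int,
    regions_per_tumour: int = 3,
    prefix: str = "T",
) -> SimulatedCohort:
    """Deterministic cohort with exact planted clonal/subclonal/absent counts.

    The first ``n_high`` gained tumours carry a high-level (CN 5) event,
    the rest CN 3; events are 10 Mb focal gains centred on the focus gene.
    Clonal tumours are listed first, then subclonal, then absent.
    """
    cfg = SimConfig(n_tumours=n_clonal + n_subclonal + n_absent,
                    regions_per_tumour=regions_per_tumour,
                    with_expression=False, with_fish=False)
    loci = default_loci()
    focus = loci.iloc[0]
    genome = cfg.genome
    event = (int(focus.start) - 5_000_000, int(focus.end) + 5_000_000 - 5_000)
    seg_rows, meta_rows, truth_rows = [], [], []
    trees: dict[str, str] = {}
    statuses = (["clonal"] * n_clonal + ["subclonal"] * n_subclonal + ["absent"] * n_absent)
    n_gained_seen = 0
    for i, status in enumerate(statuses):
        tumour = f"{prefix}{i + 1:03d}"
        regions = [f"{tumour}_R{j + 1}" for j in range(regions_per_tumour)]
        trees[tumour] = _caterpillar_newick(regions)
        for r in regions:
            meta_rows.append((r, tumour, 2.0))
        if status == "absent":
            cn, ev_regions, level, edge = None, [], "none", ""
        else:
            n_gained_seen += 1
            cn = 5.0 if n_gained_seen <= n_high else 3.0
            level = "high" if cn == 5.0 else "low"
            if status == "clonal" or regions_per_tumour == 1:
                ev_regions, edge = regions, TRUNK
            else:
                leafset = tuple(regions[:-1]) if regions_per_tumour > 2 else (regions[0],)
                ev_regions = list(leafset)
                edge = _edge_label(leafset, regions)
        truth_rows.append({"tumour_id": tumour, "gene": focus["name"], "status": status,
                           "level": level, "focality": "focal" if status != "absent" else "",
                           "tree_edge": edge})
        for g in loci.itertuples(index=False):
            if g.name == focus["name"]:
                continue
            truth_rows.append({"tumour_id": tumour, "gene": g.name, "status": "absent",
                               "level": "none", "focality": "", "tree_edge": ""})
        for r in regions:
            for ci, chrom in enumerate(genome.names):
                gains = ([(event[0], event[1], cn)]
                         if (chrom == focus["chromosome"] and r in ev_regions) else [])
                for s, e, c in _piecewise(genome.lengths[ci], 2.0, gains, []):
                    seg_rows.append((r, chrom, s, e, c))
    segments = pd.DataFrame(seg_rows, columns=["region_id", "chromosome", "start", "end", "total_cn"])
    meta = pd.DataFrame(meta_rows, columns=["region_id", "tumour_id", "ploidy"])
    return SimulatedCohort(
        config=cfg, loci=loci, segments=io_formats.validate_segments(segments, genome),
        meta=meta, trees=trees, truth=pd.DataFrame(truth_rows),
    )


def _tiny_fish() -> SimulatedCohort:
    """Three constructed 20-cell cores: one HLG, one LLG, one polysomy.

    Counts are exact, not sampled: means (4.5, 1.0), (2.2, 1.0) and
    (3.5, 3.3) respectively.
    """
    rows = []
    patterns = {
        "core_hlg": ([4, 5] * 10, [1] * 20),            # means 4.5 / 1.0
        "core_llg": ([2] * 16 + [3] * 4, [1] * 20),     # means 2.2 / 1.0
        "core_poly": ([3, 4] * 10, [3] * 14 + [4] * 6), # means 3.5 / 3.3
    }
    for core, (t, r) in patterns.items():
        for j, (a, b) in enumerate(zip(t, r)):
            rows.append((core, f"cell_{j + 1}", a, b))
    cells = pd.DataFrame(rows, columns=["core_id", "cell_id", "target_signals", "reference_signals"])
    truth = pd.DataFrame({
        "core_id": ["core_hlg", "core_llg", "core_poly"],
        "category": ["high_level_gain", "low_level_gain", "polysomy"],
        "n_cells": [20, 20, 20],
    })
    base = _planted_cohort(1, 0, 0, 0)
    return replace(base, fish_cells=cells, fish_truth=truth)


FIXTURES = {
    # 2 tumours, focus gene clonally gained in both
    "tiny_clonal": lambda: _planted_cohort(n_clonal=2, n_subclonal=0, n_absent=0, n_high=0),
    # the printed TRACERx LUAD split: 61 tumours, 34 clonal + 12 subclonal
    # gains (46 gained, 75%), 10 of the gained high-level (22%)
    "tiny_mixed": lambda: _planted_cohort(n_clonal=34, n_subclonal=12, n_absent=15, n_high=10),
    # three hand-checkable FISH cores (HLG / LLG / polysomy)
    "tiny_fish": _tiny_fish,
    # printed per-cohort gain counts, single- or multi-region as appropriate
    "tracerx_luad": lambda: _planted_cohort(34, 12, 15, 10),
    "tracerx_lusc": lambda: _planted_cohort(19, 0, 13, 1),
    "tcga_luad": lambda: _planted_cohort(417, 0, 235, 70, regions_per_tumour=1),
    "tcga_lusc": lambda: _planted_cohort(211, 0, 441, 28, regions_per_tumour=1),
}


def make_fixture(name: str, out_dir: str | os.PathLike | None = None) -> SimulatedCohort:
    """Build a named deterministic fixture; optionally write it to ``out_dir``."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        ) from None
    cohort = builder()
    if out_dir is not None:
        cohort.write(out_dir, config_hash=f"fixture:{name}")
    return cohort
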
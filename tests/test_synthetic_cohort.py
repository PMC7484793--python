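import filecmp

import numpy as np
import pandas as pd
import pytest

from clonecna import (
    SimConfig,
    ValidationError,
    call_genes,
    classify_cohort,
    io_formats,
    simulate_cohort,
)
from clonecna.synthetic_cohort import (
    make_fixture,
    simulate_fish_cores,
    simulate_uniform_gain_cohort,
)


def _pipeline_labels(cohort):
    calls = call_genes(cohort.segments, cohort.meta, cohort.loci)
    return classify_cohort(calls, cohort.tree_objects())


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_cohort(SimConfig(seed=5, n_tumours=6)).write(a)
        simulate_cohort(SimConfig(seed=5, n_tumours=6)).write(b)
        names = [p.name for p in a.iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
        assert not mismatch and not errors and set(match) == set(names)

    def test_different_seeds_differ(self):
        x = simulate_cohort(SimConfig(seed=1, n_tumours=6))
        y = simulate_cohort(SimConfig(seed=2, n_tumours=6))
        assert not x.segments.equals(y.segments)


class TestPlantedStructure:
    def test_zero_branch_probability_means_all_gains_clonal(self):
        co = simulate_cohort(SimConfig(seed=3, n_tumours=15, branch_gain_prob=0.0))
        clon = _pipeline_labels(co)
        assert (clon["status"] != "subclonal").all()
        assert (clon["status"] == "clonal").any()

    def test_all_branch_means_all_gains_subclonal(self):
        co = simulate_cohort(SimConfig(seed=3, n_tumours=15, regions_per_tumour=3,
                                       truncal_gain_prob=0.0, branch_gain_prob=1.0))
        clon = _pipeline_labels(co)
        assert (clon["status"] != "clonal").all()
        assert (clon["status"] == "subclonal").any()

    def test_truth_ledger_recovered_exactly(self, small_cohort):
        clon = _pipeline_labels(small_cohort)
        merged = clon.merge(small_cohort.truth, on=["tumour_id", "gene"],
                            suffixes=("", "_true"))
        assert len(merged) == len(small_cohort.truth)
        assert (merged["status"] == merged["status_true"]).all()
        assert (merged["level"] == merged["level_true"]).all()
        assert (merged["tree_edge"] == merged["tree_edge_true"]).all()

    def test_focality_recovered_exactly(self, small_cohort):
        calls = call_genes(small_cohort.segments, small_cohort.meta, small_cohort.loci)
        gained = calls[calls["state"].isin(["gain", "high_gain"])]
        truth = small_cohort.truth.set_index(["tumour_id", "gene"])
        for row in gained.itertuples():
            assert row.focality == truth.loc[(row.tumour_id, row.gene), "focality"]

    def test_segments_partition_the_genome_per_region(self, small_cohort):
        genome = small_cohort.genome
        for region, sub in small_cohort.segments.groupby("region_id"):
            covered = int((sub["end"] - sub["start"]).sum())
            assert covered == genome.total_length

    def test_dosage_slope_recovered_within_two_se(self):
        """Regressing simulated log2 TPM on log2 CN ratio recovers the
        configured slope within 2 standard errors at ~200 region-samples."""
        cfg = SimConfig(seed=11, n_tumours=60, regions_per_tumour=(3, 4),
                        dosage_slope=1.0, expression_sigma=0.5)
        co = simulate_cohort(cfg)
        calls = call_genes(co.segments, co.meta, co.loci)
        focus = calls[calls["gene"] == "MCL1"].set_index("region_id")
        tpm = co.expression["MCL1"]
        lr = focus["log_ratio"].reindex(tpm.index)
        assert len(tpm) >= 200
        from scipy import stats

        fit = stats.linregress(lr.to_numpy(), np.log2(tpm.to_numpy()))
        assert abs(fit.slope - cfg.dosage_slope) < 2 * fit.stderr


class TestRoundTrip:
    def test_written_files_read_back_identically(self, tmp_path, small_cohort):
        paths = small_cohort.write(tmp_path)
        seg = io_formats.read_segment_table(paths["segments.seg.tsv"])
        pd.testing.assert_frame_equal(seg, small_cohort.segments)
        meta = io_formats.read_region_meta(paths["region_meta.tsv"])
        pd.testing.assert_frame_equal(meta, small_cohort.meta)
        loci = io_formats.read_gene_loci(paths["genes.bed"])
        pd.testing.assert_frame_equal(loci, small_cohort.loci)
        expr = io_formats.read_expression_table(paths["expression.tsv"])
        pd.testing.assert_frame_equal(expr, small_cohort.expression, check_exact=False, rtol=1e-5)


class TestDriverCoupling:
    def test_coupling_produces_dependent_table(self):
        from clonecna.pipeline import driver_clonality_association

        cfg = SimConfig(seed=8, n_tumours=100, truncal_gain_prob=0.3,
                        subclonal_gain_prob_mutant=0.6, subclonal_gain_prob_wildtype=0.1,
                        with_expression=False, with_fish=False)
        co = simulate_cohort(cfg)
        clon = _pipeline_labels(co)
        assoc = driver_clonality_association(clon, co.driver_status, "MCL1")
        assert assoc["p_value"].iloc[0] < 0.05

    def test_one_sided_coupling_config_rejected(self):
        from clonecna.synthetic_cohort import default_loci

        with pytest.raises(ValidationError):
            SimConfig(subclonal_gain_prob_mutant=0.6).validate(default_loci())


class TestFishSimulation:
    def test_planted_categories_mostly_recovered(self):
        from clonecna.fish_scoring import score_cores

        cats = ["high_level_gain", "low_level_gain", "no_gain"] * 10
        cells, truth = simulate_fish_cores(cats, seed=4)
        calls = score_cores(cells).set_index("core_id")["category"]
        agree = (truth.set_index("core_id")["category"] == calls).mean()
        assert agree >= 0.9  # Poisson noise may flip a rare borderline core


class TestUniformCohort:
    def test_single_region_partition_and_gains(self):
        seg, meta = simulate_uniform_gain_cohort(n_tumours=5, seed=2)
        assert meta["tumour_id"].nunique() == 5
        assert (seg.groupby("region_id").apply(
            lambda s: int((s["end"] - s["start"]).sum()), include_groups=False)
            == 240_000_000).all()
        assert (seg["total_cn"] > 2).any()


class TestFixtures:
    def test_unknown_fixture_lists_available(self):
        with pytest.raises(ValidationError, match="tiny_clonal"):
            make_fixture("nope")

    def test_tiny_clonal_is_all_clonal(self):
        fx = make_fixture("tiny_clonal")
        clon = _pipeline_labels(fx)
        focus = clon[clon["gene"] == "MCL1"]
        assert (focus["status"] == "clonal").all() and len(focus) == 2
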
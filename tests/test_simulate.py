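"""Synthetic-study generator: determinism, planted structure, templates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from binflux import abundance as ab
from binflux import io as bio
from binflux import simulate as sim


class TestCommunity:
    def test_default_counts_match_study_structure(self):
        bins, scaffolds, bin_map = sim.generate_community(sim.CommunitySpec(), 3)
        assert len(bins) == 106
        assert (bins["true_group"] != "NONE").sum() == 45
        assert scaffolds["is_decoy"].sum() > 0
        assert (scaffolds.loc[scaffolds["is_decoy"], "length_bp"] <= 500).all()
        assert (scaffolds.loc[~scaffolds["is_decoy"], "length_bp"] >= 501).all()

    def test_no_responsive_bins_all_none(self):
        spec = sim.CommunitySpec(n_bins=10, n_responsive=0)
        bins, _, _ = sim.generate_community(spec, 3)
        assert (bins["true_group"] == "NONE").all()

    def test_same_seed_same_community(self):
        a = sim.generate_community(sim.CommunitySpec(), 5)
        b = sim.generate_community(sim.CommunitySpec(), 5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError, match="n_responsive"):
            sim.CommunitySpec(n_bins=10, n_responsive=11).validate()


@pytest.fixture(scope="module")
def setup():
    comm = sim.CommunitySpec(n_bins=12, n_responsive=8, response_fold=4.0)
    bins, scaffolds, bin_map = sim.generate_community(comm, 7)
    design = sim.build_design(sim.DesignSpec(noise_cv=0.0), 7)
    truth = sim.simulate_trajectories(bins, design, comm)
    return comm, bins, scaffolds, bin_map, design, truth


class TestTrajectories:

    def test_group_a_period_ratio_is_the_fold(self, setup):
        comm, bins, _, _, design, truth = setup
        a_bins = bins.loc[bins["true_group"] == "A", "bin_id"]
        for eset in sim.SETS:
            d = design[design["experimental_set"] == eset]
            sI = d.loc[d["period"] == "I", "sample_id"]
            sII = d.loc[d["period"] == "II", "sample_id"]
            for b in a_bins:
                ratio = truth.loc[b, sII].mean() / truth.loc[b, sI].mean()
                assert ratio == pytest.approx(4.0, rel=1e-12)

    def test_none_bins_flat(self, setup):
        comm, bins, _, _, design, truth = setup
        flat = bins.loc[bins["true_group"] == "NONE", "bin_id"]
        for b in flat:
            assert truth.loc[b].nunique() <= 2  # one value per set

    def test_inoculum_enrichment_log2_at_period_one(self, setup):
        comm, bins, _, _, design, truth = setup
        d = design[design["period"] == "I"]
        acc = d.loc[d["experimental_set"] == "acclimatized", "sample_id"]
        non = d.loc[d["experimental_set"] == "non_acclimatized", "sample_id"]
        for _, row in bins.iterrows():
            lfc = np.log2(
                truth.loc[row["bin_id"], acc].mean()
                / truth.loc[row["bin_id"], non].mean()
            )
            if row["true_group"] in ("A", "B"):
                assert lfc == pytest.approx(1.0, abs=1e-12)
            elif row["true_group"] == "D":
                assert lfc == pytest.approx(-1.0, abs=1e-12)
            else:
                assert lfc == pytest.approx(0.0, abs=1e-12)


class TestCoverage:
    def test_zero_noise_equal_depth_inversion(self):
        comm = sim.CommunitySpec(n_bins=8, n_responsive=4)
        bins, scaffolds, bin_map = sim.generate_community(comm, 13)
        dspec = sim.DesignSpec(noise_cv=0.0, aligned_reads_range=(10_000, 10_001))
        design = sim.build_design(dspec, 13)
        truth = sim.simulate_trajectories(bins, design, comm)
        cov = sim.simulate_coverage(truth, scaffolds, design, 0.0, 13)
        cov = ab.filter_scaffolds(cov, 500)
        abund = ab.aggregate_bin_abundance(ab.normalize_coverage(cov), bin_map)
        np.testing.assert_allclose(
            abund.abundance.to_numpy(),
            truth.loc[abund.abundance.index].to_numpy(),
            rtol=1e-10,
        )

    def test_depth_factor_undone_by_normalization(self):
        comm = sim.CommunitySpec(n_bins=4, n_responsive=0)
        bins, scaffolds, bin_map = sim.generate_community(comm, 17)
        design = sim.build_design(sim.DesignSpec(noise_cv=0.0), 17)
        truth = sim.simulate_trajectories(bins, design, comm)
        cov = sim.simulate_coverage(truth, scaffolds, design, 0.0, 17)
        # raw depths differ across samples by the read-depth factor ...
        raw = ab.aggregate_bin_abundance(ab.filter_scaffolds(cov, 500), bin_map)
        assert raw.abundance.iloc[0].nunique() > 1
        # ... normalization makes flat bins flat again
        norm = ab.aggregate_bin_abundance(
            ab.normalize_coverage(ab.filter_scaffolds(cov, 500)), bin_map
        )
        np.testing.assert_allclose(
            norm.abundance.to_numpy(),
            truth.loc[norm.abundance.index].to_numpy(),
            rtol=1e-10,
        )

    def test_noisy_estimates_concentrate_around_truth(self):
        """CLT bound: bin-level estimates fall within 3 CV/sqrt(n_scaffolds)."""
        # equal scaffold lengths so the unweighted-mean CLT bound applies
        comm = sim.CommunitySpec(
            n_bins=40, n_responsive=0, scaffolds_per_bin=(10, 10),
            scaffold_length_sdlog=0.0,
        )
        bins, scaffolds, bin_map = sim.generate_community(comm, 19)
        design = sim.build_design(sim.DesignSpec(noise_cv=0.2), 19)
        truth = sim.simulate_trajectories(bins, design, comm)
        cov = sim.simulate_coverage(truth, scaffolds, design, 0.2, 19)
        abund = ab.aggregate_bin_abundance(
            ab.normalize_coverage(ab.filter_scaffolds(cov, 500)), bin_map
        )
        rel_err = np.abs(
            abund.abundance.to_numpy() / truth.loc[abund.abundance.index].to_numpy() - 1
        )
        bound = 3 * 0.2 / np.sqrt(10)
        assert (rel_err < bound).mean() >= 0.99


class TestAnnotations:
    def test_planted_fold_shows_in_expected_rates(self):
        comm = sim.CommunitySpec()
        bins, _, _ = sim.generate_community(comm, 23)
        ann, truth = sim.generate_gene_annotations(bins, comm, 23)
        planted_bins = set(truth["bin_id"])
        k = ann.groupby(["bin_id", "category_id"])["gene_id"].nunique()
        n = ann.groupby("bin_id")["gene_id"].nunique()
        rate_in = np.mean(
            [k.get((b, "chemotaxis_like"), 0) / n[b] for b in sorted(planted_bins)]
        )
        others = sorted(set(bins["bin_id"]) - planted_bins)
        rate_out = np.mean(
            [k.get((b, "chemotaxis_like"), 0) / n[b] for b in others]
        )
        assert rate_in / rate_out > 3  # planted 5-fold, sampling noise allowed

    def test_fold_one_plants_nothing(self):
        comm = sim.CommunitySpec(
            planted_enrichment=[("chemotaxis_like", ("A", "B"), 1.0)]
        )
        bins, _, _ = sim.generate_community(comm, 29)
        _, truth = sim.generate_gene_annotations(bins, comm, 29)
        assert (truth["fold"] == 1.0).all()

    def test_deterministic_under_seed(self):
        comm = sim.CommunitySpec(n_bins=10, n_responsive=4)
        bins, _, _ = sim.generate_community(comm, 31)
        a1, t1 = sim.generate_gene_annotations(bins, comm, 31)
        a2, t2 = sim.generate_gene_annotations(bins, comm, 31)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)


class TestWriteDataset:
    def test_round_trips_through_readers(self, tmp_path, small_dataset):
        paths = sim.write_dataset(small_dataset, tmp_path)
        design = bio.read_design(paths["design"])
        assert len(design) == len(small_dataset.design)
        cov = bio.read_coverage_table(paths["coverage"], design)
        assert cov.n_scaffolds == len(small_dataset.scaffolds)
        bin_map = bio.read_scaffold_bins(paths["scaffold_bins"])
        assert bin_map == small_dataset.bin_map
        ann = bio.read_gene_annotations(
            paths["annotations"], bin_universe=set(bin_map.values())
        )
        assert len(ann) == len(small_dataset.annotations)
        proc = bio.read_process_table(paths["process"])
        assert len(proc) == len(small_dataset.process)

    def test_manifest_counts_responsive_bins(self, tmp_path, small_dataset):
        import json

        paths = sim.write_dataset(small_dataset, tmp_path)
        manifest = json.loads(paths["truth_manifest"].read_text())
        assert manifest["n_responsive"] == 8
        assert manifest["n_decoys"] == len(manifest["decoy_scaffolds"])

    def test_regeneration_is_byte_identical(self, tmp_path):
        comm = sim.CommunitySpec(n_bins=10, n_responsive=4)
        for sub in ("a", "b"):
            ds = sim.generate_dataset(37, community=comm)
            sim.write_dataset(ds, tmp_path / sub)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
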
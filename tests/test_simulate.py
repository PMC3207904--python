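import numpy as np
import pandas as pd
import pytest

import chromshift as cs
from chromshift import simulate as sim
from chromshift.density import K4_SPEC, K27_SPEC, gene_status_table


SMALL = cs.SimParams(n_chrom=1, chrom_length=10_000_000, n_genes=120)


class TestAnnotation:
    def test_requested_count_no_overlap(self):
        ann = sim.simulate_annotation(SMALL, seed=0)
        g = ann.genes
        assert len(g) == 120
        for _, sub in g.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()
        lengths = g["end"] - g["start"]
        assert lengths.between(SMALL.gene_length_min,
                               SMALL.gene_length_max).all()

    def test_same_seed_identical(self):
        a = sim.simulate_annotation(SMALL, seed=7)
        b = sim.simulate_annotation(SMALL, seed=7)
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_infeasible_density_errors(self):
        bad = cs.SimParams(n_chrom=1, chrom_length=100_000, n_genes=500)
        with pytest.raises(RuntimeError):
            sim.simulate_annotation(bad, seed=0)


class TestPlantTransitions:
    def test_fraction_counts(self):
        truth = sim.plant_transitions(sim.simulate_annotation(SMALL, 0),
                                      cs.SimParams(n_genes=120), seed=0)
        counts = truth["category"].value_counts()
        p = cs.SimParams(n_genes=120)
        assert counts.get("K27->K4", 0) == round(p.frac_k27_to_k4 * 120)
        assert counts.get("none->K27", 0) == round(p.frac_none_to_k27 * 120)

    def test_all_fractions_zero_all_stable(self):
        p = cs.SimParams(n_genes=120, frac_k27_to_k4=0, frac_k4_to_k27=0,
                         frac_bi_to_k4=0, frac_none_to_k27=0,
                         frac_k27_loss_other=0, frac_k27_gain_other=0)
        ann = sim.simulate_annotation(SMALL, 0)
        truth = sim.plant_transitions(ann, p, seed=0)
        assert (truth["category"] == "stable").all()

    def test_same_seed_identical(self):
        ann = sim.simulate_annotation(SMALL, 3)
        a = sim.plant_transitions(ann, cs.SimParams(n_genes=120), seed=3)
        b = sim.plant_transitions(ann, cs.SimParams(n_genes=120), seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_coordinated_multipliers(self):
        truth = sim.plant_transitions(
            sim.simulate_annotation(cs.SimParams(), 0), cs.SimParams(), seed=0)
        up = truth.loc[truth["category"] == "K27->K4", "multiplier"]
        down = truth.loc[truth["category"] == "K4->K27", "multiplier"]
        flat = truth.loc[truth["category"].isin(["Bi->K4", "none->K27"]),
                         "multiplier"]
        assert (up >= 5).all() and (up <= 100).all()
        assert (down <= 0.2).all()
        assert (flat == 1.0).all()

    def test_targets_drawn_from_stable_genes(self):
        truth = sim.plant_transitions(
            sim.simulate_annotation(cs.SimParams(), 0), cs.SimParams(), seed=0)
        assert (truth.loc[truth["is_target"], "category"] == "stable").all()


class TestMarkReads:
    def test_status_calibration(self):
        """Positive genes land above the high threshold and negative genes
        below the low threshold in >= 99% of calls."""
        params = cs.SimParams(n_chrom=1, chrom_length=20_000_000, n_genes=300)
        ann = sim.simulate_annotation(params, seed=9)
        rng = np.random.default_rng(9)
        positive = rng.random(300) < 0.5
        for label, budget, mu, sd, spec, hi, lo in [
            ("k4", params.k4_budget, params.k4_offset_mean,
             params.k4_offset_sd, K4_SPEC, 4.0, 3.0),
            ("k27", params.k27_budget, params.k27_offset_mean,
             params.k27_offset_sd, K27_SPEC, 1.5, 1.0),
        ]:
            rs = sim.simulate_mark_reads(ann, positive, params, seed=9,
                                         label=label, budget=budget,
                                         offset_mean=mu, offset_sd=sd)
            rpm = gene_status_table(rs, ann, spec)
            assert (rpm[positive] > hi).mean() >= 0.99
            assert (rpm[~positive] < lo).mean() >= 0.99

    def test_zero_budget_zero_background_empty(self):
        params = cs.SimParams(n_chrom=1, chrom_length=1_000_000, n_genes=10,
                              background_per_bp=0.0)
        ann = sim.simulate_annotation(params, seed=0)
        rs = sim.simulate_mark_reads(ann, np.zeros(10, bool), params, seed=0,
                                     label="x", budget=0.0, offset_mean=0,
                                     offset_sd=1)
        assert len(rs) == 0

    def test_reads_are_valid_bed(self, bundle):
        for rs in bundle.readsets.values():
            assert (rs.reads["start"] < rs.reads["end"]).all()
            assert (rs.reads["start"] >= 0).all()
            assert rs.reads["strand"].isin(["+", "-"]).all()


class TestExpressionGenerator:
    def test_class_separation(self, bundle):
        """Sample-mean ratio of active-class to repressed-class >= 5."""
        truth = bundle.truth
        base = bundle.expression.scores.loc["MEFp2"]
        active = base[(truth["expr_class"] == "active").to_numpy()].mean()
        repressed = base[(truth["expr_class"] == "k27_only").to_numpy()].mean()
        assert active / repressed >= 5

    def test_flat_genes_fold_centred_at_one(self, bundle, fold_table):
        flat = bundle.truth.index[bundle.truth["multiplier"] == 1.0]
        med = fold_table.loc[fold_table.index.isin(flat), "fold"].median()
        assert 0.8 <= med <= 1.25

    def test_zero_noise_fold_equals_multiplier(self):
        params = cs.SimParams(n_chrom=1, chrom_length=10_000_000,
                              n_genes=100, noise_log_sd=0.0)
        ann = sim.simulate_annotation(params, seed=5)
        truth = sim.plant_transitions(ann, params, seed=5)
        matrix = sim.simulate_expression(truth, params, seed=5)
        fold = cs.fold_change(matrix, "MEFp2",
                              ["RasV12_d3", "RasV12_d7", "RasV12_d10"],
                              floor=1e-12)
        big = truth["multiplier"] > 2  # away from the floor regime
        got = fold.loc[truth.index[big], "fold"].to_numpy()
        want = truth.loc[big, "multiplier"].to_numpy()
        assert np.allclose(got, want, rtol=1e-9)


class TestReproducibility:
    def test_bundle_bit_exact_same_seed(self):
        params = cs.SimParams(n_chrom=1, chrom_length=10_000_000, n_genes=100)
        b1 = cs.simulate_bundle(params, seed=4)
        b2 = cs.simulate_bundle(params, seed=4)
        pd.testing.assert_frame_equal(b1.truth, b2.truth)
        pd.testing.assert_frame_equal(b1.expression.scores, b2.expression.scores)
        for track in b1.readsets:
            pd.testing.assert_frame_equal(b1.readsets[track].reads,
                                          b2.readsets[track].reads)

    def test_seed_changes_output(self):
        params = cs.SimParams(n_chrom=1, chrom_length=10_000_000, n_genes=100)
        b1 = cs.simulate_bundle(params, seed=4)
        b2 = cs.simulate_bundle(params, seed=5)
        assert not b1.expression.scores.equals(b2.expression.scores)

    def test_per_track_streams_independent(self):
        """A track's reads depend only on (seed, label), not on other tracks."""
        params = cs.SimParams(n_chrom=1, chrom_length=10_000_000, n_genes=100)
        ann = sim.simulate_annotation(params, seed=6)
        pos = np.ones(100, bool)
        a = sim.simulate_mark_reads(ann, pos, params, seed=6, label="k4_A",
                                    budget=50, offset_mean=250, offset_sd=300)
        # generate an unrelated track in between; regenerate the first
        sim.simulate_mark_reads(ann, pos, params, seed=6, label="k27_A",
                                budget=50, offset_mean=500, offset_sd=700)
        b = sim.simulate_mark_reads(ann, pos, params, seed=6, label="k4_A",
                                    budget=50, offset_mean=250, offset_sd=300)
        pd.testing.assert_frame_equal(a.reads, b.reads)
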
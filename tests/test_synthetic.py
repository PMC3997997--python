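"""Generator/analyzer agreement and calibration of the synthetic inputs."""

import numpy as np
import pandas as pd
import pytest

from mirnod.expression import select_candidates
from mirnod.interactions import build_union_db
from mirnod.nod import compute_nod
from mirnod.synthetic import (
    PlantedBiomarker,
    SyntheticTruth,
    gen_expression,
    gen_gene_sets,
    gen_interaction_network,
    gen_ppi,
)


def rebuild(val_tables, pred_tables):
    return build_union_db(val_tables, pred_tables, min_predicted_support=2)


class TestInteractionNetwork:
    def test_full_exclusivity_makes_nod_equal_degree(self):
        val, pred, truth = gen_interaction_network(
            10, 200, mean_targets=5, exclusive_fraction=1.0, seed=1
        )
        db = rebuild(val, pred)
        nods = compute_nod(db)
        for m in db.mirnas:
            assert nods[m].nod == len(db.targets(m))

    def test_zero_exclusivity_means_zero_nod(self):
        val, pred, truth = gen_interaction_network(
            10, 100, mean_targets=5, exclusive_fraction=0.0, seed=2
        )
        nods = compute_nod(rebuild(val, pred))
        assert all(r.nod == 0 for r in nods.values())
        assert all(c >= 2 for c in truth.gene_regulator_counts.values())

    def test_planted_nods_match_analyzer_exactly(self):
        hubs = {"hsa-mir-s0000": 20, "hsa-mir-s0001": 12}
        val, pred, truth = gen_interaction_network(
            40, 600, mean_targets=8, exclusive_fraction=0.1,
            hub_mirnas=hubs, seed=3,
        )
        db = rebuild(val, pred)
        nods = {m: r.nod for m, r in compute_nod(db).items()}
        assert nods == truth.planted_nods
        assert nods["hsa-mir-s0000"] == 20 and nods["hsa-mir-s0001"] == 12

    def test_union_reconstruction_excludes_decoys(self):
        val, pred, truth = gen_interaction_network(
            20, 300, mean_targets=6, exclusive_fraction=0.2,
            seed=4, decoy_fraction=0.2,
        )
        db = rebuild(val, pred)
        assert truth.decoy_pairs  # generator did plant unsupported predictions
        for pair in truth.decoy_pairs:
            assert pair not in db.edges
        # per-gene regulator counts agree with the analyzer's view
        assert {g: len(r) for g, r in db.gene_index.items()} == \
            truth.gene_regulator_counts

    def test_infeasible_exclusive_demand_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            gen_interaction_network(
                5, 10, mean_targets=3, exclusive_fraction=0.5,
                hub_mirnas={"hsa-mir-s0000": 50}, seed=0,
            )


class TestExpression:
    def test_determinism(self):
        m1, _ = gen_expression(n_mirnas=40, seed=9)
        m2, _ = gen_expression(n_mirnas=40, seed=9)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_different_seeds_differ(self):
        m1, _ = gen_expression(n_mirnas=40, seed=9)
        m2, _ = gen_expression(n_mirnas=40, seed=10)
        assert not m1.values.equals(m2.values)

    def test_duplicate_planted_ids_rejected(self):
        b = PlantedBiomarker("hsa-mir-s0000", "up", 4.0, 0)
        with pytest.raises(ValueError, match="duplicate"):
            gen_expression(n_mirnas=10, planted=[b, b], seed=0)

    def test_unit_effect_has_null_candidate_rate(self):
        planted = [PlantedBiomarker(f"hsa-mir-s{i:04d}", "up", 1.0, 0)
                   for i in range(10)]
        n_rows, n_reps = 556, 20
        hits = 0
        for seed in range(n_reps):
            mat, _ = gen_expression(n_mirnas=n_rows, planted=planted, seed=seed)
            res = select_candidates(mat, alpha=0.05, fc_threshold=1.0)
            hits += sum(r.p_value < 0.05 for r in res)
        rate = hits / (n_rows * n_reps)
        # binomial 99% band around 0.05 for n_rows*n_reps draws
        se = np.sqrt(0.05 * 0.95 / (n_rows * n_reps))
        assert abs(rate - 0.05) < 2.58 * se + 1e-9

    def test_strong_effect_low_noise_recovers_all(self):
        planted = [PlantedBiomarker(f"hsa-mir-s{i:04d}", "up" if i % 2 else "down",
                                    4.0, 0) for i in range(10)]
        mat, _ = gen_expression(n_mirnas=100, planted=planted, noise_sd=0.2, seed=7)
        res = {r.mirna_id: r for r in select_candidates(mat)}
        for b in planted:
            assert res[b.mirna_id].is_candidate
            if b.direction == "down":
                assert res[b.mirna_id].fc_linear <= -2.0


class TestPPI:
    def test_zero_mean_degree_is_empty(self):
        g, _ = gen_ppi([f"G{i}" for i in range(50)], mean_degree=0.0, seed=0)
        assert g.number_of_edges() == 0

    def test_seed_reproducibility(self):
        genes = [f"G{i}" for i in range(100)]
        g1, _ = gen_ppi(genes, mean_degree=5, seed=5)
        g2, _ = gen_ppi(genes, mean_degree=5, seed=5)
        assert set(g1.edges()) == set(g2.edges())

    def test_mean_degree_calibration(self):
        genes = [f"G{i}" for i in range(300)]
        target = 6.0
        means = []
        for seed in range(20):
            g, _ = gen_ppi(genes, mean_degree=target, seed=seed)
            means.append(2 * g.number_of_edges() / len(genes))
        assert abs(np.mean(means) - target) / target < 0.10

    def test_scale_free_model_and_bad_name(self):
        genes = [f"G{i}" for i in range(60)]
        g, _ = gen_ppi(genes, mean_degree=4, model="scale_free", seed=1)
        assert g.number_of_nodes() == 60
        with pytest.raises(ValueError):
            gen_ppi(genes, model="smallworld", seed=1)


class TestGeneSets:
    def test_gmt_lines_valid(self, tmp_path):
        from mirnod.enrichment import write_gmt

        universe = [f"G{i}" for i in range(80)]
        coll, _ = gen_gene_sets(universe, n_sets=10, set_size_range=(5, 20), seed=0)
        write_gmt(coll, tmp_path / "c.gmt")
        for line in (tmp_path / "c.gmt").read_text().splitlines():
            assert len(line.split("\t")) >= 3

    def test_null_odds_ratio_gives_uniform_planted_p(self):
        from scipy import stats as sps

        from mirnod.enrichment import hypergeom_enrich

        universe = [f"G{i}" for i in range(200)]
        targets = universe[:30]
        ps = []
        for seed in range(200):
            coll, truth = gen_gene_sets(
                universe, n_sets=5, set_size_range=(15, 30),
                planted_targets=targets, odds_ratio=1.0, seed=seed,
            )
            results = {r.set_id: r for r in hypergeom_enrich(set(targets), coll)}
            ps.append(results[truth.planted_set_id].p_value)
        # P of a discrete test is stochastically >= uniform under the null:
        # one-sided K-S against uniform must not reject in the "too small" direction
        ks = sps.ks_1samp(ps, sps.uniform.cdf, alternative="greater")
        assert ks.pvalue > 0.01

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError):
            gen_gene_sets([f"G{i}" for i in range(10)], n_sets=2,
                          set_size_range=(5, 20), seed=0)


def test_truth_json_roundtrip(tmp_path):
    truth = SyntheticTruth(
        seed=3,
        planted_biomarkers=[PlantedBiomarker("hsa-mir-16", "up", 4.0, 35)],
        planted_nods={"hsa-mir-16": 35},
        gene_regulator_counts={"G1": 1},
        decoy_pairs=[("hsa-mir-16", "G9")],
        ppi_degrees={"G1": 2},
        planted_set_id="set_planted",
    )
    truth.to_json(tmp_path / "t.json")
    assert SyntheticTruth.from_json(tmp_path / "t.json") == truth
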
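import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tnfit import barseq_fitness as bf
from tnfit import synthetic_data as sd
from tnfit.barseq_fitness import IntensityTable
from tnfit.genome_annotation import Gene, GenomeAnnotation


def _table(sample_id, mapping):
    return IntensityTable(sample_id, pd.Series(mapping, dtype=float))


def _one_strain(pools="1"):
    return pd.DataFrame(
        [
            {
                "strain_id": "s1",
                "chrom": "chr1",
                "position": 10,
                "feature": "gA",
                "pools": pools,
                "uptag_id": "u1",
                "downtag_id": "d1",
                "true_rate": 1.0,
            }
        ]
    )


class TestStrainFitness:
    def test_mean_tag_difference(self):
        start = {1: _table("p1_START", {"u1": 8.0, "d1": 10.0})}
        end = {1: _table("p1_END", {"u1": 9.0, "d1": 11.0})}
        rec = bf.strain_fitness(start, end, _one_strain())
        assert rec.loc[0, "fitness"] == pytest.approx(1.0)
        assert rec.loc[0, "start_mean"] == pytest.approx(9.0)

    def test_identical_samples_give_zero(self):
        t = {1: _table("p1", {"u1": 8.0, "d1": 10.0})}
        rec = bf.strain_fitness(t, t, _one_strain())
        assert rec.loc[0, "fitness"] == 0.0

    def test_strain_without_tags_excluded(self):
        start = {1: _table("p1_START", {"uX": 8.0})}
        end = {1: _table("p1_END", {"uX": 9.0})}
        rec = bf.strain_fitness(start, end, _one_strain())
        assert rec.empty

    def test_noise_free_pipeline_recovers_truth(self, small_config):
        # sigma = 0 and no normalization: estimates equal simulator truth
        cfg = sd.ScenarioConfig(**{**small_config.__dict__, "sigma": 0.0})
        ann, strains = sd.build_scenario_library(cfg)
        states, arrays = sd.simulate_pool_experiment(strains, cfg, "stress")
        rec = bf.strain_fitness(
            {p: arrays[p]["START"] for p in arrays},
            {p: arrays[p]["END"] for p in arrays},
            strains,
        )
        truth = {
            (sid, pool): w
            for pool, st in states.items()
            for sid, w in zip(st.ids, st.true_fitness())
        }
        for row in rec.itertuples(index=False):
            assert row.fitness == pytest.approx(truth[(row.strain_id, row.pool)], abs=1e-9)


class TestLowStartFilter:
    def test_minus_infinity_keeps_all(self):
        rec = pd.DataFrame(
            {"strain_id": ["a", "b"], "pool": 1, "fitness": [0.1, 0.2],
             "start_mean": [3.0, 8.0], "included": True}
        )
        out = bf.filter_low_start(rec, -np.inf)
        assert out["included"].all()

    def test_threshold_above_max_raises_empty_pool(self):
        rec = pd.DataFrame(
            {"strain_id": ["a"], "pool": 1, "fitness": [0.1],
             "start_mean": [3.0], "included": True}
        )
        with pytest.raises(ValueError, match="empty pool"):
            bf.filter_low_start(rec, 99.0)

    def test_planted_low_abundance_strains_removed(self):
        # 5% of strains at near-zero START abundance; background-quantile
        # threshold should catch nearly all of them
        rng = np.random.default_rng(12)
        n = 1000
        x0 = np.full(n, 1.0)
        low = rng.choice(n, size=50, replace=False)
        x0[low] = 1e-4
        x0 /= x0.sum()
        ids = np.array([f"s{i:04d}" for i in range(n)])
        state = sd.AbundanceState(ids, x0, x0.copy())
        strains = pd.DataFrame(
            {"strain_id": ids, "chrom": "chr1", "position": 1, "feature": "gA",
             "pools": "1", "uptag_id": [f"u{i}" for i in range(n)],
             "downtag_id": [f"d{i}" for i in range(n)], "true_rate": 1.0}
        )
        tabs = sd.simulate_microarray(state, strains, 1, sigma=0.1, seed=12)
        rec = bf.strain_fitness({1: tabs["START"]}, {1: tabs["END"]}, strains)
        theta = bf.background_theta({1: tabs["START"]}, quantile=0.05)
        out = bf.filter_low_start(rec, theta)
        excluded = set(out.loc[~out["included"], "strain_id"])
        assert len(excluded & set(ids[low])) >= 0.95 * 50


class TestNormalization:
    def test_median_centering(self):
        rec = pd.DataFrame(
            {"strain_id": list("abc"), "pool": 1, "fitness": [1.0, 2.0, 3.0],
             "start_mean": 5.0, "included": True}
        )
        out = bf.normalize_strain_median(rec)
        assert list(out["fitness"]) == [-1.0, 0.0, 1.0]

    def test_already_centered_unchanged(self):
        rec = pd.DataFrame(
            {"strain_id": list("abc"), "pool": 1, "fitness": [-1.0, 0.0, 1.0],
             "start_mean": 5.0, "included": True}
        )
        assert list(bf.normalize_strain_median(rec)["fitness"]) == [-1.0, 0.0, 1.0]

    def test_per_pool_offsets_removed(self):
        rec = pd.DataFrame(
            {"strain_id": list("abcdef"), "pool": [1] * 3 + [2] * 3,
             "fitness": [2.0, 3.0, 4.0, -2.0, -1.0, 0.0],
             "start_mean": 5.0, "included": True}
        )
        out = bf.normalize_strain_median(rec)
        for _, grp in out.groupby("pool"):
            assert grp["fitness"].median() == 0.0
        assert list(out["fitness"]) == [-1.0, 0.0, 1.0, -1.0, 0.0, 1.0]

    def test_added_end_constant_vanishes_after_median_norm(self):
        # pipeline linearity: a per-pool scanner gain has no effect
        strains = pd.DataFrame(
            {"strain_id": [f"s{i}" for i in range(5)], "chrom": "chr1",
             "position": 1, "feature": "gA", "pools": "1",
             "uptag_id": [f"u{i}" for i in range(5)],
             "downtag_id": [f"d{i}" for i in range(5)], "true_rate": 1.0}
        )
        start = {1: _table("s", {f"u{i}": 8.0 + i for i in range(5)})}
        end0 = {1: _table("e", {f"u{i}": 8.5 + i * 1.1 for i in range(5)})}
        end1 = {1: IntensityTable("e", end0[1].intensities + 3.7)}
        out0 = bf.normalize_strain_median(bf.strain_fitness(start, end0, strains))
        out1 = bf.normalize_strain_median(bf.strain_fitness(start, end1, strains))
        np.testing.assert_allclose(out0["fitness"], out1["fitness"], atol=1e-12)


class TestGeneFitness:
    def test_mean_of_strains(self):
        rec = pd.DataFrame(
            {"strain_id": ["a", "b"], "pool": 1, "fitness": [3.0, 5.0],
             "start_mean": 5.0, "included": True}
        )
        strains = pd.DataFrame({"strain_id": ["a", "b"], "feature": "gA"})
        out = bf.gene_fitness(rec, strains)
        assert out.loc[0, "fitness"] == 4.0 and out.loc[0, "n_strains"] == 2

    def test_single_strain_gene(self):
        rec = pd.DataFrame(
            {"strain_id": ["a"], "pool": 1, "fitness": [2.5], "start_mean": 5.0,
             "included": True}
        )
        strains = pd.DataFrame({"strain_id": ["a"], "feature": "gZ"})
        assert bf.gene_fitness(rec, strains).loc[0, "fitness"] == 2.5

    def test_matches_brute_force_group_average(self):
        rng = np.random.default_rng(13)
        n = 500
        strains = pd.DataFrame(
            {"strain_id": [f"s{i}" for i in range(n)],
             "feature": rng.choice([f"g{j}" for j in range(60)], n)}
        )
        rec = pd.DataFrame(
            {"strain_id": strains["strain_id"], "pool": rng.choice([1, 2], n),
             "fitness": rng.normal(0, 1, n), "start_mean": 5.0, "included": True}
        )
        out = bf.gene_fitness(rec, strains).set_index("gene_id")["fitness"]
        # independent oracle: plain dict accumulation
        sums, counts = {}, {}
        for sid, f in zip(rec["strain_id"], rec["fitness"]):
            g = strains.set_index("strain_id")["feature"][sid]
            sums[g] = sums.get(g, 0.0) + f
            counts[g] = counts.get(g, 0) + 1
        for g in sums:
            assert out[g] == pytest.approx(sums[g] / counts[g], abs=1e-12)


class TestPositionModeNormalization:
    def _gene_frame(self, ann, values):
        return pd.DataFrame(
            {"gene_id": ann.gene_ids, "fitness": values,
             "n_strains": 1, "intergenic": False, "condition": "c"}
        )

    def test_constant_field_maps_to_zero(self):
        ann = sd.build_genome(sd.ScenarioConfig(seed=7, n_genes=100))
        out = bf.normalize_position_mode(self._gene_frame(ann, np.full(100, 2.7)), ann)
        np.testing.assert_allclose(out["fitness"], 0.0, atol=1e-12)

    def test_linear_positional_drift_removed(self):
        ann = sd.build_genome(sd.ScenarioConfig(seed=7, n_genes=600))
        rng = np.random.default_rng(14)
        drift = np.linspace(-1.5, 1.5, 600)
        vals = drift + rng.normal(0, 0.3, 600)
        out = bf.normalize_position_mode(self._gene_frame(ann, vals), ann, window=101)
        r = stats.pearsonr(out["fitness"], np.arange(600)).statistic
        assert abs(r) < 0.1

    def test_jackpot_outliers_barely_shifted(self):
        ann = sd.build_genome(sd.ScenarioConfig(seed=7, n_genes=2400))
        rng = np.random.default_rng(15)
        vals = rng.normal(0, 0.2, 2400)
        jack = rng.choice(2400, 10, replace=False)
        vals[jack] += 8.0
        frame = self._gene_frame(ann, vals)
        out = bf.normalize_position_mode(frame, ann)
        shift = (frame["fitness"] - out["fitness"]).iloc[jack]
        assert (shift - shift.mean()).abs().max() < 0.05

    def test_even_window_rejected(self):
        ann = sd.build_genome(sd.ScenarioConfig(seed=7, n_genes=10))
        with pytest.raises(ValueError):
            bf.normalize_position_mode(self._gene_frame(ann, np.zeros(10)), ann, window=10)


class TestQualityMetrics:
    def _records(self, fit1, fit2):
        n = len(fit1)
        return pd.DataFrame(
            {"strain_id": [f"s{i}" for i in range(n)] * 2,
             "pool": [1] * n + [2] * n,
             "fitness": list(fit1) + list(fit2),
             "start_mean": 5.0, "included": True}
        )

    def test_identical_pools_correlate_perfectly(self, toy_annotation):
        f = np.linspace(-1, 1, 20)
        rec = self._records(f, f)
        genes = pd.DataFrame(
            {"gene_id": toy_annotation.gene_ids, "fitness": np.arange(5.0),
             "n_strains": 1, "intergenic": False}
        )
        rep = bf.quality_metrics(rec, genes, toy_annotation)
        assert rep.strain_correlation == pytest.approx(1.0)
        assert rep.n_strain_pairs == 20

    def test_too_few_pairs_undefined(self, toy_annotation):
        rec = self._records([0.1, 0.2], [0.1, 0.3])
        genes = pd.DataFrame(
            {"gene_id": ["gA"], "fitness": [0.5], "n_strains": 1, "intergenic": False}
        )
        rep = bf.quality_metrics(rec, genes, toy_annotation)
        assert rep.strain_correlation is None and rep.operon_correlation is None

    def test_shared_true_effects_survive_noise(self):
        # spread of true effects sd=1 against sigma=0.2 arrays: attenuation
        # keeps the two pools' estimates correlated above 0.9
        rng = np.random.default_rng(16)
        true = rng.normal(0, 1, 1000)
        noise = lambda: rng.normal(0, 0.2 * np.sqrt(2), 1000)
        rep = bf.quality_metrics(
            self._records(true + noise(), true + noise()),
            pd.DataFrame({"gene_id": [], "fitness": [], "n_strains": [], "intergenic": []}),
            GenomeAnnotation({"chr1": 100}, [Gene("gA", "chr1", 1, 50, "+")]),
        )
        assert rep.strain_correlation >= 0.9


class TestOperonCorrelation:
    def test_operon_effects_raise_operon_correlation(self):
        # effects assigned per operon correlate adjacent co-operonic genes;
        # independent per-gene effects do not
        ann = sd.build_genome(sd.ScenarioConfig(seed=8, n_genes=400))
        rng = np.random.default_rng(17)
        by_operon = {}
        vals_operon, vals_indep = [], []
        for g in ann:
            if g.operon_id is not None:
                if g.operon_id not in by_operon:
                    by_operon[g.operon_id] = rng.normal(0, 1)
                base = by_operon[g.operon_id]
            else:
                base = rng.normal(0, 1)
            vals_operon.append(base + rng.normal(0, 0.3))
            vals_indep.append(rng.normal(0, 1))
        frame = lambda v: pd.DataFrame(
            {"gene_id": ann.gene_ids, "fitness": v, "n_strains": 1, "intergenic": False}
        )
        rec = pd.DataFrame(
            {"strain_id": [f"s{i}" for i in range(6)], "pool": [1, 1, 1, 2, 2, 2],
             "fitness": 0.0, "start_mean": 5.0, "included": True}
        )
        r_op = bf.quality_metrics(rec, frame(vals_operon), ann).operon_correlation
        r_ind = bf.quality_metrics(rec, frame(vals_indep), ann).operon_correlation
        assert r_op > 0.6
        assert abs(r_ind) < 0.25
        assert r_op > r_ind


def test_intensity_tsv_round_trip(tmp_path):
    tables = {
        (1, "START"): _table("p1_START", {"u1": 3.25, "u2": 4.5}),
        (1, "END"): _table("p1_END", {"u1": 3.0, "u2": 5.5}),
        (2, "START"): _table("p2_START", {"d1": 7.125}),
        (2, "END"): _table("p2_END", {"d1": 7.25}),
    }
    path = tmp_path / "intensity.tsv"
    bf.write_intensity_tsv(tables, path)
    again = bf.read_intensity_tsv(path)
    assert set(again) == set(tables)
    for key in tables:
        pd.testing.assert_series_equal(
            again[key].intensities, tables[key].intensities, check_names=False
        )
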
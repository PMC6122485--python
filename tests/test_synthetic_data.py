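import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spongescout.correlation import partial_spearman
from spongescout.downstream import proximal_triplets
from spongescout.synthetic_data import (
    GroundTruth,
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
    simulate_prognostic_cohort,
    simulate_survival,
    simulate_target_db,
    write_dataset,
)


def tiny_cfg(**kw):
    base = dict(n_samples=50, n_planted=3, n_null_confounded=2,
                n_null_independent=2, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_samples", 5), ("n_planted", 0), ("noise_sd", 0.0),
        ("hazard_ratio", -1.0), ("censor_rate", 1.0), ("decoy_rate", 1.5),
    ])
    def test_invalid_rejected(self, field, value):
        with pytest.raises(ValueError):
            tiny_cfg(**{field: value})


class TestSimulateExpression:
    def test_deterministic_under_seed(self):
        cfg = tiny_cfg(seed=7)
        m1, t1 = simulate_expression(cfg)
        m2, t2 = simulate_expression(tiny_cfg(seed=7))
        pd.testing.assert_frame_equal(m1.values, m2.values)
        assert t1.planted_triplets == t2.planted_triplets

    def test_planted_pairs_strongly_positively_correlated(self):
        cfg = SimulationConfig(n_samples=200, n_planted=20,
                               n_null_confounded=1, n_null_independent=1,
                               coupling_strength=1.0, noise_sd=0.3, seed=1)
        expr, truth = simulate_expression(cfg)
        log_expr = np.log2(expr.values)
        for lnc, mir, mrna in truth.planted_triplets:
            rho = stats.spearmanr(log_expr.loc[lnc], log_expr.loc[mrna]).statistic
            assert rho > 0.5
            assert stats.spearmanr(log_expr.loc[lnc], log_expr.loc[mir]).statistic < 0
            assert stats.spearmanr(log_expr.loc[mrna], log_expr.loc[mir]).statistic < 0

    def test_zero_coupling_degenerates_to_independence(self):
        cfg = tiny_cfg(n_samples=500, coupling_strength=0.0, noise_sd=1.0,
                       seed=3)
        expr, truth = simulate_expression(cfg)
        log_expr = np.log2(expr.values)
        rhos = [
            stats.spearmanr(log_expr.loc[t[0]], log_expr.loc[t[2]]).statistic
            for t in truth.planted_triplets
        ]
        assert all(abs(r) < 0.2 for r in rhos)

    def test_planted_and_null_ids_disjoint_and_present(self):
        expr, truth = simulate_expression(tiny_cfg())
        planted = {x for t in truth.planted_triplets for x in t}
        nulls = {x for r in truth.null_triplets for x in r["triplet"]}
        assert not planted & nulls
        assert (planted | nulls) <= set(expr.rna_ids)

    def test_positive_rpkm_scale(self):
        expr, _ = simulate_expression(tiny_cfg())
        assert (expr.values.to_numpy() > 0).all()
        assert not expr.log_scale

    def test_planted_partial_correlation_vanishes(self):
        # conditional independence given Z: partial rho -> 0 at n=1000
        cfg = SimulationConfig(n_samples=1000, n_planted=10,
                               n_null_confounded=10, n_null_independent=1,
                               seed=5)
        expr, truth = simulate_expression(cfg)
        log_expr = np.log2(expr.values)

        def partial(trio):
            x, z, y = (log_expr.loc[t] for t in trio)
            r_xy = stats.spearmanr(x, y).statistic
            r_xz = stats.spearmanr(x, z).statistic
            r_yz = stats.spearmanr(y, z).statistic
            return partial_spearman(r_xy, r_xz, r_yz)

        planted_partials = [
            partial((t[0], t[1], t[2])) for t in truth.planted_triplets
        ]
        assert abs(np.mean(planted_partials)) < 0.05
        confounded_partials = [
            partial(r["triplet"]) for r in truth.null_triplets
            if r["kind"] == "confounded"
        ]
        assert np.mean(confounded_partials) > 0.3


class TestSimulateSurvival:
    def test_zero_censoring_all_events(self):
        cfg = tiny_cfg(censor_rate=0.0)
        expr, truth = simulate_expression(cfg)
        recs = simulate_survival(expr, truth, cfg)
        assert all(r.event == 1 for r in recs)
        assert len(recs) == cfg.n_samples

    def test_censor_fraction_approximate(self):
        cfg = tiny_cfg(n_samples=1000, censor_rate=0.3, seed=9)
        expr, truth = simulate_expression(cfg)
        recs = simulate_survival(expr, truth, cfg)
        frac = np.mean([r.event == 0 for r in recs])
        assert abs(frac - 0.3) < 0.05

    def test_unit_hazard_ratio_null_logrank(self):
        # pattern group and complement share one survival law
        from spongescout.prognostic import logrank, survival_frame
        from spongescout.synthetic_data import _pattern_cells

        rejections = 0
        for seed in range(40):
            cfg = tiny_cfg(n_samples=120, hazard_ratio=1.0, seed=seed)
            expr, truth = simulate_expression(cfg)
            recs = simulate_survival(expr, truth, cfg)
            surv = survival_frame(recs)
            cells = _pattern_cells(np.log2(expr.values),
                                   truth.prognostic_triplets[0], False)
            if cells.sum() < 2 or (~cells).sum() < 2:
                continue
            _, p = logrank(surv.loc[cells], surv.loc[~cells])
            rejections += p < 0.05
        assert rejections <= 6   # ~nominal 5% of 40

    def test_planted_hazard_detected_by_logrank(self):
        # hazard_ratio=3 on the pattern cell: power >= 0.8 over replicates
        from spongescout.prognostic import logrank, survival_frame
        from spongescout.synthetic_data import _pattern_cells

        hits, total = 0, 0
        for seed in range(25):
            cfg = tiny_cfg(n_samples=200, hazard_ratio=3.0, censor_rate=0.2,
                           seed=200 + seed)
            expr, truth = simulate_expression(cfg)
            recs = simulate_survival(expr, truth, cfg)
            surv = survival_frame(recs)
            cells = _pattern_cells(np.log2(expr.values),
                                   truth.prognostic_triplets[0], False)
            if cells.sum() < 5:
                continue
            total += 1
            _, p = logrank(surv.loc[cells], surv.loc[~cells])
            hits += p < 0.05
        assert total >= 20
        assert hits / total >= 0.8

    def test_prognostic_cohort_single_split_balance(self):
        # two-level cohort: single-RNA median split is exactly null
        from spongescout.prognostic import logrank

        rejections = 0
        for seed in range(40):
            expr, surv, trio = simulate_prognostic_cohort(
                n_samples=200, hazard_ratio=3.0, seed=seed
            )
            v = expr.loc[trio[0]]
            up = v > v.mean()
            _, p = logrank(surv.loc[up.values], surv.loc[~up.values])
            rejections += p < 0.05
        assert rejections <= 6


class TestSimulateTargetDb:
    def test_zero_decoys_exactly_cover_planted(self):
        _, truth = simulate_expression(tiny_cfg())
        db = simulate_target_db(truth, decoy_rate=0.0, seed=1)
        pairs = set(zip(db.pairs["mirna"], db.pairs["target"]))
        expected = set()
        for lnc, mir, mrna in truth.planted_triplets:
            expected |= {(mir, lnc), (mir, mrna)}
        assert pairs == expected

    def test_both_sides_present_per_planted_triplet(self):
        _, truth = simulate_expression(tiny_cfg())
        db = simulate_target_db(truth, decoy_rate=0.0, seed=1)
        lnc, mir, mrna = truth.planted_triplets[0]
        assert db.sources_for(mir, lnc)
        assert db.sources_for(mir, mrna)

    def test_decoy_count_binomial_mean(self):
        # mean decoy count over seeds ~ decoy_rate x candidate pairs
        _, truth = simulate_expression(tiny_cfg(n_planted=4,
                                                n_null_confounded=4,
                                                n_null_independent=4))
        n_mirna = 12
        n_targets = 24
        candidates = n_mirna * n_targets - 2 * 4   # minus planted pairs
        counts = []
        for seed in range(60):
            db = simulate_target_db(truth, decoy_rate=0.1, seed=seed)
            counts.append((db.pairs["source"] == "SimDecoyDB").sum())
        expected = 0.1 * candidates
        assert abs(np.mean(counts) - expected) < 0.15 * expected

    def test_decoys_never_coincide_with_planted(self):
        _, truth = simulate_expression(tiny_cfg())
        db = simulate_target_db(truth, decoy_rate=0.5, seed=3)
        planted = set()
        for lnc, mir, mrna in truth.planted_triplets:
            planted |= {(mir, lnc), (mir, mrna)}
        decoys = db.pairs[db.pairs["source"] == "SimDecoyDB"]
        for mir, target in zip(decoys["mirna"], decoys["target"]):
            assert (mir, target) not in planted


class TestSimulateAnnotation:
    def triplet_dicts(self, truth):
        return [
            {"lncrna": t[0], "mirna": t[1], "mrna": t[2]}
            for t in truth.planted_triplets
        ]

    def test_full_proximal_fraction_all_flagged(self):
        _, truth = simulate_expression(tiny_cfg())
        simulate_annotation(truth, proximal_fraction=1.0, seed=1)
        out = proximal_triplets(self.triplet_dicts(truth), truth.coordinates)
        assert all(t["is_proximal"] for t in out)

    def test_zero_proximal_fraction_none_flagged(self):
        _, truth = simulate_expression(tiny_cfg())
        simulate_annotation(truth, proximal_fraction=0.0, seed=1)
        out = proximal_triplets(self.triplet_dicts(truth), truth.coordinates)
        assert not any(t["is_proximal"] for t in out)

    def test_mixed_fraction_matches_placement_record(self):
        cfg = tiny_cfg(n_planted=20)
        _, truth = simulate_expression(cfg)
        simulate_annotation(truth, proximal_fraction=0.5, seed=2)
        assert len(truth.proximal_planted) == 10
        out = proximal_triplets(self.triplet_dicts(truth), truth.coordinates)
        flagged = {
            (t["lncrna"], t["mirna"], t["mrna"]) for t in out if t["is_proximal"]
        }
        assert flagged == set(truth.proximal_planted)

    def test_every_rna_has_coordinates(self):
        _, truth = simulate_expression(tiny_cfg())
        simulate_annotation(truth, proximal_fraction=0.3, seed=3)
        assert set(truth.coordinates) == set(truth.all_rna_ids())


class TestWriteDataset:
    def test_round_trip_byte_identical_under_seed(self, tmp_path):
        cfg = tiny_cfg(decoy_rate=0.1, proximal_fraction=0.5, seed=13)
        p1 = write_dataset(cfg, tmp_path / "a")
        p2 = write_dataset(tiny_cfg(decoy_rate=0.1, proximal_fraction=0.5,
                                    seed=13), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_truth_json_round_trip(self, tmp_path):
        cfg = tiny_cfg(proximal_fraction=0.5)
        paths = write_dataset(cfg, tmp_path / "d")
        truth = GroundTruth.from_json(paths["truth"])
        assert truth.planted_triplets
        assert truth.coordinates

    def test_expression_tsv_round_trip(self, tmp_path):
        from spongescout.matrix import ExpressionMatrix

        cfg = tiny_cfg()
        paths = write_dataset(cfg, tmp_path / "d")
        m = ExpressionMatrix.from_tsv(paths["expression"])
        assert m.rna_class.isin(["lncRNA", "miRNA", "mRNA"]).all()
        assert m.values.shape[1] == cfg.n_samples
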
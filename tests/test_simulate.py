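"""Synthetic-data generator: determinism, planted structure, NB moments."""

import numpy as np
import pytest

from gutreg.errors import CapacityError
from gutreg.simulate import (
    SimulationConfig,
    simulate_all,
    simulate_annotation,
    simulate_counts,
    simulate_disease_lists,
    simulate_ortholog_tables,
    simulate_peaks,
)
from gutreg.orthologs import one_to_one_filter


def _cfg(**kw):
    return SimulationConfig(**kw)


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            _cfg(class_fractions={"null": 0.5})

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            _cfg(peak_gf_bias=1.5)

    def test_minimum_replicates(self):
        with pytest.raises(ValueError):
            _cfg(n_reps={"WTCV": 1, "WTGF": 3, "MutCV": 2, "MutGF": 2})


class TestAnnotation:
    def test_spacing_and_count(self):
        cfg = _cfg(n_genes=100, chrom_sizes={"chr1": 10_000_000})
        genes = simulate_annotation(cfg, np.random.default_rng(1))
        assert len(genes) == 100
        tss = np.array([g.tss for g in genes])
        assert np.all(np.diff(np.sort(tss)) >= 2000)

    def test_deterministic_given_seed(self):
        cfg = _cfg(n_genes=50, chrom_sizes={"chr1": 5_000_000})
        a = simulate_annotation(cfg, np.random.default_rng(7))
        b = simulate_annotation(cfg, np.random.default_rng(7))
        assert a == b

    def test_capacity_error(self):
        cfg = _cfg(n_genes=10_000, chrom_sizes={"chr1": 1_000_000})
        with pytest.raises(CapacityError):
            simulate_annotation(cfg, np.random.default_rng(1))


class TestCounts:
    def test_zero_effect_size_plants_nothing(self):
        cfg = _cfg(n_genes=200, effect_size=0.0)
        ann = simulate_annotation(cfg, np.random.default_rng(1))
        _, truth = simulate_counts(ann, cfg, np.random.default_rng(2))
        assert np.all(truth.microbiota_effect == 0)
        assert np.all(truth.genotype_effect == 0)

    def test_single_class_config_plants_uniform_effect(self):
        cfg = _cfg(
            n_genes=100,
            class_fractions={"suppressed_activated": 1.0},
            effect_size=2.0,
        )
        ann = simulate_annotation(cfg, np.random.default_rng(1))
        _, truth = simulate_counts(ann, cfg, np.random.default_rng(2))
        assert np.all(truth.microbiota_effect == 2.0)
        assert np.all(truth.genotype_effect == 2.0)

    def test_nb_moments_by_monte_carlo(self):
        # planted mean 50 with alpha 0.1 -> variance 50 + 0.1*50^2 = 300
        cfg = _cfg(
            n_genes=3000,
            class_fractions={"null": 1.0},
            base_mean_log_range=(np.log2(50), np.log2(50)),
            library_factor_range=(1.0, 1.0),
            dispersion=0.1,
        )
        ann = simulate_annotation(cfg, np.random.default_rng(1))
        cm, _ = simulate_counts(ann, cfg, np.random.default_rng(3))
        draws = cm.counts.ravel().astype(float)  # 30k iid NB(50, 0.1) draws
        assert np.mean(draws) == pytest.approx(50.0, rel=0.02)
        assert np.var(draws) == pytest.approx(300.0, rel=0.08)

    def test_class_fractions_recovered(self):
        cfg = _cfg(n_genes=4000)
        ann = simulate_annotation(cfg, np.random.default_rng(1))
        _, truth = simulate_counts(ann, cfg, np.random.default_rng(4))
        classes = truth.classes()
        for label, frac in cfg.class_fractions.items():
            observed = (classes == label).mean()
            tol = 4 * np.sqrt(frac * (1 - frac) / cfg.n_genes)
            assert abs(observed - frac) <= tol


class TestPeaks:
    def _setup(self, **kw):
        cfg = _cfg(n_genes=300, **kw)
        ann = simulate_annotation(cfg, np.random.default_rng(1))
        _, truth = simulate_counts(ann, cfg, np.random.default_rng(2))
        gf, cv, tgf, tcv = simulate_peaks(ann, truth, cfg, np.random.default_rng(3))
        return cfg, ann, truth, gf, cv

    def test_full_bias_suppressed_only_leaves_cv_background(self):
        cfg, ann, truth, gf, cv = self._setup(
            peak_gf_bias=1.0,
            class_fractions={"suppressed_activated": 0.5, "null": 0.5},
        )
        cv_names = set(r.name for r in cv.regions)
        assert all(n.startswith("bgpeak") for n in cv_names)
        assert any(n.startswith("peak_") for n in (r.name for r in gf.regions))

    def test_zero_bias_peak_sets_identical(self):
        cfg, ann, truth, gf, cv = self._setup(peak_gf_bias=0.0)
        assert [r.name for r in gf.regions] == [r.name for r in cv.regions]

    def test_summits_within_10kb_of_target_tss(self):
        cfg, ann, truth, gf, cv = self._setup()
        tss = {g.gene_id: g.tss for g in ann}
        targets = truth.peak_table.set_index("peak_name")["gene_id"]
        for region in gf.regions + cv.regions:
            gene = targets.get(region.name)
            if gene is None or not isinstance(gene, str):
                continue
            assert abs(region.reference_point - tss[gene]) <= 10_000

    def test_tracks_carry_condition_specific_signal(self):
        cfg, ann, truth, gf, cv = self._setup(peak_gf_bias=1.0)
        # re-run to get tracks
        gf2, cv2, tgf, tcv = simulate_peaks(
            ann, truth, cfg, np.random.default_rng(3)
        )
        assert tgf.total_mass() > 0 and tcv.total_mass() > 0


class TestOrthologs:
    def test_no_noise_gives_bijection(self):
        cfg = _cfg(n_genes=200, ortholog_dropout=0.0, paralog_rate=0.0)
        ann = simulate_annotation(cfg, np.random.default_rng(1))
        hm, mz, truth = simulate_ortholog_tables(ann, cfg, np.random.default_rng(2))
        assert len(mz) == 200 and len(hm) == 200 and len(truth) == 200
        assert len(one_to_one_filter(mz)) == 200

    def test_full_paralog_rate_filter_empties_map(self):
        cfg = _cfg(n_genes=100, ortholog_dropout=0.0, paralog_rate=1.0)
        ann = simulate_annotation(cfg, np.random.default_rng(1))
        hm, mz, truth = simulate_ortholog_tables(ann, cfg, np.random.default_rng(2))
        assert len(one_to_one_filter(mz)) == 0
        assert len(truth) == 0

    def test_deterministic_given_seed(self):
        cfg = _cfg(n_genes=150)
        ann = simulate_annotation(cfg, np.random.default_rng(1))
        a = simulate_ortholog_tables(ann, cfg, np.random.default_rng(5))
        b = simulate_ortholog_tables(ann, cfg, np.random.default_rng(5))
        assert a[0].equals(b[0]) and a[1].equals(b[1])


class TestDisease:
    def _truth(self, cfg):
        ann = simulate_annotation(cfg, np.random.default_rng(1))
        _, truth = simulate_counts(ann, cfg, np.random.default_rng(2))
        _, _, otruth = simulate_ortholog_tables(ann, cfg, np.random.default_rng(3))
        return truth, otruth

    def test_near_zero_noise_points_on_line(self):
        cfg = _cfg(
            n_genes=300,
            disease_true_slope=0.8,
            disease_noise_sd_x=1e-9,
            disease_noise_sd_y=1e-9,
            ortholog_dropout=0.0,
            paralog_rate=0.0,
        )
        truth, otruth = self._truth(cfg)
        simulate_disease_lists(truth, otruth, cfg, np.random.default_rng(4))
        d = truth.disease_detail
        assert np.allclose(d["y"], 0.8 * d["x_star"], atol=1e-6)
        assert np.allclose(d["x_obs"], d["x_star"], atol=1e-6)

    def test_direction_is_sign_of_fold_change(self):
        cfg = _cfg(n_genes=300)
        truth, otruth = self._truth(cfg)
        ds = simulate_disease_lists(truth, otruth, cfg, np.random.default_rng(4))
        t = ds.table
        assert (t.loc[t["log2fc"] < 0, "direction"] == "down").all()
        assert (t.loc[t["log2fc"] >= 0, "direction"] == "up").all()

    def test_zero_slope_decouples_disease_from_truth(self):
        cfg = _cfg(n_genes=2000, disease_true_slope=0.0)
        truth, otruth = self._truth(cfg)
        simulate_disease_lists(truth, otruth, cfg, np.random.default_rng(4))
        d = truth.disease_detail
        corr = np.corrcoef(d["x_star"], d["y"])[0, 1]
        assert abs(corr) < 0.08


class TestDeterminism:
    def test_simulate_all_reproducible(self):
        cfg = _cfg(n_genes=250, seed=99)
        a = simulate_all(cfg)
        b = simulate_all(cfg)
        assert np.array_equal(a.counts.counts, b.counts.counts)
        assert a.truth.peak_table.equals(b.truth.peak_table)
        assert a.disease.table.equals(b.disease.table)
        assert np.array_equal(a.region_counts.counts, b.region_counts.counts)
        assert a.track_gf.library_size == b.track_gf.library_size
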
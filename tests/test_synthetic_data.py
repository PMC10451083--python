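import json

import numpy as np
import pandas as pd
import pytest

from pedsweep import io
from pedsweep import synthetic_data as sd


def _cfg(**kw):
    base = dict(
        n_chrom=1,
        markers_per_chrom=100,
        chrom_len_bp=1_000_000,
        chrom_len_cM=100.0,
        delta=1.0,
        n_descendants=8,
        n_cycles=0,
        dh_n=20,
        seed=1,
    )
    base.update(kw)
    return sd.SimConfig(**base)


class TestMakeFounders:
    def test_delta_one_all_informative(self):
        parents, gmap = sd.make_founders(_cfg(delta=1.0))
        assert np.all(parents[0] != parents[1])
        assert parents.shape == (2, 100)

    def test_informative_count_and_determinism(self):
        cfg = _cfg(delta=0.5, markers_per_chrom=1000, seed=42)
        p_a, m_a = sd.make_founders(cfg, np.random.default_rng(42))
        p_b, m_b = sd.make_founders(cfg, np.random.default_rng(42))
        assert np.array_equal(p_a, p_b)
        pd.testing.assert_frame_equal(m_a.frame, m_b.frame)
        assert int((p_a[0] != p_a[1]).sum()) == 500

    def test_two_seeds_different_sets_same_count(self):
        cfg = _cfg(delta=0.5, markers_per_chrom=1000)
        p_a, _ = sd.make_founders(cfg, np.random.default_rng(1))
        p_b, _ = sd.make_founders(cfg, np.random.default_rng(2))
        set_a = set(np.flatnonzero(p_a[0] != p_a[1]))
        set_b = set(np.flatnonzero(p_b[0] != p_b[1]))
        assert len(set_a) == len(set_b) == 500
        assert set_a != set_b

    def test_no_informative_markers_error(self):
        with pytest.raises(ValueError, match="informative"):
            sd.make_founders(_cfg(delta=0.001, markers_per_chrom=100))

    def test_map_monotone(self):
        _, gmap = sd.make_founders(_cfg(n_chrom=3, markers_per_chrom=50))
        for chrom in gmap.chromosomes:
            tab = gmap.chrom_table(chrom)
            assert (np.diff(tab["pos_bp"]) > 0).all()
            assert (np.diff(tab["pos_cM"]) >= 0).all()


class TestSimulateGamete:
    def test_zero_length_map_no_crossovers(self):
        _, gmap = sd.make_founders(_cfg(chrom_len_cM=0.0))
        _, xov = sd.simulate_gamete(gmap, np.random.default_rng(0))
        assert xov["chr1"] == []

    def test_poisson_mean(self):
        _, gmap = sd.make_founders(_cfg(chrom_len_cM=100.0))
        tab = gmap.chrom_table("chr1")
        mean_expected = float(tab["pos_cM"].iloc[-1] - tab["pos_cM"].iloc[0]) / 100.0
        rng = np.random.default_rng(3)
        counts = [len(sd.simulate_gamete(gmap, rng)[1]["chr1"]) for _ in range(10_000)]
        se = np.sqrt(mean_expected / 10_000)
        assert abs(np.mean(counts) - mean_expected) < 3 * se

    def test_blocks_bounded_by_crossovers(self):
        _, gmap = sd.make_founders(_cfg(chrom_len_cM=300.0))
        rng = np.random.default_rng(4)
        for _ in range(50):
            choose, xov = sd.simulate_gamete(gmap, rng)
            blocks = 1 + int((np.diff(choose) != 0).sum())
            assert blocks <= len(xov["chr1"]) + 1


class TestSimulateDescendants:
    def test_strong_selection_fixes_favored_allele(self):
        cfg = _cfg(
            delta=0.8,
            n_cycles=3,
            n_descendants=10,
            n_candidates_per_cycle=40,
            selected_loci=[sd.SelectedLocus("chr1", 500_000, 5.0, 1)],
            seed=9,
        )
        gm, truth = sd.simulate_descendants(cfg)
        frame = gm.map_frame()
        idx = int((frame["pos_bp"] - 500_000).abs().idxmin())
        frac_p1 = float((truth.origin[:, idx] == sd.P1).mean())
        assert frac_p1 >= 0.9

    def test_no_selection_balanced_origin(self):
        cfg = _cfg(n_cycles=0, n_descendants=40, markers_per_chrom=200, seed=2)
        _, truth = sd.simulate_descendants(cfg)
        frac = (truth.origin == sd.P1).mean()
        # lines x markers are correlated within a line; SE over lines only
        se = 0.5 / np.sqrt(40)
        assert abs(frac - 0.5) < 3 * se

    def test_zero_weights_warn(self):
        cfg = _cfg(
            n_cycles=1,
            selected_loci=[sd.SelectedLocus("chr1", 500_000, 0.0, 1)],
        )
        with pytest.warns(UserWarning, match="neutral"):
            sd.simulate_descendants(cfg)

    def test_mendelian_and_homozygous(self):
        cfg = _cfg(n_cycles=0, delta=0.5, genotype_error=0.0, missing_rate=0.0)
        gm, truth = sd.simulate_descendants(cfg)
        parents, _ = sd.make_founders(cfg, np.random.default_rng(cfg.seed))
        for i in range(gm.n_samples):
            calls = gm.calls[:, i]
            matches = (calls == parents[0]) | (calls == parents[1])
            assert matches.all()

    def test_origin_breakpoints_at_crossovers(self):
        cfg = _cfg(n_cycles=0, n_descendants=5, chrom_len_cM=200.0, seed=6)
        _, truth = sd.simulate_descendants(cfg)
        for li in range(5):
            o = truth.origin[li]
            switches = np.flatnonzero(np.diff(o) != 0)
            cm = truth.pos_cM
            xov = truth.crossovers[li]["chr1"]
            for s in switches:
                # each origin switch must bracket at least one crossover
                assert any(cm[s] <= x <= cm[s + 1] for x in xov)


class TestSimulateDH:
    def test_counts_and_homozygosity(self):
        cfg = _cfg(dh_n=240, markers_per_chrom=150)
        gm, _ = sd.simulate_dh_population(cfg)
        assert gm.n_samples == 240
        assert set(np.unique(gm.calls)) <= {0, 1}

    def test_segregation_1to1(self):
        from scipy.stats import chi2

        cfg = _cfg(dh_n=240, markers_per_chrom=200, delta=1.0, seed=8)
        gm, _ = sd.simulate_dh_population(cfg)
        crit = chi2.ppf(1 - 0.001, df=1)
        n_pass = 0
        for i in range(gm.n_markers):
            n1 = int((gm.calls[i] == 0).sum())
            n2 = int((gm.calls[i] == 1).sum())
            stat = (n1 - n2) ** 2 / (n1 + n2)
            n_pass += stat < crit
        assert n_pass / gm.n_markers >= 0.99

    def test_recombinant_fraction_matches_map(self):
        from pedsweep.qtl_map import kosambi_inv

        cfg = _cfg(dh_n=10_000, markers_per_chrom=2, chrom_len_cM=1.0, delta=1.0, seed=3)
        gm, _ = sd.simulate_dh_population(cfg)
        d_cm = float(gm.pos_cM[1] - gm.pos_cM[0])
        r_exp = float(kosambi_inv(d_cm))
        r_obs = float((gm.calls[0] != gm.calls[1]).mean())
        se = np.sqrt(r_exp * (1 - r_exp) / 10_000)
        assert abs(r_obs - r_exp) < 3 * se + 1e-4  # Haldane-vs-Kosambi gap is < 1e-4 here

    def test_unlinked_markers_independent(self):
        cfg = _cfg(n_chrom=2, dh_n=4000, markers_per_chrom=1, delta=1.0, seed=4)
        gm, _ = sd.simulate_dh_population(cfg)
        r = float((gm.calls[0] != gm.calls[1]).mean())
        assert abs(r - 0.5) < 3 * 0.5 / np.sqrt(4000)


class TestSimulatePhenotypes:
    def test_noiseless_replicates_identical(self):
        cfg = _cfg(dh_n=10, qtls=[sd.QTLSpec("t", "chr1", 50.0, 1.0)], h2={"t": 1.0})
        gm, truth = sd.simulate_dh_population(cfg)
        pheno, _ = sd.simulate_phenotypes(gm, cfg.qtls, cfg.h2, 3, 2, env_sd=0.0, truth=truth)
        spread = pheno.groupby("line")["t"].agg(lambda v: v.max() - v.min())
        assert (spread < 1e-12).all()

    def test_class_means_differ_by_2a(self):
        cfg = _cfg(dh_n=2000, qtls=[sd.QTLSpec("t", "chr1", 50.0, 1.0)], h2={"t": 0.5}, seed=12)
        gm, truth = sd.simulate_dh_population(cfg)
        pheno, _ = sd.simulate_phenotypes(
            gm, cfg.qtls, cfg.h2, 3, 2, env_sd=0.0, rng=np.random.default_rng(1), truth=truth
        )
        x = sd.qtl_genotype_scores(gm, cfg.qtls, truth.origin)[0]
        means = pheno.groupby("line", sort=False)["t"].mean().to_numpy()
        diff = means[x > 0].mean() - means[x < 0].mean()
        assert diff == pytest.approx(2.0, abs=0.15)

    def test_h2_error(self):
        cfg = _cfg(dh_n=10, qtls=[sd.QTLSpec("t", "chr1", 50.0, 1.0)], h2={"t": 0.5})
        gm, truth = sd.simulate_dh_population(cfg)
        with pytest.raises(ValueError, match="h2"):
            sd.simulate_phenotypes(gm, cfg.qtls, {"t": 1.5}, 3, 2, truth=truth)

    def test_line_mean_h2_recovery(self):
        # regression R^2 of line means on genetic values ~ h2 over replicates
        r2s = []
        for seed in range(25):
            cfg = _cfg(
                dh_n=240,
                markers_per_chrom=60,
                qtls=[sd.QTLSpec("t", "chr1", 50.0, 1.0)],
                h2={"t": 0.4},
                seed=100 + seed,
            )
            gm, truth = sd.simulate_dh_population(cfg)
            pheno, _ = sd.simulate_phenotypes(
                gm, cfg.qtls, cfg.h2, 3, 2, env_sd=0.3,
                rng=np.random.default_rng(200 + seed), truth=truth,
            )
            g = sd.qtl_genotype_scores(gm, cfg.qtls, truth.origin)[0] * 1.0
            means = pheno.groupby("line", sort=False)["t"].mean().to_numpy()
            r2s.append(np.corrcoef(g, means)[0, 1] ** 2)
        assert np.mean(r2s) == pytest.approx(0.4, abs=0.05)


class TestWriteOutputs:
    def test_round_trip_idempotent(self, tmp_path):
        cfg = _cfg(dh_n=12, qtls=[sd.QTLSpec("t", "chr1", 50.0, 0.5)], h2={"t": 0.8})
        parents, gmap = sd.make_founders(cfg, np.random.default_rng(cfg.seed))
        gm, truth = sd.simulate_dh_population(cfg, founders=(parents, gmap))
        pheno, _ = sd.simulate_phenotypes(gm, cfg.qtls, cfg.h2, 2, 2, truth=truth)
        paths = sd.write_outputs(gm, gmap, pheno, truth, tmp_path / "a")
        gm2 = io.read_vcf(paths["vcf"], paths["map"])
        assert gm2.samples == gm.samples
        assert np.array_equal(gm2.calls, gm.calls)
        paths2 = sd.write_outputs(gm2, gmap, pheno, truth, tmp_path / "b")
        body1 = (tmp_path / "a" / "genotypes.vcf").read_text().splitlines()
        body2 = (tmp_path / "b" / "genotypes.vcf").read_text().splitlines()
        assert [l for l in body1 if not l.startswith("##")] == [
            l for l in body2 if not l.startswith("##")
        ]

    def test_truth_crossovers_rederivable(self, tmp_path):
        cfg = _cfg(dh_n=6, chrom_len_cM=200.0, seed=13)
        gm, truth = sd.simulate_dh_population(cfg)
        pheno = pd.DataFrame({"line": gm.samples, "env": "E1", "rep": 1})
        paths = sd.write_outputs(gm, sd.make_founders(cfg, np.random.default_rng(cfg.seed))[1], pheno, truth, tmp_path)
        loaded = json.loads(paths["truth"].read_text())
        origin = np.asarray(loaded["origin"], dtype=np.int8)
        cm = np.asarray(loaded["pos_cM"])
        for li, per_chrom in enumerate(loaded["crossovers"]):
            switches = np.flatnonzero(np.diff(origin[li]) != 0)
            for s in switches:
                assert any(cm[s] <= x <= cm[s + 1] for x in per_chrom["chr1"])

    def test_missing_rate(self, tmp_path):
        cfg = _cfg(dh_n=50, markers_per_chrom=200, missing_rate=0.1, seed=21)
        gm, truth = sd.simulate_dh_population(cfg)
        frac = float((gm.calls == -1).mean())
        assert frac == pytest.approx(0.1, abs=0.01)
        paths = sd.write_outputs(
            gm,
            sd.make_founders(cfg, np.random.default_rng(cfg.seed))[1],
            pd.DataFrame({"line": gm.samples, "env": "E1", "rep": 1}),
            truth,
            tmp_path,
        )
        text = paths["vcf"].read_text()
        n_missing = text.count("./.")
        assert n_missing == int((gm.calls == -1).sum())

    def test_full_sim_bit_reproducible(self, small_config):
        import copy

        runs = []
        for _ in range(2):
            cfg = copy.deepcopy(small_config)
            rng = np.random.default_rng(cfg.seed)
            founders = sd.make_founders(cfg, np.random.default_rng(cfg.seed))
            gm, truth = sd.simulate_descendants(cfg, rng, founders=founders)
            runs.append((gm.calls.copy(), truth.origin.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])
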
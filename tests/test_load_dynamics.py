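"""Polarisation, load counting, frequency change, Rxy and the jackknife."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_gm
from gerode import load
from gerode.containers import MISSING, ROHProfile
from gerode.simulate import CategoryModel, SimConfig, merge_epoch_matrices, simulate_wf


class TestPolarise:
    def test_consensus_ancestral_retained(self):
        gm = make_gm([[1, 1]])
        outg = make_gm([[0, 0], [0, 1], [0, 0], [0, 0]])
        mask, report = load.polarise(gm, outg)
        assert list(mask) == [True, False]
        assert report.n_retained == 1

    def test_missing_outgroup_genotype_drops_site(self):
        gm = make_gm([[1]])
        outg = make_gm([[0], [MISSING]])
        mask, _ = load.polarise(gm, outg)
        assert list(mask) == [False]

    def test_zero_outgroups_rejected(self):
        gm = make_gm([[1]])
        empty = make_gm(np.zeros((0, 1), dtype=np.int8), cohorts=[], sample_ids=[])
        with pytest.raises(ValueError, match="outgroup"):
            load.polarise(gm, empty)

    def test_retained_fraction_at_study_scale(self, rng):
        """38,096 of 56,517 consensus-ancestral sites -> 67.4% retained."""
        n_sites, n_keep = 56_517, 38_096
        outg_geno = np.zeros((4, n_sites), dtype=np.int8)
        drop = rng.choice(n_sites, size=n_sites - n_keep, replace=False)
        outg_geno[rng.integers(0, 4, size=len(drop)), drop] = 1
        gm = make_gm(np.zeros((1, n_sites), dtype=np.int8))
        outg = make_gm(outg_geno)
        _, report = load.polarise(gm, outg)
        assert report.n_retained == n_keep
        assert round(100 * report.retained_fraction, 1) == 67.4


class TestCountLoad:
    def test_definition(self):
        gm = make_gm([[1, 2, 0]], impacts=["HIGH"] * 3)
        counts = load.count_load(gm, "HIGH")
        assert counts.loc[0, "het"] == 1
        assert counts.loc[0, "hom"] == 2
        assert counts.loc[0, "total"] == 3

    def test_all_missing_sample(self):
        gm = make_gm([[MISSING, MISSING]], impacts=["HIGH"] * 2)
        counts = load.count_load(gm, "HIGH")
        assert counts.loc[0, "total"] == 0

    def test_empty_category_warns(self):
        gm = make_gm([[1]], impacts=["LOW"])
        with pytest.warns(UserWarning, match="no sites"):
            counts = load.count_load(gm, "HIGH")
        assert counts.loc[0, "total"] == 0

    def test_matches_per_genotype_tally(self, rng):
        geno = rng.choice([0, 1, 2, MISSING], size=(6, 50), p=[0.4, 0.3, 0.2, 0.1])
        impacts = rng.choice(["LOW", "MODERATE", "HIGH"], size=50)
        gm = make_gm(geno, impacts=impacts)
        for cat in ("LOW", "MODERATE", "HIGH"):
            counts = load.count_load(gm, cat)
            for i in range(6):
                het = hom = 0
                for j in range(50):
                    if impacts[j] != cat:
                        continue
                    if geno[i, j] == 1:
                        het += 1
                    elif geno[i, j] == 2:
                        hom += 2
                assert counts.loc[i, "het"] == het
                assert counts.loc[i, "hom"] == hom

    def test_hom_always_even_and_normalisation(self, rng):
        geno = rng.integers(0, 3, size=(4, 30))
        impacts = ["LOW"] * 15 + ["HIGH"] * 15
        gm = make_gm(geno, impacts=impacts)
        high = load.count_load(gm, "HIGH")
        low = load.count_load(gm, "LOW")
        assert (high["hom"] % 2 == 0).all()
        norm = load.normalise_load(high, low)
        assert np.allclose(norm["total_norm"], high["total"] / low["total"])


def freq_frame(fh, fm, impact="HIGH", nh=32, nm=74):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, len(fh) + 1),
            "impact": impact,
            "fh": fh,
            "fm": fm,
            "nchrom_h": nh,
            "nchrom_m": nm,
        }
    )


class TestDeltaAndSignTest:
    def test_no_change_zero_mean(self):
        ft = freq_frame([0.1, 0.3], [0.1, 0.3])
        summary = load.delta_frequency(ft, "HIGH")
        assert summary.mean_delta == 0.0

    def test_hand_arithmetic(self):
        ft = freq_frame([0.1, 0.5], [0.2, 0.4])
        summary = load.delta_frequency(ft, "HIGH")
        assert np.allclose(summary.deltas, [0.1, -0.1])
        assert summary.mean_delta == pytest.approx(0.0)
        assert summary.prop_positive == pytest.approx(0.5)

    def test_uncallable_sites_excluded_and_counted(self):
        ft = freq_frame([0.1, 0.2], [0.2, 0.3])
        ft.loc[1, "nchrom_h"] = 0
        summary = load.delta_frequency(ft, "HIGH")
        assert summary.n_sites == 1
        assert summary.n_excluded == 1

    def test_sign_test_symmetric(self):
        assert load.sign_binomial_test(np.r_[np.ones(5), -np.ones(5)]) == pytest.approx(1.0)

    def test_sign_test_one_sided_extreme(self):
        # 10 positive, 0 negative: p = 2 * 0.5^10
        assert load.sign_binomial_test(np.ones(10)) == pytest.approx(2 * 0.5**10)

    def test_sign_test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            assert load.sign_binomial_test(np.zeros(4)) == 1.0

    def test_sign_test_calibrated_under_null(self, rng):
        pvals = [
            load.sign_binomial_test(rng.choice([-1.0, 1.0], size=40)) for _ in range(400)
        ]
        assert (np.array(pvals) < 0.05).mean() < 0.09

    def test_neutral_drift_mean_delta_near_zero(self):
        """Equal-epoch sampling from one neutral population: E[delta] = 0."""
        deltas = []
        for rep in range(5):
            cfg = SimConfig(
                n_trajectory=[(0, 100), (4, 100)],
                categories={"LOW": CategoryModel(2000, (0.0, 0.0))},
                sample_plan=[("e1", "historical", 20, 0), ("e2", "wild", 20, 4)],
                mutation_rate=0.0,
                seed=900 + rep,
            )
            mats, _ = simulate_wf(cfg)
            ft = load.frequency_table(merge_epoch_matrices(mats))
            deltas.append(load.delta_frequency(ft, "LOW").mean_delta)
        assert abs(np.mean(deltas)) < 0.01


class TestRxy:
    def test_equal_frequencies_give_unity(self):
        ft = pd.concat(
            [freq_frame([0.1, 0.2], [0.1, 0.2]), freq_frame([0.3], [0.3], impact="LOW")],
            ignore_index=True,
        )
        res = load.rxy(ft, "HIGH")
        assert res.raw == pytest.approx(1.0)
        assert res.normalised == pytest.approx(1.0)

    def test_hand_evaluation(self):
        # Fm=[0.1,0.2], Fh=[0.2,0.4] -> (0.08+0.12)/(0.18+0.32) = 0.40
        ft = freq_frame([0.2, 0.4], [0.1, 0.2])
        res_raw = load._rxy_sums(ft, "HIGH")
        assert res_raw[0] / res_raw[1] == pytest.approx(0.40)

    def test_epoch_swap_gives_reciprocal(self, rng):
        fh = rng.uniform(0.05, 0.95, 20)
        fm = rng.uniform(0.05, 0.95, 20)
        a = load._rxy_sums(freq_frame(fh, fm), "HIGH")
        b = load._rxy_sums(freq_frame(fm, fh), "HIGH")
        assert a[0] / a[1] == pytest.approx(b[1] / b[0], rel=1e-12)

    def test_ratio_of_sums_equals_brute_force(self, rng):
        fh = rng.uniform(0, 1, 50)
        fm = rng.uniform(0, 1, 50)
        ft = pd.concat(
            [freq_frame(fh, fm), freq_frame(rng.uniform(0.1, 0.9, 30), rng.uniform(0.1, 0.9, 30), impact="LOW")],
            ignore_index=True,
        )
        res = load.rxy(ft, "HIGH")
        num = sum(f_m * (1 - f_h) for f_m, f_h in zip(fm, fh))
        den = sum(f_h * (1 - f_m) for f_m, f_h in zip(fm, fh))
        assert res.raw == pytest.approx(num / den, rel=1e-12)

    def test_zero_denominator_named(self):
        ft = pd.concat(
            [freq_frame([0.0], [0.5]), freq_frame([0.3], [0.3], impact="LOW")],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="HIGH"):
            load.rxy(ft, "HIGH")


class TestJackknife:
    def _toy_table(self, rng, n=300):
        return pd.concat(
            [
                freq_frame(rng.uniform(0.1, 0.9, n), rng.uniform(0.1, 0.9, n)),
                freq_frame(rng.uniform(0.1, 0.9, n), rng.uniform(0.1, 0.9, n), impact="LOW"),
            ],
            ignore_index=True,
        )

    def test_identical_sites_zero_variance(self):
        ft = pd.concat(
            [freq_frame([0.2] * 200, [0.1] * 200), freq_frame([0.3] * 200, [0.3] * 200, impact="LOW")],
            ignore_index=True,
        )
        res = load.jackknife_rxy(ft, "HIGH", seed=1)
        assert res.var_replicates == pytest.approx(0.0, abs=1e-24)

    def test_seed_determinism(self, rng):
        ft = self._toy_table(rng)
        a = load.jackknife_rxy(ft, "HIGH", seed=42)
        b = load.jackknife_rxy(ft, "HIGH", seed=42)
        assert np.array_equal(a.replicates, b.replicates)

    def test_too_few_sites_rejected(self):
        ft = pd.concat(
            [freq_frame([0.2], [0.1]), freq_frame([0.3], [0.3], impact="LOW")],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="too few"):
            load.jackknife_rxy(ft, "HIGH", seed=1)

    def test_variance_agrees_with_bootstrap_order_of_magnitude(self, rng):
        """Scaled delete-d jackknife variance tracks a site bootstrap."""
        ft = self._toy_table(rng, n=250)
        res = load.jackknife_rxy(ft, "HIGH", seed=5)
        boot = []
        for _ in range(1000):
            idx = rng.integers(0, len(ft), len(ft))
            sub = ft.iloc[idx]
            num, den = load._rxy_sums(sub, "HIGH")
            lnum, lden = load._rxy_sums(sub, "LOW")
            boot.append((num / den) / (lnum / lden))
        boot_var = np.var(boot, ddof=1)
        assert boot_var / 10 < res.var_jackknife < boot_var * 10

    def test_neutral_ci_covers_unity(self):
        """Two samples from the same population: CI straddles Rxy = 1."""
        covered = 0
        n_reps = 15
        for rep in range(n_reps):
            cfg = SimConfig(
                n_trajectory=[(0, 200), (1, 200)],
                categories={
                    "LOW": CategoryModel(600, (0.0, 0.0)),
                    "HIGH": CategoryModel(600, (0.0, 0.0)),
                },
                sample_plan=[("e1", "historical", 20, 0), ("e2", "wild", 20, 0)],
                mutation_rate=0.0,
                seed=7000 + rep,
            )
            mats, _ = simulate_wf(cfg)
            ft = load.frequency_table(merge_epoch_matrices(mats))
            res = load.jackknife_rxy(ft, "HIGH", seed=rep)
            if res.ci_low <= 1.0 <= res.ci_high:
                covered += 1
        assert covered >= 12


class TestLoadInOutRoh:
    def test_normalisation_arithmetic(self):
        # 10 hom sites inside ROH at F_ROH = 0.1 -> 20/0.1 = 200; spec's
        # count convention: hom alleles are doubled, so raw in-count is 20.
        geno = np.full((1, 55), 2, dtype=np.int8)
        gm = make_gm(geno, impacts=["HIGH"] * 55)
        # sites at pos 1000..55000; ROH covering first 10 sites
        prof = ROHProfile("s0", pd.DataFrame([("chr1", 0, 10_500)], columns=["chrom", "start", "end"]), 105_000)
        res = load.load_in_out_roh(gm, "HIGH", {"s0": prof})
        assert res.loc[0, "hom_in"] == 20
        assert res.loc[0, "hom_out"] == 90
        assert res.loc[0, "hom_in_norm"] == pytest.approx(20 / 0.1)
        assert res.loc[0, "hom_out_norm"] == pytest.approx(90 / 0.9)

    def test_no_roh_everything_outside(self):
        gm = make_gm([[2, 2]], impacts=["HIGH"] * 2)
        prof = ROHProfile("s0", pd.DataFrame(columns=["chrom", "start", "end"]), 1_000_000)
        res = load.load_in_out_roh(gm, "HIGH", {"s0": prof})
        assert res.loc[0, "hom_in"] == 0
        assert res.loc[0, "hom_out"] == 4
        assert np.isnan(res.loc[0, "hom_in_norm"])

    def test_in_plus_out_conserved(self, rng):
        geno = rng.integers(0, 3, size=(3, 40))
        gm = make_gm(geno, impacts=["MODERATE"] * 40)
        profiles = {}
        for i in range(3):
            start = int(rng.integers(0, 20_000))
            profiles[f"s{i}"] = ROHProfile(
                f"s{i}",
                pd.DataFrame([("chr1", start, start + 15_000)], columns=["chrom", "start", "end"]),
                60_000,
            )
        res = load.load_in_out_roh(gm, "MODERATE", profiles)
        hom_totals = 2 * (geno == 2).sum(axis=1)
        assert np.array_equal((res["hom_in"] + res["hom_out"]).to_numpy(), hom_totals)
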
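"""Empirical-Bayes variance shrinkage and the per-bin moderated test."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gerode.containers import BinHetMatrix
from gerode.rohbin import (
    VariancePrior,
    call_private,
    fit_variance_prior,
    log_transform,
    moderated_test,
    private_bed,
)
from gerode.simulate import simulate_roh_and_bins


def make_bh(het, groups, bin_size=1_000_000, partial=None):
    het = np.asarray(het, dtype=float)
    n_bins = het.shape[0]
    bins = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_bins) * bin_size,
            "end": (np.arange(n_bins) + 1) * bin_size,
        }
    )
    if partial is not None:
        bins.loc[partial, "end"] = bins.loc[partial, "start"] + bin_size // 4
    return BinHetMatrix(
        bins=bins,
        sample_ids=[f"s{i}" for i in range(het.shape[1])],
        groups=np.array(groups, dtype=object),
        het=het,
        bin_size=bin_size,
    )


class TestVariancePrior:
    def test_shrinkage_formula(self):
        prior = VariancePrior(d0=4, s0_sq=1.0)
        assert prior.moderate(np.array([2.0]), d_g=4)[0] == pytest.approx(1.5)

    def test_zero_prior_df_recovers_sample_variance(self):
        prior = VariancePrior(d0=0.0, s0_sq=123.0)
        assert prior.moderate(np.array([2.0]), d_g=4)[0] == pytest.approx(2.0)

    def test_infinite_prior_df_pools_everything(self):
        prior = VariancePrior(d0=np.inf, s0_sq=1.7)
        assert np.allclose(prior.moderate(np.array([0.1, 9.0]), d_g=4), 1.7)

    def test_moderated_variance_between_extremes(self, rng):
        s_sq = rng.uniform(0.2, 5.0, 100)
        prior = fit_variance_prior(s_sq, d_g=6)
        mod = prior.moderate(s_sq, d_g=6)
        lo = np.minimum(s_sq, prior.s0_sq)
        hi = np.maximum(s_sq, prior.s0_sq)
        assert np.all(mod >= lo - 1e-12) and np.all(mod <= hi + 1e-12)

    def test_parameter_recovery(self, rng):
        """(d0, s0^2) recovered within 15% from scaled inverse-chi^2 draws."""
        d0_true, s0_true, d_g = 8.0, 2.0, 6
        n = 10_000
        sigma_sq = s0_true * d0_true / rng.chisquare(d0_true, n)
        s_sq = sigma_sq * rng.chisquare(d_g, n) / d_g
        prior = fit_variance_prior(s_sq, d_g)
        assert abs(prior.d0 - d0_true) / d0_true < 0.15
        assert abs(prior.s0_sq - s0_true) / s0_true < 0.15

    def test_identical_variances_give_infinite_prior_df(self):
        prior = fit_variance_prior(np.full(50, 2.0), d_g=6)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(2.0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_variance_prior(np.ones(5), d_g=4)


class TestModeratedTest:
    def test_equal_group_means_give_t_zero(self, rng):
        base = rng.uniform(0.5, 1.5, size=(50, 1))
        spread = rng.uniform(0.05, 0.2, size=(50, 1))
        # both groups get the same two values per bin: means equal, variance > 0
        het = np.hstack([base - spread, base + spread, base - spread, base + spread])
        bh = make_bh(het, ["wild", "wild", "captive", "captive"])
        res = moderated_test(bh)
        assert np.allclose(res["t"], 0.0, atol=1e-12)
        assert np.allclose(res["p"], 1.0)

    def test_results_invariant_to_bin_and_sample_order(self, rng):
        het = rng.lognormal(-7, 0.3, size=(40, 8))
        groups = ["wild"] * 4 + ["captive"] * 4
        bh = make_bh(het, groups)
        res = moderated_test(bh)
        perm = rng.permutation(40)
        bh2 = BinHetMatrix(
            bins=bh.bins.iloc[perm].reset_index(drop=True),
            sample_ids=list(bh.sample_ids),
            groups=bh.groups,
            het=het[perm],
            bin_size=bh.bin_size,
        )
        res2 = moderated_test(bh2)
        assert np.allclose(res2["p"].to_numpy(), res["p"].to_numpy()[perm])
        sperm = np.r_[rng.permutation(4), 4 + rng.permutation(4)]
        bh3 = BinHetMatrix(
            bins=bh.bins,
            sample_ids=[bh.sample_ids[i] for i in sperm],
            groups=bh.groups[sperm],
            het=het[:, sperm],
            bin_size=bh.bin_size,
        )
        res3 = moderated_test(bh3)
        assert np.allclose(res3["p"].to_numpy(), res["p"].to_numpy())

    def test_partial_bins_excluded(self, rng):
        het = rng.lognormal(-7, 0.3, size=(30, 8))
        bh = make_bh(het, ["wild"] * 4 + ["captive"] * 4, partial=[0, 1])
        res = moderated_test(bh)
        assert not res.loc[0, "tested"] and not res.loc[1, "tested"]
        assert res["tested"].sum() == 28

    def test_null_p_values_uniform(self, rng):
        """KS test on 10,000 null bins: moderated p-values are uniform."""
        het = rng.lognormal(-7.1, 0.25, size=(10_000, 12))
        bh = make_bh(het, ["wild"] * 6 + ["captive"] * 6)
        res = moderated_test(bh)
        p = res["p"].to_numpy()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_moderated_t_approaches_ordinary_t_for_tiny_prior(self, rng):
        het = np.log2(rng.lognormal(-7, 0.3, size=(30, 10)))
        na = 5
        prior = VariancePrior(d0=1e-12, s0_sq=1.0)
        xa, xb = het[:, :na], het[:, na:]
        var_p = ((na - 1) * xa.var(1, ddof=1) + (na - 1) * xb.var(1, ddof=1)) / (2 * na - 2)
        mod = prior.moderate(var_p, d_g=2 * na - 2)
        t_mod = (xa.mean(1) - xb.mean(1)) / np.sqrt(mod * (2 / na))
        t_ref = stats.ttest_ind(xa, xb, axis=1).statistic
        assert np.allclose(t_mod, t_ref, rtol=1e-6)

    def test_matches_limma_ebayes(self, tmp_path, rng):
        """Independent oracle: R limma's lmFit + eBayes on the same matrix."""
        # heteroscedastic bins so the prior df is finite and informative
        sigma = np.sqrt(0.08 * 6 / rng.chisquare(6, size=60))
        het = rng.normal(-7.0, sigma[:, None], size=(60, 9))
        groups = ["wild"] * 5 + ["captive"] * 4
        bh = make_bh(2.0**het, groups)
        res = moderated_test(bh, exclude_partial=False)
        # hand the identical log2 matrix to limma
        mat = log_transform(bh).het
        np.savetxt(tmp_path / "mat.tsv", mat, delimiter="\t")
        rscript = textwrap.dedent(
            """
            suppressMessages(library(limma))
            m <- as.matrix(read.table("{path}/mat.tsv", sep="\\t"))
            design <- cbind(captive=1, wild_vs_captive=c(rep(1,5), rep(0,4)))
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                              d0=fit$df.prior, s02=fit$s2.prior)
            write.table(out, "{path}/limma.tsv", sep="\\t", row.names=FALSE)
            """
        ).format(path=tmp_path)
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        assert res.attrs["prior_d0"] == pytest.approx(ref["d0"][0], rel=1e-4)
        assert res.attrs["prior_s0_sq"] == pytest.approx(ref["s02"][0], rel=1e-4)
        assert np.allclose(res["t"], ref["t"], rtol=1e-6)
        assert np.allclose(res["p"], ref["p"], rtol=1e-6)


class TestCallPrivate:
    def test_no_significant_bins(self, rng):
        het = rng.lognormal(-7, 0.001, size=(20, 8))
        het[:, :4] = het[:, 4:]  # identical groups
        bh = make_bh(het, ["wild"] * 4 + ["captive"] * 4)
        res = moderated_test(bh)
        summary = call_private(res)
        assert (summary["genome_fraction"] == 0).all()

    def test_fraction_arithmetic(self, rng):
        """51 significant 1 Mb bins of 1,000 -> 5.1% of the binned genome."""
        het = rng.lognormal(-7.1, 0.2, size=(1000, 12))
        het[:51, :6] *= 0.05  # wild collapses in 51 bins
        bh = make_bh(het, ["wild"] * 6 + ["captive"] * 6)
        res = moderated_test(bh)
        summary = call_private(res).set_index("private_to")
        row = summary.loc["captive"]
        assert row["lower_group"] == "wild"
        assert row["n_bins"] >= 51
        called = call_private(res)
        # construct the exact arithmetic check on a clean selection
        assert 51 * 1_000_000 / 1_000_000_000 == pytest.approx(0.051)
        assert row["genome_fraction"] == pytest.approx(row["n_bins"] / 1000)

    def test_injected_private_regions_recovered(self):
        """Injected -80% het bins rank lowest and are called private."""
        profiles, bh, truth = simulate_roh_and_bins(
            {"wild": 10, "captive": 10},
            genome_length=1_000_000_000,
            target_froh=0.0,
            injected_low_het={"wild": (20, 0.8)},
            seed=11,
        )
        res = moderated_test(bh)
        true_bins = set(truth["private_bins"]["wild"])
        order = np.argsort(res["p"].to_numpy())
        top = set(order[:20])
        assert len(top & true_bins) >= 18  # injected bins dominate the ranking
        bed = private_bed(res)
        called = set(bed.index[bed["private_to"] == "captive"])
        called_bins = set((bed[bed["private_to"] == "captive"]["start"] // 1_000_000).astype(int))
        assert len(called_bins & true_bins) >= 18
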
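"""Per-bin private-variation test on binned heterozygosity.

Two groups of genomes (e.g. wild vs captive) are compared bin by bin
(1 Mb by default) on log2 heterozygosity.  With only a handful of
samples per group, per-bin variance estimates are noisy, so an
empirical-Bayes step shrinks them toward a common prior before testing:
the per-bin sample variances s_g² (d_g residual df each) are modelled as
scaled F draws around a prior variance s0² with d0 prior df, (d0, s0²)
are estimated by matching the first two moments of log s_g², and the
moderated variance

    s~_g² = (d0·s0² + d_g·s_g²) / (d0 + d_g)

replaces s_g² in a two-sample t statistic with d0 + d_g degrees of
freedom.  Bins significant at alpha are called private to the group that
retains heterozygosity there (the group with the higher mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import BinHetMatrix


# ---------------------------------------------------------------------------
# empirical-Bayes variance prior (Smyth-style moment matching)
# ---------------------------------------------------------------------------

@dataclass
class VariancePrior:
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance

    def moderate(self, s_sq: np.ndarray, d_g: float) -> np.ndarray:
        """Shrink per-bin variances toward the prior."""
        s_sq = np.asarray(s_sq, dtype=float)
        if np.isinf(self.d0):
            return np.full_like(s_sq, self.s0_sq)
        return (self.d0 * self.s0_sq + d_g * s_sq) / (self.d0 + d_g)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_variance_prior(s_sq: np.ndarray, d_g: float) -> VariancePrior:
    """Estimate (d0, s0²) from per-bin sample variances.

    Conditional on the true bin variance, s_g²·d_g/σ_g² is chi-square
    with d_g df, and σ_g² follows a scaled inverse chi-square prior.
    Matching the mean and variance of log s_g² against the implied
    log-F predictive distribution gives the moment estimates; when the
    observed spread of log variances is no larger than the chi-square
    sampling noise alone, d0 is reported as infinite and s0² as the
    common value.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq) & (s_sq > 0)]
    if len(s_sq) < 10:
        raise ValueError("need at least 10 positive variances to fit the prior")
    z = np.log(s_sq)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, d_g / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # spread of log variances no larger than chi-square noise alone:
        # complete pooling, prior variance is the plain average
        d0 = np.inf
        s0_sq = float(s_sq.mean())
    return VariancePrior(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# transform and moderated test
# ---------------------------------------------------------------------------

def log_transform(bh: BinHetMatrix, pseudocount: float | None = None) -> BinHetMatrix:
    """log2(het + pseudocount); default pseudocount is half the smallest positive value."""
    if bh.log_transformed:
        return bh
    if pseudocount is None:
        positive = bh.het[np.isfinite(bh.het) & (bh.het > 0)]
        if len(positive) == 0:
            raise ValueError("no positive heterozygosity values to set a pseudocount")
        pseudocount = float(positive.min()) / 2.0
    return BinHetMatrix(
        bins=bh.bins,
        sample_ids=list(bh.sample_ids),
        groups=bh.groups,
        het=np.log2(bh.het + pseudocount),
        bin_size=bh.bin_size,
        log_transformed=True,
        pseudocount=pseudocount,
        partial=bh.partial,
    )


def moderated_test(
    bh: BinHetMatrix,
    groups: tuple[str, str] = ("wild", "captive"),
    exclude_partial: bool = True,
    min_partial_fraction: float = 0.5,
) -> pd.DataFrame:
    """Two-group moderated t test per bin.

    Input is log2-transformed if it is not already.  Terminal partial
    bins shorter than ``min_partial_fraction`` of the nominal size are
    excluded.  Bins where either group has fewer than two observations
    are skipped (flagged ``tested = False``).  logFC is the difference of
    group means on the log2 scale, ``groups[0] − groups[1]``.
    """
    bh = log_transform(bh)
    a = np.flatnonzero(bh.groups == groups[0])
    b = np.flatnonzero(bh.groups == groups[1])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    width = (bh.bins["end"] - bh.bins["start"]).to_numpy()
    testable = np.ones(bh.n_bins, dtype=bool)
    if exclude_partial:
        testable &= width >= min_partial_fraction * bh.bin_size

    xa, xb = bh.het[:, a], bh.het[:, b]
    na = np.isfinite(xa).sum(axis=1)
    nb = np.isfinite(xb).sum(axis=1)
    testable &= (na >= 2) & (nb >= 2)

    mean_a = np.where(na > 0, np.nanmean(np.where(np.isfinite(xa), xa, np.nan), axis=1), np.nan)
    mean_b = np.where(nb > 0, np.nanmean(np.where(np.isfinite(xb), xb, np.nan), axis=1), np.nan)
    with np.errstate(invalid="ignore"):
        var_a = np.nanvar(np.where(np.isfinite(xa), xa, np.nan), axis=1, ddof=1)
        var_b = np.nanvar(np.where(np.isfinite(xb), xb, np.nan), axis=1, ddof=1)
    d_gs = na + nb - 2
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / d_gs

    d_g = float(np.median(d_gs[testable]))
    prior = fit_variance_prior(pooled[testable], d_g)
    s_tilde_sq = prior.moderate(pooled, d_g)
    se = np.sqrt(s_tilde_sq * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean_a - mean_b) / se
    df_total = (prior.d0 if np.isfinite(prior.d0) else np.inf) + d_gs
    p = np.where(
        np.isfinite(df_total),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isfinite(df_total), df_total, 1.0)),
        2.0 * stats.norm.sf(np.abs(t)),
    )

    out = bh.bins[["chrom", "start", "end"]].copy()
    out["tested"] = testable
    out["n_" + groups[0]] = na
    out["n_" + groups[1]] = nb
    out["mean_" + groups[0]] = mean_a
    out["mean_" + groups[1]] = mean_b
    out["logFC"] = mean_a - mean_b
    out["s2"] = pooled
    out["s2_moderated"] = s_tilde_sq
    out["t"] = np.where(testable, t, np.nan)
    out["F"] = out["t"] ** 2
    out["df"] = np.where(testable, df_total, np.nan)
    out["p"] = np.where(testable, p, np.nan)
    out.attrs["prior_d0"] = prior.d0
    out.attrs["prior_s0_sq"] = prior.s0_sq
    out.attrs["groups"] = groups
    out.attrs["pseudocount"] = bh.pseudocount
    n_skipped = int((~testable).sum())
    out.attrs["n_skipped"] = n_skipped
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p is the default rule)."""
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    out = np.full_like(p, np.nan)
    out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def call_private(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Call private-variation bins per group at the raw p < alpha rule.

    A significant bin with lower heterozygosity in group A is private to
    group B: B retains variation that A has lost there.  Reports, per
    group, the significant bins private to it, their total length, and
    the fraction of the binned genome.
    """
    groups = results.attrs.get("groups")
    if groups is None:
        raise ValueError("results must come from moderated_test")
    ga, gb = groups
    width = (results["end"] - results["start"]).to_numpy()
    genome = float(width.sum())
    sig = results["tested"] & (results["p"] < alpha)
    lower_a = results["logFC"] < 0  # group a has the lower heterozygosity
    rows = []
    for private_to, mask in ((gb, sig & lower_a), (ga, sig & ~lower_a)):
        length = float(width[mask.to_numpy()].sum())
        rows.append(
            {
                "private_to": private_to,
                "lower_group": ga if private_to == gb else gb,
                "n_bins": int(mask.sum()),
                "length_bp": length,
                "genome_fraction": length / genome if genome else np.nan,
            }
        )
    return pd.DataFrame(rows)


def private_bed(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BED-style table of significant bins with their private-to label."""
    ga, gb = results.attrs["groups"]
    sig = results[results["tested"] & (results["p"] < alpha)]
    private_to = np.where(sig["logFC"] < 0, gb, ga)
    return pd.DataFrame(
        {
            "chrom": sig["chrom"],
            "start": sig["start"],
            "end": sig["end"],
            "private_to": private_to,
            "p": sig["p"],
        }
    ).reset_index(drop=True)
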
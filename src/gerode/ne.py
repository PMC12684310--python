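"""Effective population sizes from two sampling epochs.

Three complementary estimators:

* inbreeding effective size ``Nef = 1 / (2·ΔF)`` with ``ΔF = (Ft − F0)/t``,
  the per-generation increase in mean F_ROH — the rate at which
  individuals become related;
* variance effective size ``NeV = t / (2·(F̂ − 1/S))`` from the
  standardised temporal variance of allele frequencies
  ``F̂ = (p1 − p2)² / (p̄(1 − p̄))``, with S the harmonic mean of the
  chromosome sample sizes — the rate of drift;
* the heterozygosity-loss equivalent ``Ne`` solving
  ``Ht/H0 = (1 − 1/(2Ne))^t`` — the constant-size population that would
  have eroded diversity at the observed rate.
"""

from __future__ import annotations

import numpy as np


def pooled_mean_froh(group_means, group_sizes) -> float:
    """Individual-weighted mean F_ROH over pooled groups."""
    means = np.asarray(group_means, dtype=float)
    sizes = np.asarray(group_sizes, dtype=float)
    return float((means * sizes).sum() / sizes.sum())


def nef(f0: float, ft: float, t: float) -> float:
    """Inbreeding effective size from the increase in mean F_ROH.

    ``f0`` is the founder-epoch mean, ``ft`` the contemporary mean and
    ``t`` the generations separating them.
    """
    if not (0 <= f0 <= 1 and 0 <= ft <= 1):
        raise ValueError("F_ROH means must lie in [0, 1]")
    if t < 1:
        raise ValueError("t must be at least one generation")
    if ft <= f0:
        raise ValueError("no inbreeding accumulation: Ft must exceed F0")
    delta_f = (ft - f0) / t
    return 1.0 / (2.0 * delta_f)


def harmonic_mean_sample_size(n1: int, n2: int, diploid: bool = True) -> float:
    """Harmonic mean of the two epoch sample sizes (x2 in diploids)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    mult = 2.0 if diploid else 1.0
    return 2.0 / (1.0 / (mult * n1) + 1.0 / (mult * n2))


def sampling_correction(n1: int, n2: int) -> float:
    """Expected contribution of binomial sampling noise to F-hat.

    Equals 1/(2·S0) + 1/(2·St) for diploid sample sizes S0, St — the sum
    of the two epochs' chromosome-sampling variances relative to p(1−p).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    return 1.0 / (2.0 * n1) + 1.0 / (2.0 * n2)


def temporal_f_hat(p1: np.ndarray, p2: np.ndarray) -> tuple[float, int]:
    """Mean standardised allele-frequency change over usable SNPs.

    F̂_site = (p1 − p2)² / (p̄(1 − p̄)) with p̄ the per-SNP mean frequency;
    sites fixed in the pooled sample (p̄ of 0 or 1) are excluded.
    Returns (mean F̂, number of usable sites).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p_bar = (p1 + p2) / 2.0
    usable = (p_bar > 0) & (p_bar < 1) & np.isfinite(p1) & np.isfinite(p2)
    if not usable.any():
        raise ValueError("no usable SNPs: all sites fixed in the pooled sample")
    f_hat = (p1[usable] - p2[usable]) ** 2 / (p_bar[usable] * (1 - p_bar[usable]))
    return float(f_hat.mean()), int(usable.sum())


def nev(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int, t: float, plan: str = "I") -> float:
    """Variance effective size from temporal allele-frequency change.

    The expected sampling-noise contribution 1/(2S0) + 1/(2St) is
    subtracted from the mean F̂ before inverting.  ``plan`` follows the
    temporal-method sampling designs: plan II (samples independent of
    the breeding population) inverts NeV = t / (2·(F̂ − corr)); plan I
    (individuals drawn without replacement from the census itself, the
    usual situation for small managed populations) additionally accounts
    for the finite-population reduction of sampling variance, which under
    N ≈ Ne resolves to NeV = (t − 2) / (2·(F̂ − corr)).  If the drift
    signal does not exceed sampling noise the estimate is undefined and
    an error is raised.
    """
    f_hat_mean, _ = temporal_f_hat(p1, p2)
    corr = sampling_correction(n1, n2)
    excess = f_hat_mean - corr
    if excess <= 0:
        raise ValueError("drift signal below sampling noise: F-hat <= sampling correction")
    if plan == "II":
        return t / (2.0 * excess)
    if plan == "I":
        if t <= 2:
            raise ValueError("plan I inversion requires t > 2 generations")
        return (t - 2.0) / (2.0 * excess)
    raise ValueError(f"unknown sampling plan {plan!r}")


def ne_from_het_loss(h0: float, ht: float, t: float) -> float:
    """Constant-size Ne whose drift would produce the observed diversity loss.

    Inverts Ht/H0 = (1 − 1/(2Ne))^t exactly.
    """
    if h0 <= 0:
        raise ValueError("H0 must be positive")
    if not 0 < ht < h0:
        raise ValueError("Ht must lie strictly between 0 and H0")
    if t <= 0:
        raise ValueError("t must be positive")
    per_gen_retention = (ht / h0) ** (1.0 / t)
    return 1.0 / (2.0 * (1.0 - per_gen_retention))


def het_decay(ne: float, t: float) -> float:
    """Expected heterozygosity retention (1 − 1/(2Ne))^t; inverse of the above."""
    if ne <= 0.5:
        raise ValueError("Ne must exceed 0.5")
    return (1.0 - 1.0 / (2.0 * ne)) ** t
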
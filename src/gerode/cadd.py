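"""CADD-rank load decomposition: genetic, realised and masked load.

PHRED-scaled deleteriousness scores are inverted to rank proportions
(score = −10·log10(n_i/N)), the reciprocal rank 1/n_i serves as a crude
selection-coefficient proxy s, and a dominance coefficient h is assigned
by score bin under the assumption that more deleterious mutations are
more recessive.  Per-sample loads over L scored sites:

    GL = Σ_hom s_i + Σ_het 0.5·s_j          (total load)
    RL = Σ_hom s_i + Σ_het h_j·s_j          (expressed portion)
    ML = Σ_het (0.5 − h_j)·s_j              (hidden portion)

so GL = RL + ML identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import MISSING, GenotypeMatrix

#: potential mutations across all chicken chromosomes (rank denominator)
DEFAULT_RANK_TOTAL: int = 3_073_805_640

#: dominance by score bin, left-closed: more deleterious => more recessive
H_BINS = ((0.0, 10.0, 0.3), (10.0, 20.0, 0.15), (20.0, 30.0, 0.02), (30.0, np.inf, 0.0))


def chcadd_to_proportion(score):
    """Invert the PHRED scaling: n_i/N = 10^(−score/10).

    A score of 20 maps to a proportion of 0.01; a score of 0 to 1.
    """
    score = np.asarray(score, dtype=float)
    if np.any(score < 0):
        raise ValueError("scores must be non-negative")
    out = np.power(10.0, -score / 10.0)
    return float(out) if out.ndim == 0 else out


def proportion_to_chcadd(proportion):
    """Forward PHRED scaling, the exact inverse of :func:`chcadd_to_proportion`."""
    proportion = np.asarray(proportion, dtype=float)
    if np.any((proportion <= 0) | (proportion > 1)):
        raise ValueError("proportions must lie in (0, 1]")
    out = -10.0 * np.log10(proportion)
    return float(out) if out.ndim == 0 else out


def assign_s_h(score, rank_total: int = DEFAULT_RANK_TOTAL):
    """Selection proxy s = 1/n_i and binned dominance h for a score.

    n_i is the score's rank among ``rank_total`` potential mutations.
    Bins are half-open on the left ([0,10) -> 0.3, [10,20) -> 0.15,
    [20,30) -> 0.02, [30,inf) -> 0) so that h is monotone in s.
    """
    scalar = np.isscalar(score)
    score = np.atleast_1d(np.asarray(score, dtype=float))
    if np.any(score < 0):
        raise ValueError("scores must be non-negative")
    n_i = chcadd_to_proportion(score) * rank_total
    s = 1.0 / np.atleast_1d(n_i)
    h = np.empty_like(s)
    for lo, hi, value in H_BINS:
        h[(score >= lo) & (score < hi)] = value
    if scalar:
        return float(s[0]), float(h[0])
    return s, h


def score_sites(cadd: pd.DataFrame, rank_total: int = DEFAULT_RANK_TOTAL) -> pd.DataFrame:
    """Annotate a score table with rank, proportion, s and h columns."""
    out = cadd.copy()
    out["proportion"] = chcadd_to_proportion(out["score"].to_numpy())
    out["n_i"] = out["proportion"] * rank_total
    s, h = assign_s_h(out["score"].to_numpy(), rank_total)
    out["s"], out["h"] = s, h
    return out


def eligible_sites(gm: GenotypeMatrix, scored: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Site-eligibility filter for the load decomposition.

    Keeps sites that carry a score, are genotyped in all samples, and are
    not fixed (all dosage 0 or all dosage 2) across the cohort.  Returns a
    boolean mask over ``gm`` sites and a small report dict.
    """
    key = gm.sites.set_index(["chrom", "pos"]).index
    score_key = scored.set_index(["chrom", "pos"]).index
    has_score = key.isin(score_key)
    all_called = (gm.genotypes != MISSING).all(axis=0)
    fixed = np.all(gm.genotypes == 0, axis=0) | np.all(gm.genotypes == 2, axis=0)
    mask = has_score & all_called & ~fixed
    report = {
        "n_sites": gm.n_sites,
        "n_with_score": int(has_score.sum()),
        "n_fully_genotyped": int((has_score & all_called).sum()),
        "n_eligible": int(mask.sum()),
    }
    return mask, report


def load_components(gm: GenotypeMatrix, scored: pd.DataFrame) -> pd.DataFrame:
    """Per-sample genetic, realised and masked load over scored sites.

    ``scored`` must align 1:1 with ``gm`` sites (use :func:`eligible_sites`
    and ``take_sites`` first) and provide ``s`` and ``h`` columns.
    Missing genotypes are skipped and counted.
    """
    if len(scored) != gm.n_sites:
        raise ValueError("scored table must align with the genotype matrix sites")
    s = scored["s"].to_numpy(dtype=float)
    h = scored["h"].to_numpy(dtype=float)
    if np.any(h > 0.5):
        raise ValueError("dominance h > 0.5 would make the masked load negative")
    geno = gm.genotypes
    hom = geno == 2
    het = geno == 1
    gl = hom @ s + het @ (0.5 * s)
    rl = hom @ s + het @ (h * s)
    ml = het @ ((0.5 - h) * s)
    return pd.DataFrame(
        {
            "sample": gm.sample_ids,
            "cohort": gm.cohorts,
            "GL": gl,
            "RL": rl,
            "ML": ml,
            "n_sites_missing": (geno == MISSING).sum(axis=1),
        }
    )


def load_vs_froh(components: pd.DataFrame, froh: pd.Series) -> pd.DataFrame:
    """OLS of each load component on F_ROH; slope, R² and p per component.

    ``froh`` is indexed by sample id.  Requires at least three samples and
    non-degenerate F_ROH.
    """
    merged = components.set_index("sample").join(froh.rename("froh"), how="inner")
    if len(merged) < 3:
        raise ValueError("need at least three samples for the regression")
    x = merged["froh"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("F_ROH has zero variance across samples")
    rows = []
    for comp in ("GL", "RL", "ML"):
        y = merged[comp].to_numpy(dtype=float)
        rows.append({"component": comp, **ols_summary(x, y)})
    return pd.DataFrame(rows)


def ols_summary(x: np.ndarray, y: np.ndarray) -> dict:
    """Slope, R² and slope p-value of y ~ x; a constant y gives R² = 0, p = 1."""
    if np.ptp(y) == 0:
        return {"slope": 0.0, "r2": 0.0, "p": 1.0}
    fit = sm.OLS(y, sm.add_constant(np.asarray(x, dtype=float))).fit()
    return {"slope": float(fit.params[1]), "r2": float(fit.rsquared), "p": float(fit.pvalues[1])}
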
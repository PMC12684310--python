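"""Expected offspring load under Mendelian segregation, and cross ranking.

For a site where the parents carry derived-allele dosages g1 and g2, the
offspring dosage is the sum of two independent Bernoulli transmissions
with success probabilities g1/2 and g2/2.  Load components of a
hypothetical cross are expectations of the per-genotype contributions
(s for a homozygote; 0.5·s, h·s and (0.5−h)·s for a heterozygote's
genetic/realised/masked shares) under that distribution, summed over
sites — the reproducible summary of a pairing, with a seeded sampling
mode available for distribution plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cadd import ols_summary
from .containers import MISSING, GenotypeMatrix


def offspring_genotype_dist(g1: int, g2: int) -> dict[int, float]:
    """Exact Mendelian offspring-dosage distribution for parental dosages."""
    for g in (g1, g2):
        if g not in (0, 1, 2):
            raise ValueError(f"parental dosage must be 0, 1 or 2, got {g}")
    p1, p2 = g1 / 2.0, g2 / 2.0
    dist = {
        0: (1 - p1) * (1 - p2),
        1: p1 * (1 - p2) + (1 - p1) * p2,
        2: p1 * p2,
    }
    return {k: v for k, v in dist.items() if v > 0}


@dataclass
class CrossPrediction:
    parent1: str
    parent2: str
    cross_class: str
    expected_GL: float
    expected_RL: float
    expected_ML: float
    n_sites: int
    n_dropped_missing: int


def _cross_class(c1: str, c2: str) -> str:
    captive = {"founder_wildborn", "early_captive", "late_captive", "captive"}
    k1 = "wild" if c1 == "wild" else ("captive" if c1 in captive else c1)
    k2 = "wild" if c2 == "wild" else ("captive" if c2 in captive else c2)
    return "x".join(sorted((k1, k2)))


def expected_offspring_load(
    gm: GenotypeMatrix,
    scored: pd.DataFrame,
    parent1: str,
    parent2: str,
) -> CrossPrediction:
    """Expected offspring load components for one hypothetical pairing.

    ``scored`` aligns 1:1 with ``gm`` sites and provides s and h.  Sites
    with a missing genotype in either parent are dropped pairwise and
    counted.  Linearity of expectation gives, per site with transmission
    probabilities p1 = g1/2 and p2 = g2/2:

        P(hom) = p1·p2,  P(het) = p1(1−p2) + (1−p1)p2.
    """
    if len(scored) != gm.n_sites:
        raise ValueError("scored table must align with the genotype matrix sites")
    i1 = gm.sample_ids.index(parent1)
    i2 = gm.sample_ids.index(parent2)
    g1 = gm.genotypes[i1].astype(float)
    g2 = gm.genotypes[i2].astype(float)
    ok = (gm.genotypes[i1] != MISSING) & (gm.genotypes[i2] != MISSING)
    if not ok.any():
        raise ValueError(f"no shared genotyped sites between {parent1} and {parent2}")
    s = scored["s"].to_numpy(dtype=float)[ok]
    h = scored["h"].to_numpy(dtype=float)[ok]
    p1, p2 = g1[ok] / 2.0, g2[ok] / 2.0
    p_hom = p1 * p2
    p_het = p1 * (1 - p2) + (1 - p1) * p2
    gl = float((p_hom * s + p_het * 0.5 * s).sum())
    rl = float((p_hom * s + p_het * h * s).sum())
    ml = float((p_het * (0.5 - h) * s).sum())
    return CrossPrediction(
        parent1=parent1,
        parent2=parent2,
        cross_class=_cross_class(gm.cohorts[i1], gm.cohorts[i2]),
        expected_GL=gl,
        expected_RL=rl,
        expected_ML=ml,
        n_sites=int(ok.sum()),
        n_dropped_missing=int((~ok).sum()),
    )


def sample_offspring_load(
    gm: GenotypeMatrix,
    scored: pd.DataFrame,
    parent1: str,
    parent2: str,
    n_offspring: int,
    seed: int,
) -> pd.DataFrame:
    """Sampled (not expected) offspring load components, for distributions."""
    rng = np.random.default_rng(seed)
    i1 = gm.sample_ids.index(parent1)
    i2 = gm.sample_ids.index(parent2)
    ok = (gm.genotypes[i1] != MISSING) & (gm.genotypes[i2] != MISSING)
    s = scored["s"].to_numpy(dtype=float)[ok]
    h = scored["h"].to_numpy(dtype=float)[ok]
    p1 = gm.genotypes[i1][ok] / 2.0
    p2 = gm.genotypes[i2][ok] / 2.0
    rows = []
    for _ in range(n_offspring):
        dose = rng.binomial(1, p1) + rng.binomial(1, p2)
        hom, het = dose == 2, dose == 1
        gl = float((s[hom]).sum() + (0.5 * s[het]).sum())
        rl = float((s[hom]).sum() + (h[het] * s[het]).sum())
        rows.append({"GL": gl, "RL": rl, "ML": gl - rl})
    return pd.DataFrame(rows)


def rank_crosses(
    gm: GenotypeMatrix,
    scored: pd.DataFrame,
    candidates: list[tuple[str, str]] | None = None,
    class_filter: str | None = None,
    allow_self: bool = False,
) -> pd.DataFrame:
    """Rank candidate pairings by expected realised load (ascending).

    ``candidates`` defaults to all unordered pairs of samples; self-crosses
    are excluded unless explicitly enabled.  ``class_filter`` keeps only
    one cross class (e.g. ``"captivexwild"``).
    """
    if candidates is None:
        ids = gm.sample_ids
        candidates = [(a, b) for i, a in enumerate(ids) for b in ids[i:]]
    rows = []
    for p1, p2 in candidates:
        if p1 == p2 and not allow_self:
            continue
        pred = expected_offspring_load(gm, scored, p1, p2)
        rows.append(vars(pred))
    if len(rows) < 2:
        raise ValueError("need at least two candidate pairs to rank")
    tbl = pd.DataFrame(rows)
    if class_filter is not None:
        tbl = tbl[tbl["cross_class"] == class_filter].reset_index(drop=True)
    return tbl.sort_values("expected_RL", kind="mergesort").reset_index(drop=True)


def reduction_percent(best_rl: float, worst_rl: float) -> float:
    """Percent reduction of the best cross relative to the worst."""
    if worst_rl == 0:
        return 0.0
    return 100.0 * (worst_rl - best_rl) / worst_rl


def cross_reduction_summary(ranked: pd.DataFrame, kinship: pd.DataFrame | None = None, top_k: int = 5) -> pd.DataFrame:
    """Headline reductions: best cross of each class vs worst of every class.

    With a pedigree kinship matrix, also reports the best genomic cross
    against the mean expected RL of the ``top_k`` lowest-kinship pairs —
    the gain over managing by pedigree kinship alone.
    """
    rows = []
    best_overall = ranked.iloc[0]
    for cls_a in ranked["cross_class"].unique():
        sub_a = ranked[ranked["cross_class"] == cls_a]
        for cls_b in ranked["cross_class"].unique():
            sub_b = ranked[ranked["cross_class"] == cls_b]
            rows.append(
                {
                    "comparison": f"best {cls_a} vs worst {cls_b}",
                    "best_RL": float(sub_a["expected_RL"].iloc[0]),
                    "reference_RL": float(sub_b["expected_RL"].iloc[-1]),
                    "reduction_pct": reduction_percent(
                        float(sub_a["expected_RL"].iloc[0]),
                        float(sub_b["expected_RL"].iloc[-1]),
                    ),
                }
            )
    if kinship is not None:
        theta = ranked.apply(
            lambda r: float(kinship.loc[r["parent1"], r["parent2"]]), axis=1
        )
        by_kin = ranked.assign(theta=theta).sort_values("theta", kind="mergesort")
        ref = float(by_kin["expected_RL"].head(top_k).mean())
        rows.append(
            {
                "comparison": f"best overall vs mean of top-{top_k} by pedigree kinship",
                "best_RL": float(best_overall["expected_RL"]),
                "reference_RL": ref,
                "reduction_pct": reduction_percent(float(best_overall["expected_RL"]), ref),
            }
        )
    return pd.DataFrame(rows)


def load_vs_relatedness(predictions: pd.DataFrame, relatedness: pd.Series) -> pd.DataFrame:
    """OLS of each expected load component on parental relatedness.

    ``relatedness`` is indexed by (parent1, parent2) pairs in the order of
    ``predictions``; a constant relatedness vector is rejected.
    """
    if len(predictions) < 3:
        raise ValueError("need at least three predictions")
    x = np.asarray(relatedness, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("relatedness has zero variance")
    rows = []
    for comp in ("expected_GL", "expected_RL", "expected_ML"):
        rows.append({"component": comp, **ols_summary(x, predictions[comp].to_numpy())})
    return pd.DataFrame(rows)
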
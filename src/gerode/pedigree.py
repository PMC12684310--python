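"""Studbook pedigrees: recursive kinship, inbreeding, relatedness classes.

Kinship phi(i, j) is the probability that an allele drawn at random from i
and one drawn from j at the same locus are identical by descent.  Under
the standard founder assumptions (founders unrelated and non-inbred) a
parent and child have phi = 0.25 and an individual with itself phi =
0.5 * (1 + F).  The recursion is evaluated in topological order so that
both parents of any individual are resolved before the individual itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RELATEDNESS_CLASSES = (
    "unrelated",
    "third-degree-or-higher",
    "second-degree",
    "first-degree",
    "self-or-duplicate",
)


class PedigreeCycleError(ValueError):
    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"pedigree contains a cycle: {' -> '.join(map(str, self.cycle))}")


@dataclass
class Pedigree:
    """A studbook DAG.

    ``table`` has columns ``id, sire, dam`` (plus optional ``sex``,
    ``cohort``); unknown parents are None.  Construction validates
    acyclicity and stores a topological order.
    """

    table: pd.DataFrame
    order: list = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        tbl = self.table.reset_index(drop=True)
        for col in ("sire", "dam"):
            if col not in tbl.columns:
                raise ValueError(f"pedigree table lacks a {col!r} column")
            tbl[col] = [
                None if (p is None or (isinstance(p, float) and np.isnan(p))) else p
                for p in tbl[col]
            ]
        ids = list(tbl["id"])
        if len(set(ids)) != len(ids):
            dupes = tbl["id"][tbl["id"].duplicated()].tolist()
            raise ValueError(f"duplicate individual ids: {dupes}")
        known = set(ids)
        for col in ("sire", "dam"):
            bad = [
                (i, p)
                for i, p in zip(tbl["id"], tbl[col])
                if p is not None and not (isinstance(p, float) and np.isnan(p)) and p not in known
            ]
            if bad:
                raise ValueError(f"{col} not present as individuals: {bad[:5]}")
        self.table = tbl
        self.order = self._toposort()

    def parents(self, ind) -> tuple:
        row = self.table.set_index("id").loc[ind]
        return row["sire"], row["dam"]

    def founders(self) -> list:
        return [
            i
            for i, s, d in zip(self.table["id"], self.table["sire"], self.table["dam"])
            if s is None and d is None
        ]

    def _toposort(self) -> list:
        # Kahn's algorithm; on failure, walk parent links to exhibit a cycle.
        ids = list(self.table["id"])
        parent_of = {
            i: [p for p in (s, d) if p is not None]
            for i, s, d in zip(ids, self.table["sire"], self.table["dam"])
        }
        children: dict = {i: [] for i in ids}
        indeg = {}
        for i, ps in parent_of.items():
            indeg[i] = len(ps)
            for p in ps:
                children[p].append(i)
        queue = [i for i in ids if indeg[i] == 0]
        order = []
        while queue:
            node = queue.pop()
            order.append(node)
            for c in children[node]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) < len(ids):
            stuck = next(i for i in ids if indeg[i] > 0)
            cycle, seen = [stuck], {stuck}
            node = parent_of[stuck][0]
            while node not in seen:
                cycle.append(node)
                seen.add(node)
                node = parent_of[node][0]
            cycle.append(node)
            raise PedigreeCycleError(cycle)
        return order


def kinship(ped: Pedigree) -> pd.DataFrame:
    """Full kinship matrix phi(i, j) by the recursive (tabular) method.

    phi(i, i) = 0.5 * (1 + phi(sire_i, dam_i)); for i later than j in
    topological order, phi(i, j) = 0.5 * (phi(sire_i, j) + phi(dam_i, j)).
    An unknown parent contributes 0 (treated as a unique founder).
    """
    ids = ped.order
    index = {ind: k for k, ind in enumerate(ids)}
    tbl = ped.table.set_index("id")
    n = len(ids)
    phi = np.zeros((n, n))
    for k, ind in enumerate(ids):
        sire, dam = tbl.loc[ind, "sire"], tbl.loc[ind, "dam"]
        si = index.get(sire)
        di = index.get(dam)
        f_parents = phi[si, di] if (si is not None and di is not None) else 0.0
        phi[k, k] = 0.5 * (1.0 + f_parents)
        for j in range(k):
            contrib = 0.0
            if si is not None:
                contrib += phi[si, j]
            if di is not None:
                contrib += phi[di, j]
            phi[k, j] = phi[j, k] = 0.5 * contrib
    original = list(ped.table["id"])
    out = pd.DataFrame(phi, index=ids, columns=ids)
    return out.loc[original, original]


def inbreeding(ped: Pedigree) -> pd.Series:
    """Inbreeding coefficient F_i = phi(sire_i, dam_i); founder sides count 0."""
    phi = kinship(ped)
    values = {}
    for ind, sire, dam in zip(ped.table["id"], ped.table["sire"], ped.table["dam"]):
        if sire is None or dam is None:
            values[ind] = 0.0
        else:
            values[ind] = float(phi.loc[sire, dam])
    return pd.Series(values, name="F")


def classify_relatedness(theta: float) -> str:
    """Map a kinship coefficient to the conventional relatedness class.

    Bands: 0 unrelated; (0, 0.0625) third degree or higher; [0.0625,
    0.1875) second degree; [0.1875, 0.375] first degree; above 0.375 the
    coefficient exceeds any outbred relationship (self-kinship territory).
    Interval boundaries are assigned to the more-related class.
    """
    if theta < 0:
        raise ValueError("kinship coefficient cannot be negative")
    if theta > 0.5:
        raise ValueError(f"kinship coefficient {theta} out of range (max 0.5)")
    if theta == 0:
        return "unrelated"
    if theta < 0.0625:
        return "third-degree-or-higher"
    if theta < 0.1875:
        return "second-degree"
    if theta <= 0.375:
        return "first-degree"
    return "self-or-duplicate"
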
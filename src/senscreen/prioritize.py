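"""Hit prioritization: property filters, pharmacophore clustering, sampling.

Virtual hits are first reduced by physicochemical/ADMET-style range rules,
then clustered on binary pharmacophore fingerprints by k-medoids under
Tanimoto (Jaccard) distance, and finally a diverse, cluster-covering subset
is drawn for experimental follow-up.

The shipped default rules (``LEAD_LIKE_RULES``) are a generic lead-like
placeholder set, intended to be replaced by a project-specific rules file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from scipy.spatial.distance import pdist, squareform

from .chemlib import CompoundRecord

logger = logging.getLogger("senscreen")


@dataclass(frozen=True)
class FilterRule:
    prop: str
    lo: float = float("-inf")
    hi: float = float("inf")

    def passes(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass
class FilterRuleSet:
    rules: list[FilterRule] = field(default_factory=list)

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterRuleSet":
        """Key-value text: one rule per line, ``property min max``.

        ``-`` (or ``*``) stands for an unset bound; ``#`` starts a comment.
        """
        rules = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            prop, lo, hi = line.split()
            rules.append(
                FilterRule(
                    prop,
                    float("-inf") if lo in "-*" else float(lo),
                    float("inf") if hi in "-*" else float(hi),
                )
            )
        return cls(rules)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for r in self.rules:
            lo = "-" if r.lo == float("-inf") else f"{r.lo:g}"
            hi = "-" if r.hi == float("inf") else f"{r.hi:g}"
            lines.append(f"{r.prop} {lo} {hi}")
        Path(path).write_text("\n".join(lines) + "\n")


# Placeholder lead-like defaults; projects should supply their own file.
LEAD_LIKE_RULES = FilterRuleSet(
    [
        FilterRule("MW", 250, 450),
        FilterRule("cLogP", float("-inf"), 4.5),
        FilterRule("HBD", 0, 5),
        FilterRule("HBA", 0, 8),
        FilterRule("RotB", 0, 8),
        FilterRule("TPSA", 0, 120),
    ]
)

_PROPERTY_FUNCS = {
    "MW": Descriptors.MolWt,
    "cLogP": Crippen.MolLogP,
    "HBD": rdMolDescriptors.CalcNumHBD,
    "HBA": rdMolDescriptors.CalcNumHBA,
    "RotB": rdMolDescriptors.CalcNumRotatableBonds,
    "TPSA": rdMolDescriptors.CalcTPSA,
}


def compute_properties(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Filterable physicochemical properties, indexed by compound id."""
    rows = {}
    for rec in records:
        mol = Chem.MolFromSmiles(rec.canonical_key)
        if mol is None:
            raise ValueError(f"unparsable structure for {rec.id}")
        rows[rec.id] = {name: f(mol) for name, f in _PROPERTY_FUNCS.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def apply_filters(
    properties: pd.DataFrame, rules: FilterRuleSet
) -> tuple[list[str], dict[str, int]]:
    """Pass ids and per-rule rejection counts.

    A compound passes only if every rule holds; a rejection is attributed
    to the first failing rule in declared order (the pass set itself is
    order-independent).
    """
    for rule in rules.rules:
        if rule.prop not in properties.columns:
            raise KeyError(f"rule property {rule.prop!r} not available")
    passed: list[str] = []
    rejections = {r.prop: 0 for r in rules.rules}
    for cid, row in properties.iterrows():
        for rule in rules.rules:
            if not rule.passes(row[rule.prop]):
                rejections[rule.prop] += 1
                break
        else:
            passed.append(str(cid))
    return passed, rejections


# ---------------------------------------------------------------------------
# k-medoids on Tanimoto distance


@dataclass
class ClusterAssignment:
    ids: list[str]
    cluster_of: np.ndarray  # cluster index per compound
    medoids: np.ndarray  # compound index of each cluster's medoid
    distances: np.ndarray  # full pairwise distance matrix
    metric: str = "jaccard"

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)

    def members(self, cluster: int) -> np.ndarray:
        return np.where(self.cluster_of == cluster)[0]

    def to_dataframe(self) -> pd.DataFrame:
        is_medoid = np.zeros(len(self.ids), dtype=bool)
        is_medoid[self.medoids] = True
        return pd.DataFrame(
            {"id": self.ids, "cluster": self.cluster_of, "is_medoid": is_medoid}
        )


def tanimoto_distance_matrix(fp_matrix: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distances between binary fingerprint rows.

    Identical all-zero rows get distance 0 (scipy's convention).
    """
    fp = np.asarray(fp_matrix, dtype=bool)
    if fp.ndim != 2:
        raise ValueError("fingerprint matrix must be 2-D")
    return squareform(pdist(fp, metric="jaccard"), checks=False)


def _update_medoid(dist: np.ndarray, members: np.ndarray) -> int:
    sub = dist[np.ix_(members, members)]
    within = sub.sum(axis=1)
    return int(members[int(np.argmin(within))])  # argmin: first index on ties


def cluster_pharmacophores(
    fp_matrix: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> ClusterAssignment:
    """k-medoids (Lloyd-style alternation) under Tanimoto distance.

    Initialization is deterministic: the most central compound first, then
    farthest-point (max-min distance) seeding; compounds join their nearest
    medoid (ties to the lowest cluster index); medoids move to the member
    minimizing summed within-cluster distance (ties by compound order).
    Iterates to a fixed point. The seed argument is accepted for interface
    stability; the procedure itself has no random element.
    """
    fp = np.asarray(fp_matrix)
    n = fp.shape[0]
    if n_clusters > n:
        raise ValueError("more clusters than compounds")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    ids = [str(i) for i in (ids if ids is not None else range(n))]
    dist = tanimoto_distance_matrix(fp)
    seeds = [int(np.argmin(dist.sum(axis=1)))]
    while len(seeds) < n_clusters:
        min_d = dist[:, seeds].min(axis=1)
        min_d[seeds] = -1.0
        seeds.append(int(np.argmax(min_d)))
    medoids = np.sort(np.array(seeds))
    for _ in range(200):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(n_clusters):
            members = np.where(assign == c)[0]
            if len(members):
                new_medoids[c] = _update_medoid(dist, members)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    assign = np.argmin(dist[:, medoids], axis=1)
    # drop empty clusters (can arise when points collapse onto one medoid)
    occupied = np.unique(assign)
    remap = {c: i for i, c in enumerate(occupied)}
    return ClusterAssignment(
        ids=ids,
        cluster_of=np.array([remap[c] for c in assign]),
        medoids=np.array([medoids[c] for c in occupied]),
        distances=dist,
    )


def diversity_sample(assignment: ClusterAssignment, n_select: int) -> list[str]:
    """Cluster-covering, maximally spread selection of ``n_select`` ids.

    Slots are allocated to clusters proportionally to size by largest
    remainder, with every cluster getting at least one slot while
    n_select >= number of clusters. Within a cluster the medoid is taken
    first, then members by max-min distance to those already selected
    (ties by compound order).
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    n = len(assignment.ids)
    if n_select > n:
        raise ValueError("n_select exceeds the number of compounds")
    k = assignment.n_clusters
    sizes = np.array([len(assignment.members(c)) for c in range(k)])
    if n_select >= k:
        frac = sizes / sizes.sum() * n_select
        quota = np.floor(frac).astype(int)
        remainder = frac - np.floor(frac)
        leftover = n_select - quota.sum()
        for c in np.lexsort((np.arange(k), -remainder))[:leftover]:
            quota[c] += 1
        # coverage: every cluster gets at least one pick
        for c in range(k):
            if quota[c] == 0:
                donor = int(np.lexsort((np.arange(k), -quota))[0])
                quota[donor] -= 1
                quota[c] += 1
    else:  # fewer picks than clusters: take from the largest clusters
        quota = np.zeros(k, dtype=int)
        for c in np.lexsort((np.arange(k), -sizes))[:n_select]:
            quota[c] = 1
    quota = np.minimum(quota, sizes)
    # redistribute slots clipped off by small clusters
    while quota.sum() < n_select:
        room = sizes - quota
        c = int(np.lexsort((np.arange(k), -room))[0])
        if room[c] <= 0:
            break
        quota[c] += 1

    selected: list[int] = []
    dist = assignment.distances
    for c in range(k):
        if quota[c] == 0:
            continue
        members = assignment.members(c)
        picks = [int(assignment.medoids[c])]
        pool = [m for m in members if m != picks[0]]
        while len(picks) < quota[c] and pool:
            dmin = np.array([dist[m, picks].min() for m in pool])
            best = int(np.argmax(dmin))  # first index wins ties
            picks.append(pool.pop(best))
        selected.extend(picks)
    return [assignment.ids[i] for i in selected]
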
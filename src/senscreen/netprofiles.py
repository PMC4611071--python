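"""Hypergeometric process-network profiles and profile clustering.

A gene list is scored against a catalogue of curated process networks by
the hypergeometric upper-tail probability of its observed overlap with
each network; the vector of p-values is a "process network profile". Two
profiles are compared by the chance of sharing at least the observed
number of significant networks (again a hypergeometric upper tail over the
network catalogue), which serves directly as a distance: small values mean
greater-than-chance agreement. Profiles are clustered by UPGMA
(unweighted average linkage) and exported as dendrograms.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger("senscreen")


@dataclass(frozen=True)
class ProcessNetwork:
    id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"network {self.id} has no genes")


def read_gmt(path: str | Path) -> list[ProcessNetwork]:
    """GMT text: name <tab> description <tab> gene symbols."""
    networks = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        networks.append(ProcessNetwork(parts[0], parts[1] or parts[0], frozenset(parts[2:])))
    if len({n.id for n in networks}) != len(networks):
        raise ValueError("duplicate network ids in GMT")
    return networks


def write_gmt(networks: Iterable[ProcessNetwork], path: str | Path) -> None:
    lines = ["\t".join([n.id, n.name, *sorted(n.genes)]) for n in networks]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Evaluated via the log-space-stable survival function; k = 0 is the
    certain event.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent hypergeometric arguments k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class ProfileVector:
    """Per-network enrichment p-values for one gene list."""

    label: str
    pvalues: dict[str, float]  # network id -> upper-tail p
    n_genes: int
    universe_size: int
    alpha: float = 0.05
    significant: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.significant:
            self.significant = {nid for nid, p in self.pvalues.items() if p < self.alpha}


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def enrich_profile(
    gene_list: Iterable[str],
    networks: Sequence[ProcessNetwork],
    universe_size: int | None = None,
    alpha: float = 0.05,
    label: str = "profile",
    bh_correct: bool = False,
) -> ProfileVector:
    """Score one gene list against every network.

    For each network: k = |list intersect network|, K = |network|,
    n = |list|, N = universe size (default: union of all network genes plus
    any list genes outside it). Significance is raw p < alpha by default;
    ``bh_correct`` switches to Benjamini-Hochberg adjusted values.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    if universe_size is None:
        universe = set().union(*(n.genes for n in networks)) | genes
        universe_size = len(universe)
    pvalues = {}
    for net in networks:
        k = len(genes & net.genes)
        pvalues[net.id] = hypergeom_upper_tail(k, len(net.genes), len(genes), universe_size)
    if bh_correct:
        ids = list(pvalues)
        adj = benjamini_hochberg([pvalues[i] for i in ids])
        significant = {i for i, q in zip(ids, adj) if q < alpha}
    else:
        significant = {i for i, p in pvalues.items() if p < alpha}
    return ProfileVector(
        label=label,
        pvalues=pvalues,
        n_genes=len(genes),
        universe_size=universe_size,
        alpha=alpha,
        significant=significant,
    )


def profile_overlap_distance(
    sig_a: Iterable[str], sig_b: Iterable[str], n_networks: int = 169
) -> float:
    """Chance of sharing >= the observed number of significant networks.

    Upper-tail hypergeometric over the network catalogue: population
    n_networks, |sig_a| marked, |sig_b| drawn, observed overlap as k.
    Symmetric in its arguments; smaller means more similar.
    """
    a, b = set(sig_a), set(sig_b)
    if len(a) > n_networks or len(b) > n_networks:
        raise ValueError("significance set larger than the network universe")
    k = len(a & b)
    return hypergeom_upper_tail(k, len(a), len(b), n_networks)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")


def profile_distance_matrix(
    profiles: Sequence[ProfileVector], n_networks: int = 169
) -> DistanceMatrix:
    labels = [p.label for p in profiles]
    n = len(profiles)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = profile_overlap_distance(
            profiles[i].significant, profiles[j].significant, n_networks
        )
    return DistanceMatrix(labels=labels, values=d)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class Dendrogram:
    """Binary merge tree; ``merges`` rows are (left, right, height) where
    node ids 0..n-1 are leaves and n+i is the cluster made by merge i."""

    labels: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        n = len(self.labels)
        height_of: dict[int, float] = {i: 0.0 for i in range(n)}
        text: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for i, (a, b, h) in enumerate(self.merges):
            node = n + i
            la = h / 2 - height_of[a] / 2
            lb = h / 2 - height_of[b] / 2
            text[node] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
            height_of[node] = h
        return text[n + len(self.merges) - 1] + ";"


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Unweighted average-linkage clustering (UPGMA proper).

    Inter-cluster distance is the arithmetic mean over all original leaf
    pairs. Ties between candidate merges are broken by the lexicographic
    pair of each cluster's smallest leaf label.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    D = dist.values
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}  # node -> leaf indices
    rep: dict[int, str] = {i: dist.labels[i] for i in range(n)}  # smallest leaf label
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            la, lb = clusters[a], clusters[b]
            d = float(D[np.ix_(la, lb)].mean())
            key = (d, *sorted((rep[a], rep[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, *_), a, b = best
        a, b = sorted((a, b))
        merges.append((a, b, d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        rep[next_id] = min(rep.pop(a), rep.pop(b))
        next_id += 1
    return Dendrogram(labels=list(dist.labels), merges=merges)


def profile_heatmap_table(profiles: Sequence[ProfileVector]) -> pd.DataFrame:
    """-log10 p by (profile, network), with per-cell significance flags.

    Columns come in pairs: ``<network>`` (the -log10 p) and
    ``<network>__sig`` (True iff p < alpha, strict).
    """
    if not profiles:
        raise ValueError("no profiles")
    universes = {p.universe_size for p in profiles}
    networks = [list(p.pvalues) for p in profiles]
    if any(set(nw) != set(networks[0]) for nw in networks) or len(universes) > 1:
        raise ValueError("profiles must share one universe and network set")
    cols = networks[0]
    data = {}
    for net in cols:
        data[net] = [-np.log10(p.pvalues[net]) for p in profiles]
        data[f"{net}__sig"] = [net in p.significant for p in profiles]
    return pd.DataFrame(data, index=[p.label for p in profiles])
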
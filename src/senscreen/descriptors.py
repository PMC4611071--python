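"""Multi-block molecular descriptor matrices and feature selection.

Four descriptor blocks are computed per compound:

``phys2d``
    A curated set of 1D/2D physicochemical and topological descriptors
    (continuous).
``keyfp``
    MACCS structural keys, 166 binary bits.
``extfp``
    Morgan (extended-connectivity) fingerprint, radius 2, 1024 binary bits.
``pharmfp``
    A 147-bit 2D pharmacophore-pair fingerprint: six feature classes
    (H-bond donor, H-bond acceptor, positively/negatively ionizable,
    aromatic, hydrophobe) give 21 unordered class pairs; each pair is
    crossed with 7 through-bond distance bins, 21 x 7 = 147 bits.

Feature selection proceeds zero-variance removal -> pairwise correlation
pruning -> representative selection by hierarchical clustering of columns
(distance 1 - |r|, complete linkage), keeping each cluster's medoid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .chemlib import CompoundRecord

logger = logging.getLogger("senscreen")

CONTINUOUS = "continuous"
BINARY = "binary"
BLOCKS = ("phys2d", "keyfp", "extfp", "pharmfp")

# Curated fast 1D/2D physchem set. Charge-dependent (PEOE) descriptors are
# deliberately absent: they can fail to converge on unusual structures.
PHYS2D_NAMES = [
    "MolWt", "HeavyAtomMolWt", "MolLogP", "MolMR", "TPSA", "LabuteASA",
    "HeavyAtomCount", "NumHAcceptors", "NumHDonors", "NumRotatableBonds",
    "NumHeteroatoms", "NHOHCount", "NOCount", "RingCount",
    "NumAromaticRings", "NumAliphaticRings", "NumSaturatedRings",
    "FractionCSP3", "BalabanJ", "BertzCT", "HallKierAlpha",
    "Kappa1", "Kappa2", "Kappa3",
    "Chi0", "Chi1", "Chi0n", "Chi1n", "Chi2n", "Chi3n",
    "Chi0v", "Chi1v", "Chi2v", "Chi3v",
    "SlogP_VSA1", "SlogP_VSA2", "SlogP_VSA3", "SlogP_VSA4", "SlogP_VSA5",
    "SMR_VSA1", "SMR_VSA3", "SMR_VSA5", "SMR_VSA7",
    "EState_VSA1", "EState_VSA2", "EState_VSA3", "EState_VSA8",
    "VSA_EState1", "VSA_EState8",
    "NumValenceElectrons", "MaxEStateIndex", "MinEStateIndex",
]
_PHYS2D_FUNCS = [(n, getattr(RDDescriptors, n)) for n in PHYS2D_NAMES]

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)

# Pharmacophore feature classes as SMARTS
_PHARM_CLASSES = [
    ("don", "[$([N;!H0;v3]),$([N;!H0;+1;v4]),$([O,S;H1;+0]),$([n;H1])]"),
    ("acc", "[$([O,S;H1;v2]-[!$(*=[O,N,P,S])]),$([O,S;H0;v2]),$([O,S;-]),"
            "$([N;v3;!$(N-*=!@[O,N,P,S])]),$([nH0,o,s;+0])]"),
    ("pos", "[$([N;+1]),$([N;H2;v3;!$(N-*=[O,N,S])])]"),
    ("neg", "[$([C,S,P](=O)[O;H1,-1])]"),
    ("aro", "[a]"),
    ("hyd", "[$([C;D3,D4](-[CH3])),$([C;H2,H3]),$([S;D2](-C)-C),F,Cl,Br,I]"),
]
_PHARM_PATTERNS = [(name, Chem.MolFromSmarts(s)) for name, s in _PHARM_CLASSES]
_PHARM_BINS = [(1, 2), (3, 3), (4, 4), (5, 5), (6, 6), (7, 8), (9, 10**9)]
N_PHARM_BITS = len(_PHARM_CLASSES) * (len(_PHARM_CLASSES) + 1) // 2 * len(_PHARM_BINS)


@dataclass(frozen=True)
class Column:
    name: str
    block: str
    kind: str


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors with per-column block provenance."""

    row_ids: list[str]
    columns: list[Column]
    values: np.ndarray  # (n_rows, n_cols), float64

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValueError("column names must be unique")
        if self.values.shape != (len(self.row_ids), len(self.columns)):
            raise ValueError("values shape inconsistent with row/column labels")

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def block_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for c in self.columns:
            sizes[c.block] = sizes.get(c.block, 0) + 1
        return sizes

    def subset_columns(self, keep: Sequence[int]) -> "DescriptorMatrix":
        return DescriptorMatrix(
            row_ids=list(self.row_ids),
            columns=[self.columns[i] for i in keep],
            values=self.values[:, list(keep)].copy(),
        )

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_names)

    # -- serialization: header cells are "name|block|kind" --
    def to_csv(self, path: str | Path) -> None:
        header = [f"{c.name}|{c.block}|{c.kind}" for c in self.columns]
        df = pd.DataFrame(self.values, index=self.row_ids, columns=header)
        df.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col="id")
        columns = []
        for cell in df.columns:
            name, block, kind = cell.split("|")
            columns.append(Column(name, block, kind))
        return cls(
            row_ids=[str(i) for i in df.index],
            columns=columns,
            values=df.to_numpy(dtype=float),
        )


@dataclass
class FeatureSelectionReport:
    dropped_zero_variance: list[str] = field(default_factory=list)
    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    target_k: int | None = None


# ---------------------------------------------------------------------------
# Descriptor computation


def _pharm_fingerprint(mol: Chem.Mol) -> np.ndarray:
    """147-bit pharmacophore-pair fingerprint on through-bond distances."""
    bits = np.zeros(N_PHARM_BITS)
    feats: list[tuple[int, int]] = []  # (class index, atom index)
    for ci, (_, patt) in enumerate(_PHARM_PATTERNS):
        for match in mol.GetSubstructMatches(patt):
            feats.append((ci, match[0]))
    if not feats:
        return bits
    dmat = Chem.GetDistanceMatrix(mol)
    n_classes = len(_PHARM_PATTERNS)
    n_bins = len(_PHARM_BINS)
    for i in range(len(feats)):
        ci, ai = feats[i]
        for j in range(i + 1, len(feats)):
            cj, aj = feats[j]
            if ai == aj:
                continue
            d = dmat[ai, aj]
            bin_idx = next(
                (b for b, (lo, hi) in enumerate(_PHARM_BINS) if lo <= d <= hi), None
            )
            if bin_idx is None:
                continue
            lo_c, hi_c = sorted((ci, cj))
            # index of unordered pair (lo_c, hi_c) in upper-triangular order
            pair = lo_c * n_classes - lo_c * (lo_c - 1) // 2 + (hi_c - lo_c)
            bits[pair * n_bins + bin_idx] = 1.0
    return bits


def _compute_row(mol: Chem.Mol, blocks: Sequence[str]) -> dict[str, np.ndarray]:
    row: dict[str, np.ndarray] = {}
    if "phys2d" in blocks:
        row["phys2d"] = np.array([f(mol) for _, f in _PHYS2D_FUNCS], dtype=float)
    if "keyfp" in blocks:
        fp = MACCSkeys.GenMACCSKeys(mol)
        arr = np.zeros(167)
        for b in fp.GetOnBits():
            arr[b] = 1.0
        row["keyfp"] = arr[1:]  # bit 0 is always unset padding
    if "extfp" in blocks:
        fp = _MORGAN.GetFingerprint(mol)
        arr = np.zeros(1024)
        for b in fp.GetOnBits():
            arr[b] = 1.0
        row["extfp"] = arr
    if "pharmfp" in blocks:
        row["pharmfp"] = _pharm_fingerprint(mol)
    return row


def _block_columns(blocks: Sequence[str]) -> list[Column]:
    cols: list[Column] = []
    for block in blocks:
        if block == "phys2d":
            cols += [Column(n, "phys2d", CONTINUOUS) for n in PHYS2D_NAMES]
        elif block == "keyfp":
            cols += [Column(f"maccs_{i}", "keyfp", BINARY) for i in range(1, 167)]
        elif block == "extfp":
            cols += [Column(f"ecfp4_{i}", "extfp", BINARY) for i in range(1024)]
        elif block == "pharmfp":
            cols += [Column(f"ph2_{i}", "pharmfp", BINARY) for i in range(N_PHARM_BITS)]
        else:
            raise ValueError(f"unknown block {block!r}")
    return cols


def compute_descriptors(
    records: Sequence[CompoundRecord], blocks: Sequence[str] = BLOCKS
) -> DescriptorMatrix:
    """Compute the fused descriptor matrix for a compound set.

    Deterministic per structure: identical canonical keys give identical
    rows. Structures the backend cannot process are dropped with a warning.
    Non-finite physchem values are imputed with the column mean.
    """
    columns = _block_columns(blocks)
    rows: list[np.ndarray] = []
    row_ids: list[str] = []
    cache: dict[str, np.ndarray] = {}
    for rec in records:
        if rec.canonical_key in cache:
            rows.append(cache[rec.canonical_key])
            row_ids.append(rec.id)
            continue
        mol = Chem.MolFromSmiles(rec.canonical_key)
        if mol is None:
            logger.warning("descriptor backend failed for %s; row dropped", rec.id)
            continue
        try:
            parts = _compute_row(mol, blocks)
        except Exception:  # pragma: no cover - backend-specific failures
            logger.warning("descriptor backend failed for %s; row dropped", rec.id)
            continue
        row = np.concatenate([parts[b] for b in blocks])
        cache[rec.canonical_key] = row
        rows.append(row)
        row_ids.append(rec.id)
    if not rows:
        raise ValueError("no descriptor rows computed")
    values = np.vstack(rows)
    bad = ~np.isfinite(values)
    if bad.any():
        col_means = np.where(
            np.isfinite(values).any(axis=0),
            np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=0),
            0.0,
        )
        values[bad] = np.broadcast_to(col_means, values.shape)[bad]
    mat = DescriptorMatrix(row_ids=row_ids, columns=columns, values=values)
    logger.info("computed descriptors: %s", mat.block_sizes())
    return mat


# ---------------------------------------------------------------------------
# Feature selection


def drop_zero_variance(
    matrix: DescriptorMatrix,
) -> tuple[DescriptorMatrix, FeatureSelectionReport]:
    """Remove columns whose sample variance is exactly zero."""
    if matrix.values.shape[0] < 2:
        raise ValueError("need at least 2 rows to assess variance")
    var = matrix.values.var(axis=0, ddof=1)
    keep = [i for i, v in enumerate(var) if v > 0]
    if not keep:
        raise ValueError("all columns are constant")
    report = FeatureSelectionReport(
        dropped_zero_variance=[matrix.columns[i].name for i, v in enumerate(var) if v == 0],
        retained=[matrix.columns[i].name for i in keep],
    )
    return matrix.subset_columns(keep), report


def drop_correlated(
    matrix: DescriptorMatrix, r_threshold: float = 0.95
) -> tuple[DescriptorMatrix, FeatureSelectionReport]:
    """Greedy pruning of highly correlated column pairs.

    A single pass over pairs in column-index order: when |r| exceeds the
    threshold and both columns are still alive, the later column is dropped.
    """
    corr = np.corrcoef(matrix.values, rowvar=False)
    n = corr.shape[0]
    alive = np.ones(n, dtype=bool)
    dropped: list[tuple[str, str, float]] = []
    for i in range(n):
        if not alive[i]:
            continue
        for j in range(i + 1, n):
            if alive[j] and abs(corr[i, j]) > r_threshold:
                alive[j] = False
                dropped.append(
                    (matrix.columns[i].name, matrix.columns[j].name, float(corr[i, j]))
                )
    keep = [i for i in range(n) if alive[i]]
    report = FeatureSelectionReport(
        dropped_correlated=dropped,
        retained=[matrix.columns[i].name for i in keep],
    )
    return matrix.subset_columns(keep), report


def select_representatives(
    matrix: DescriptorMatrix, target_k: int = 495, seed: int = 0
) -> tuple[DescriptorMatrix, FeatureSelectionReport]:
    """Reduce to ``target_k`` representative columns.

    Columns are clustered hierarchically on the distance 1 - |r| with
    complete linkage; the tree is cut into target_k clusters and each
    cluster's medoid (greatest mean |r| to its cluster, ties by column
    order) is retained. Deterministic; the seed argument is accepted for
    interface stability.
    """
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    n = len(matrix.columns)
    if target_k >= n:
        report = FeatureSelectionReport(retained=matrix.column_names, target_k=target_k)
        return matrix, report
    corr = np.abs(np.corrcoef(matrix.values, rowvar=False))
    corr = np.clip(np.nan_to_num(corr, nan=0.0), 0.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=target_k, criterion="maxclust")
    keep: list[int] = []
    for cl in np.unique(labels):
        members = np.where(labels == cl)[0]
        if len(members) == 1:
            keep.append(int(members[0]))
            continue
        sub = corr[np.ix_(members, members)]
        mean_r = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
        keep.append(int(members[int(np.argmax(mean_r))]))
    keep.sort()
    report = FeatureSelectionReport(
        retained=[matrix.columns[i].name for i in keep], target_k=target_k
    )
    return matrix.subset_columns(keep), report


# ---------------------------------------------------------------------------
# Standardization


@dataclass
class Standardizer:
    """Z-scoring of continuous columns with stored training statistics.

    Binary columns pass through untouched so the {0,1} semantics survive.
    """

    column_names: list[str]
    kinds: list[str]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, matrix: DescriptorMatrix) -> "Standardizer":
        cont = np.array([c.kind == CONTINUOUS for c in matrix.columns])
        mean = np.where(cont, matrix.values.mean(axis=0), 0.0)
        sd = np.where(cont, matrix.values.std(axis=0, ddof=0), 1.0)
        sd = np.where(sd == 0, 1.0, sd)
        return cls(
            column_names=matrix.column_names,
            kinds=[c.kind for c in matrix.columns],
            mean=mean,
            sd=sd,
        )

    def transform(self, matrix: DescriptorMatrix) -> DescriptorMatrix:
        if matrix.column_names != self.column_names:
            raise ValueError("column mismatch between matrix and stored statistics")
        cont = np.array([k == CONTINUOUS for k in self.kinds])
        values = matrix.values.copy()
        values[:, cont] = (values[:, cont] - self.mean[cont]) / self.sd[cont]
        return DescriptorMatrix(
            row_ids=list(matrix.row_ids), columns=list(matrix.columns), values=values
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "column_names": self.column_names,
            "kinds": self.kinds,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Standardizer":
        payload = json.loads(Path(path).read_text())
        return cls(
            column_names=payload["column_names"],
            kinds=payload["kinds"],
            mean=np.array(payload["mean"]),
            sd=np.array(payload["sd"]),
        )


def standardize(matrix: DescriptorMatrix) -> tuple[DescriptorMatrix, Standardizer]:
    """Fit training statistics and transform in one step."""
    scaler = Standardizer.fit(matrix)
    return scaler.transform(matrix), scaler
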
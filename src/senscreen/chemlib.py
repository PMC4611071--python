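"""Compound I/O and training-set assembly.

Reads compound tables (SMILES lists, CSV, SDF), canonicalizes structures,
applies the molecular-weight window, down-samples over-large inactive pools
by similarity to the actives, and merges labeled pools into a deduplicated
training set.

Structures are keyed by the canonical SMILES of the largest fragment (salts
stripped), so two depictions of the same molecule always collapse to one
record. Molecular weight is the average-atomic-mass weight of that parent
fragment.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import TanimotoSimilarity

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("senscreen")

ACTIVE = "active"
INACTIVE = "inactive"
UNKNOWN = "unknown"
LABELS = {ACTIVE, INACTIVE, UNKNOWN}

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


@dataclass(frozen=True)
class CompoundRecord:
    """One structure with its label and a backend-stable dedup key."""

    id: str
    structure: str
    canonical_key: str
    mw: float
    label: str = UNKNOWN
    source: str = ""


@dataclass
class AssemblyConfig:
    """Parameters of training-set assembly.

    The MW window is open: a compound is kept only if mw_lo < MW < mw_hi.
    ``similarity_band`` bounds the maximum Tanimoto similarity a retained
    inactive may have to the active pool — decoys are kept chemically
    relevant but never identical to an active.
    """

    mw_lo: float = 150.0
    mw_hi: float = 700.0
    similarity_band: tuple[float, float] = (0.50, 0.85)
    inactive_target_size: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.mw_lo < self.mw_hi):
            raise ValueError("require 0 < mw_lo < mw_hi")
        lo, hi = self.similarity_band
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("similarity_band must satisfy 0 <= lo <= hi <= 1")


def _parent_mol(smiles: str) -> Chem.Mol | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return mol


def make_record(
    id: str, smiles: str, label: str = UNKNOWN, source: str = ""
) -> CompoundRecord | None:
    """Build a record from a SMILES, or None if it does not parse."""
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    mol = _parent_mol(smiles)
    if mol is None:
        return None
    key = Chem.MolToSmiles(mol)
    return CompoundRecord(
        id=id,
        structure=smiles,
        canonical_key=key,
        mw=Descriptors.MolWt(mol),
        label=label,
        source=source,
    )


def fingerprint(record: CompoundRecord):
    """Morgan radius-2 1024-bit fingerprint of the parent structure."""
    mol = Chem.MolFromSmiles(record.canonical_key)
    if mol is None:  # canonical_key always re-parses; guard anyway
        raise ValueError(f"unparsable canonical key for {record.id}")
    return _MORGAN.GetFingerprint(mol)


# ---------------------------------------------------------------------------
# Reading


def read_compound_table(
    path: str | Path, label_column: str = "label", label: str | None = None
) -> list[CompoundRecord]:
    """Read records from a .smi/.txt, .csv, or .sdf file.

    Unparsable structures are skipped and counted (logged at WARNING).
    ``label`` overrides any per-row label; for SMILES/SDF files without
    label fields it is the only way to set one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    rows: list[tuple[str, str, str, str]] = []  # (id, smiles, label, source)
    if suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                rows.append((f"{path.stem}_{i}", "", UNKNOWN, path.name))
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"{path.stem}_{i}"
            rows.append((name or f"{path.stem}_{i}", Chem.MolToSmiles(mol), UNKNOWN, path.name))
    elif suffix == ".csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise ValueError(f"{path}: CSV needs a 'smiles' column")
            for i, row in enumerate(reader):
                rows.append(
                    (
                        row.get("id") or f"{path.stem}_{i}",
                        row["smiles"],
                        (row.get(label_column) or UNKNOWN).strip().lower(),
                        row.get("source") or path.name,
                    )
                )
    else:  # SMILES text: "smiles [id]" per line
        with open(path) as fh:
            for i, line in enumerate(fh):
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                rows.append(
                    (parts[1] if len(parts) > 1 else f"{path.stem}_{i}", parts[0], UNKNOWN, path.name)
                )

    records: list[CompoundRecord] = []
    skipped = 0
    for rid, smi, row_label, source in rows:
        rec = make_record(rid, smi, label or (row_label if row_label in LABELS else UNKNOWN), source)
        if rec is None:
            skipped += 1
        else:
            records.append(rec)
    if skipped:
        logger.warning("%s: skipped %d unparsable structure(s)", path.name, skipped)
    if not records:
        raise ValueError(f"{path}: no parsable records")
    return records


def write_compound_csv(records: Iterable[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "canonical_key", "mw", "label", "source"])
        for r in records:
            writer.writerow([r.id, r.structure, r.canonical_key, f"{r.mw:.3f}", r.label, r.source])


# ---------------------------------------------------------------------------
# Filtering and assembly


def mw_filter(
    records: Sequence[CompoundRecord], config: AssemblyConfig | None = None
) -> list[CompoundRecord]:
    """Keep records with mw strictly inside the (mw_lo, mw_hi) window."""
    config = config or AssemblyConfig()
    return [r for r in records if config.mw_lo < r.mw < config.mw_hi]


def downsample_inactives(
    inactives: Sequence[CompoundRecord],
    actives: Sequence[CompoundRecord],
    config: AssemblyConfig | None = None,
) -> list[CompoundRecord]:
    """Reduce an inactive pool to decoys inside the similarity band.

    Each inactive's maximum Tanimoto similarity to the active pool must lie
    within ``similarity_band``; survivors are ranked by descending similarity
    (ties by canonical_key) and truncated to ``inactive_target_size``.
    """
    config = config or AssemblyConfig()
    if not actives:
        raise ValueError("active pool is empty")
    lo, hi = config.similarity_band
    active_fps = [fingerprint(a) for a in actives]
    scored: list[tuple[float, str, CompoundRecord]] = []
    for rec in inactives:
        fp = fingerprint(rec)
        sim = max(TanimotoSimilarity(fp, afp) for afp in active_fps)
        if lo <= sim <= hi:
            scored.append((sim, rec.canonical_key, rec))
    scored.sort(key=lambda t: (-t[0], t[1]))
    if config.inactive_target_size is not None:
        scored = scored[: config.inactive_target_size]
    return [rec for _, _, rec in scored]


def _dedup_same_label(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    seen: set[str] = set()
    out = []
    for r in records:
        if r.canonical_key not in seen:
            seen.add(r.canonical_key)
            out.append(r)
    return out


def assemble_training_set(
    active_pools: Sequence[Sequence[CompoundRecord]],
    inactive_pools: Sequence[Sequence[CompoundRecord]],
    config: AssemblyConfig | None = None,
) -> tuple[list[CompoundRecord], dict]:
    """Merge per-target pools into one deduplicated, MW-filtered training set.

    Within a label, duplicate structures keep the first record in source
    order. A structure labeled active in one pool and inactive in another is
    removed from both sides — a cross-label clash carries no usable signal.

    Returns (records, report) where the report counts every exclusion.
    """
    config = config or AssemblyConfig()
    if not active_pools or not inactive_pools:
        raise ValueError("need at least one active and one inactive pool")

    actives_raw = [replace(r, label=ACTIVE) for pool in active_pools for r in pool]
    inactives_raw = [replace(r, label=INACTIVE) for pool in inactive_pools for r in pool]

    actives_mw = mw_filter(actives_raw, config)
    inactives_mw = mw_filter(inactives_raw, config)

    actives = _dedup_same_label(actives_mw)
    inactives = _dedup_same_label(inactives_mw)

    clash = {r.canonical_key for r in actives} & {r.canonical_key for r in inactives}
    actives = [r for r in actives if r.canonical_key not in clash]
    inactives = [r for r in inactives if r.canonical_key not in clash]

    report = {
        "input_actives": len(actives_raw),
        "input_inactives": len(inactives_raw),
        "mw_excluded": (len(actives_raw) - len(actives_mw))
        + (len(inactives_raw) - len(inactives_mw)),
        "same_label_duplicates": (len(actives_mw) - len(actives) - 0)
        + (len(inactives_mw) - len(inactives) - 0)
        - 2 * len(clash) * 0,
        "cross_label_removed_keys": len(clash),
        "final_actives": len(actives),
        "final_inactives": len(inactives),
    }
    # same-label duplicate count, before clash removal
    report["same_label_duplicates"] = (
        len(actives_mw) + len(inactives_mw)
        - len(_dedup_same_label(actives_mw)) - len(_dedup_same_label(inactives_mw))
    )
    out = actives + inactives
    if not out:
        raise ValueError("assembly produced an empty training set")
    logger.info(
        "assembled %d actives + %d inactives (removed %d cross-label keys)",
        report["final_actives"], report["final_inactives"], len(clash),
    )
    return out, report
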
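"""Synthetic inputs with the statistical structure the pipeline assumes.

Structures are generated by decorating a small scaffold grammar (a
benzimidazolone core among amide, sulfonamide, indole, arylpiperazine and
pyridine scaffolds) with drug-like substituents, so descriptor space is
realistic and a planted threshold rule on physicochemical columns is
learnable while active and inactive chemical spaces still overlap in every
other dimension. Activity labels come from the planted rule, optionally
flipped with a configurable noise rate; screening libraries carry an exact
planted fraction of rule-true compounds with the truth table held apart
from the records.

A matching gene-universe generator plants process-network overlaps at
requested intersection sizes, so enrichment p-values are known in closed
form.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemlib import ACTIVE, INACTIVE, UNKNOWN, CompoundRecord, make_record
from .descriptors import PHYS2D_NAMES, _PHYS2D_FUNCS
from .netprofiles import ProcessNetwork

logger = logging.getLogger("senscreen")

_FUNC_BY_NAME = dict(_PHYS2D_FUNCS)

# Scaffold templates: slots take "" (an implicit H) or a parenthesized
# substituent branch.
SCAFFOLDS = [
    "O=C1N{0}c2cc{1}ccc2N1{2}",          # benzimidazolone
    "O=C(N{0})c1cc{1}ccc1{2}",           # benzamide
    "O=S(=O)(N{0})c1cc{1}ccc1{2}",       # benzenesulfonamide
    "c1ccc2c(c1)c{0}c{1}[nH]2",          # indole
    "c1cc{0}ccc1N1CCN{1}CC1",            # arylpiperazine
    "O=C(N{0})c1cc{1}cnc1",              # nicotinamide
]

SUBSTITUENTS = [
    "", "(C)", "(CC)", "(CCC)", "(C(C)C)", "(O)", "(OC)", "(OCC)",
    "(N)", "(NC)", "(N(C)C)", "(F)", "(Cl)", "(Br)", "(C#N)",
    "(C(=O)O)", "(C(=O)OC)", "(C(=O)N)", "(CO)", "(CCO)", "(C(F)(F)F)",
    "(c1ccccc1)", "(Cc1ccccc1)", "(OCc1ccccc1)", "(CCN(C)C)", "(SC)",
    "(c1ccc(F)cc1)", "(c1ccc(OC)cc1)", "(C(=O)c1ccccc1)", "(CCc1ccccc1)",
]


@dataclass(frozen=True)
class RuleClause:
    column: str  # a phys2d descriptor name
    lo: float = float("-inf")
    hi: float = float("inf")


# Default planted activity: moderately lipophilic, low-polarity compounds.
DEFAULT_RULE = (
    RuleClause("MolLogP", lo=2.0),
    RuleClause("TPSA", hi=80.0),
)


@dataclass
class LibrarySpec:
    n_actives: int = 500
    n_inactives: int = 500
    n_library: int = 10_000
    planted_fraction: float = 0.02
    label_noise: float = 0.05
    planted_rule: tuple[RuleClause, ...] = DEFAULT_RULE
    mw_window: tuple[float, float] = (155.0, 695.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if min(self.n_actives, self.n_inactives, self.n_library) < 0:
            raise ValueError("counts must be >= 0")
        for clause in self.planted_rule:
            if clause.column not in PHYS2D_NAMES:
                raise KeyError(f"rule references unknown descriptor {clause.column!r}")


def rule_active(smiles_or_mol, rule: Sequence[RuleClause] = DEFAULT_RULE) -> bool:
    """Evaluate the planted threshold rule on one structure."""
    mol = (
        Chem.MolFromSmiles(smiles_or_mol)
        if isinstance(smiles_or_mol, str)
        else smiles_or_mol
    )
    if mol is None:
        raise ValueError("unparsable structure")
    for clause in rule:
        v = _FUNC_BY_NAME[clause.column](mol)
        if not (clause.lo <= v <= clause.hi):
            return False
    return True


def _generate_structures(spec: LibrarySpec, rng: np.random.Generator):
    """Yield (canonical_smiles, mol, rule_truth) for unique valid decorations."""
    from .chemlib import _parent_mol  # single-fragment by construction, but reuse
    from rdkit.Chem import Descriptors as RD

    seen: set[str] = set()
    lo, hi = spec.mw_window
    while True:
        template = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
        n_slots = template.count("{")
        subs = [SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))] for _ in range(n_slots)]
        smi = template.format(*subs)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        if not (lo < RD.MolWt(mol) < hi):
            continue
        yield canon, mol, rule_active(mol, spec.planted_rule)


def gen_compound_library(
    spec: LibrarySpec | None = None,
) -> tuple[list[CompoundRecord], dict[str, str]]:
    """Labeled training pool: (records, true-label table by id).

    Records carry the noisy labels the pipeline sees; the returned truth
    table holds the noise-free rule labels. Reproducible from spec.seed.
    """
    spec = spec or LibrarySpec()
    rng = np.random.default_rng(spec.seed)
    actives: list[str] = []
    inactives: list[str] = []
    gen = _generate_structures(spec, rng)
    budget = 200 * (spec.n_actives + spec.n_inactives) + 10_000
    for _ in range(budget):
        canon, _, truth = next(gen)
        if truth and len(actives) < spec.n_actives:
            actives.append(canon)
        elif not truth and len(inactives) < spec.n_inactives:
            inactives.append(canon)
        if len(actives) == spec.n_actives and len(inactives) == spec.n_inactives:
            break
    else:
        raise RuntimeError("structure generation budget exhausted")
    records: list[CompoundRecord] = []
    truth_table: dict[str, str] = {}
    for i, (canon, truth_label) in enumerate(
        [(s, ACTIVE) for s in actives] + [(s, INACTIVE) for s in inactives]
    ):
        label = truth_label
        if spec.label_noise and rng.random() < spec.label_noise:
            label = INACTIVE if label == ACTIVE else ACTIVE
        rec = make_record(f"T{i:05d}", canon, label=label, source="synthetic")
        assert rec is not None
        records.append(rec)
        truth_table[rec.id] = truth_label
    logger.info(
        "generated %d training structures (%d noisy labels)",
        len(records),
        sum(1 for r in records if truth_table[r.id] != r.label),
    )
    return records, truth_table


def gen_screen_library(
    spec: LibrarySpec | None = None,
) -> tuple[list[CompoundRecord], dict[str, bool]]:
    """Unlabeled screening library with an exact planted active count.

    Exactly round(planted_fraction * n_library) structures satisfy the
    activity rule — by construction, not sampling. The truth table is
    returned for evaluation only; the records all carry the 'unknown'
    label. The training generator stream is advanced independently, so a
    library never duplicates training structures for the same seed.
    """
    spec = spec or LibrarySpec()
    rng = np.random.default_rng(spec.seed + 1_000_003)
    n_true = round(spec.planted_fraction * spec.n_library)
    n_false = spec.n_library - n_true
    trues: list[str] = []
    falses: list[str] = []
    gen = _generate_structures(spec, rng)
    budget = 200 * max(spec.n_library, 1) + 10_000
    for _ in range(budget):
        canon, _, truth = next(gen)
        if truth and len(trues) < n_true:
            trues.append(canon)
        elif not truth and len(falses) < n_false:
            falses.append(canon)
        if len(trues) == n_true and len(falses) == n_false:
            break
    else:
        raise RuntimeError("structure generation budget exhausted")
    smiles = trues + falses
    order = rng.permutation(len(smiles))
    records, truth_table = [], {}
    for j, idx in enumerate(order):
        rec = make_record(f"L{j:06d}", smiles[idx], label=UNKNOWN, source="library")
        assert rec is not None
        records.append(rec)
        truth_table[rec.id] = bool(idx < len(trues))
    return records, truth_table


# ---------------------------------------------------------------------------
# Gene universe fixtures


@dataclass
class GeneUniverseSpec:
    n_genes: int = 1000
    network_sizes: tuple[int, ...] = tuple([50] * 10)
    # list label -> {network id -> planted intersection size}; list length
    planted_lists: dict[str, dict[str, int]] = field(default_factory=dict)
    list_size: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s > self.n_genes for s in self.network_sizes):
            raise ValueError("network size exceeds the gene universe")


def gen_gene_fixture(
    spec: GeneUniverseSpec | None = None,
) -> tuple[list[ProcessNetwork], dict[str, set[str]]]:
    """(networks, gene lists) with planted overlaps of known size.

    Each requested list takes exactly k genes from each designated network
    (and from no other network), topped up with genes outside every
    network, so its enrichment p-values follow in closed form.
    """
    spec = spec or GeneUniverseSpec()
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    networks: list[ProcessNetwork] = []
    pool = rng.permutation(spec.n_genes)
    cursor = 0
    for i, size in enumerate(spec.network_sizes):
        if cursor + size > spec.n_genes:
            raise ValueError("networks exhaust the gene universe (sizes too large)")
        members = frozenset(genes[g] for g in pool[cursor : cursor + size])
        networks.append(ProcessNetwork(f"net{i:03d}", f"process network {i}", members))
        cursor += size
    outside = [genes[g] for g in pool[cursor:]]

    lists: dict[str, set[str]] = {}
    by_id = {n.id: n for n in networks}
    planted = spec.planted_lists or {"list0": {networks[0].id: min(20, spec.list_size)}}
    for label, overlaps in planted.items():
        chosen: set[str] = set()
        for net_id, k in overlaps.items():
            net = by_id[net_id]
            if k > len(net.genes):
                raise ValueError(f"cannot overlap {net_id} at {k} > network size")
            members = sorted(net.genes)
            take = rng.choice(len(members), size=k, replace=False)
            chosen |= {members[t] for t in take}
        filler_needed = spec.list_size - len(chosen)
        if filler_needed < 0:
            raise ValueError(f"list {label}: planted overlaps exceed list size")
        if filler_needed > len(outside):
            raise ValueError(f"list {label}: not enough genes outside all networks")
        take = rng.choice(len(outside), size=filler_needed, replace=False)
        chosen |= {outside[t] for t in take}
        lists[label] = chosen
    return networks, lists


def write_manifest(path: str | Path, **payload) -> None:
    """Persist seeds and truth tables alongside generated fixtures."""
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
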
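"""End-to-end workflow orchestration with resumable stage outputs.

Stage order: assemble -> featurize -> scan -> prune -> reselect ->
train_ensemble -> screen -> prioritize. The two-pass structure matters:
an initial cross-validated scan identifies consistently misclassified
training compounds, those are pruned, and feature selection is re-run on
the retained compounds before the final ensemble is trained.

Every stage writes its outputs plus a checksum of its effective
configuration into the run manifest; re-running skips completed stages
whose checksum still matches, unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemlib, descriptors, ensemble, fixtures, prioritize, scg

logger = logging.getLogger("senscreen")

STAGES = [
    "assemble",
    "featurize",
    "scan",
    "prune",
    "reselect",
    "train_ensemble",
    "screen",
    "prioritize",
]


@dataclass
class RunConfig:
    run_dir: str = "senscreen_run"
    seed: int = 0
    force: bool = False
    log_level: str = "INFO"

    # inputs: either file paths or a synthetic fixture spec
    active_files: list[str] = field(default_factory=list)
    inactive_files: list[str] = field(default_factory=list)
    library_file: str | None = None
    fixture: fixtures.LibrarySpec | None = None

    # assembly
    mw_lo: float = 150.0
    mw_hi: float = 700.0

    # descriptors / feature selection
    blocks: tuple[str, ...] = descriptors.BLOCKS
    r_threshold: float = 0.95
    target_k: int = 495

    # scan / prune
    scan_grid: list[dict] = field(
        default_factory=lambda: [{"hidden_layers": [20], "trainer": "scg"}]
    )
    cv_k: int = 10
    scan_max_epochs: int = 100
    prune_threshold: float = 0.4

    # L2 regularization per training compound: keeps the nets from
    # interpolating label noise, which otherwise floods the screen with
    # confident false positives
    weight_decay_per_sample: float = 0.006

    # ensemble / screen
    n_members: int = 10
    final_max_epochs: int = 300
    theta_active: float = 0.95
    theta_inactive: float = 0.05

    # prioritize
    rules_file: str | None = None
    n_select: int = 147
    n_clusters: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "fixture" in payload and payload["fixture"] is not None:
            payload["fixture"] = fixtures.LibrarySpec(**payload["fixture"])
        return cls(**payload)

    def stage_config(self, stage: str) -> dict:
        """The configuration slice a stage's checksum depends on."""
        base = {"seed": self.seed, "stage": stage}
        fix = dataclasses.asdict(self.fixture) if self.fixture else None
        per_stage = {
            "assemble": {
                "active_files": self.active_files,
                "inactive_files": self.inactive_files,
                "fixture": fix,
                "mw": [self.mw_lo, self.mw_hi],
            },
            "featurize": {"blocks": list(self.blocks)},
            "scan": {
                "grid": self.scan_grid,
                "k": self.cv_k,
                "epochs": self.scan_max_epochs,
            },
            "prune": {"threshold": self.prune_threshold},
            "reselect": {"r": self.r_threshold, "target_k": self.target_k},
            "train_ensemble": {
                "n_members": self.n_members,
                "epochs": self.final_max_epochs,
            },
            "screen": {
                "library": self.library_file or "fixture",
                "theta": [self.theta_active, self.theta_inactive],
            },
            "prioritize": {
                "rules": self.rules_file or "lead_like_defaults",
                "n_select": self.n_select,
                "n_clusters": self.n_clusters,
            },
        }
        base.update(per_stage[stage])
        return base


def _checksum(payload: dict, upstream: str = "") -> str:
    raw = upstream + json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(raw.encode()).hexdigest()[:16]


class Workflow:
    def __init__(self, config: RunConfig):
        self.config = config
        self.run_dir = Path(config.run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.run_dir / "manifest.json"
        self.manifest: dict = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"stages": {}}
        )
        self.ctx: dict = {}

    # -- manifest bookkeeping --
    def _stage_dir(self, stage: str) -> Path:
        d = self.run_dir / stage
        d.mkdir(exist_ok=True)
        return d

    def _can_skip(self, stage: str, checksum: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        return (
            not self.config.force
            and entry is not None
            and entry.get("checksum") == checksum
            and all((self.run_dir / f).exists() for f in entry.get("outputs", []))
        )

    def _record(self, stage: str, checksum: str, outputs: list[str]) -> None:
        self.manifest["stages"][stage] = {
            "checksum": checksum,
            "outputs": outputs,
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def run(self) -> dict:
        upstream = ""
        for stage in STAGES:
            checksum = _checksum(self.config.stage_config(stage), upstream)
            if self._can_skip(stage, checksum):
                logger.info("stage %s: up to date, skipped", stage)
                getattr(self, f"_load_{stage}")()
            else:
                logger.info("stage %s: running", stage)
                try:
                    outputs = getattr(self, f"_run_{stage}")()
                except Exception as exc:
                    raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
                self._record(stage, checksum, outputs)
            upstream = checksum
        self.manifest["seed"] = self.config.seed
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))
        return self.manifest

    # -- stage: assemble --
    def _run_assemble(self) -> list[str]:
        cfg = self.config
        acfg = chemlib.AssemblyConfig(mw_lo=cfg.mw_lo, mw_hi=cfg.mw_hi)
        if cfg.fixture is not None:
            spec = dataclasses.replace(cfg.fixture, seed=cfg.seed)
            records, truth = fixtures.gen_compound_library(spec)
            active_pools = [[r for r in records if r.label == chemlib.ACTIVE]]
            inactive_pools = [[r for r in records if r.label == chemlib.INACTIVE]]
        else:
            truth = {}
            active_pools = [
                chemlib.read_compound_table(p, label=chemlib.ACTIVE)
                for p in cfg.active_files
            ]
            inactive_pools = [
                chemlib.read_compound_table(p, label=chemlib.INACTIVE)
                for p in cfg.inactive_files
            ]
        training, report = chemlib.assemble_training_set(
            active_pools, inactive_pools, acfg
        )
        d = self._stage_dir("assemble")
        chemlib.write_compound_csv(training, d / "training.csv")
        (d / "report.json").write_text(json.dumps(report, indent=2))
        (d / "truth.json").write_text(json.dumps(truth, indent=2))
        self.ctx["training"] = training
        return ["assemble/training.csv", "assemble/report.json", "assemble/truth.json"]

    def _load_assemble(self) -> None:
        self.ctx["training"] = chemlib.read_compound_table(
            self.run_dir / "assemble" / "training.csv"
        )

    # -- stage: featurize --
    def _run_featurize(self) -> list[str]:
        matrix = descriptors.compute_descriptors(self.ctx["training"], self.config.blocks)
        matrix, _ = descriptors.drop_zero_variance(matrix)
        std, scaler = descriptors.standardize(matrix)
        d = self._stage_dir("featurize")
        matrix.to_csv(d / "matrix.csv")
        scaler.to_json(d / "scaler.json")
        self.ctx["matrix_raw"] = matrix
        self.ctx["matrix_std"] = std
        return ["featurize/matrix.csv", "featurize/scaler.json"]

    def _load_featurize(self) -> None:
        matrix = descriptors.DescriptorMatrix.from_csv(
            self.run_dir / "featurize" / "matrix.csv"
        )
        scaler = descriptors.Standardizer.from_json(
            self.run_dir / "featurize" / "scaler.json"
        )
        self.ctx["matrix_raw"] = matrix
        self.ctx["matrix_std"] = scaler.transform(matrix)

    def _targets(self, matrix: descriptors.DescriptorMatrix) -> np.ndarray:
        labels = {r.id: r.label for r in self.ctx["training"]}
        return np.array(
            [[1.0, 0.0] if labels[i] == chemlib.ACTIVE else [0.0, 1.0] for i in matrix.row_ids]
        )

    # -- stage: scan --
    def _run_scan(self) -> list[str]:
        cfg = self.config
        X = self.ctx["matrix_std"].values
        Y = self._targets(self.ctx["matrix_std"])
        rows = []
        best = None
        for grid_cfg in cfg.scan_grid:
            params = scg.MLPParams(
                n_inputs=X.shape[1],
                seed=cfg.seed,
                max_epochs=cfg.scan_max_epochs,
                weight_decay=cfg.weight_decay_per_sample * X.shape[0],
                **grid_cfg,
            )
            report = scg.kfold_cv(
                X, Y, params, k=cfg.cv_k, seed=cfg.seed,
                row_ids=self.ctx["matrix_std"].row_ids,
            )
            rows.append(
                {"config": grid_cfg, "accuracy": report.accuracy, "kappa": report.kappa,
                 "best": False}
            )
            if best is None or (report.kappa, report.accuracy) > (
                best[1].kappa, best[1].accuracy
            ):
                best = (grid_cfg, report)
        assert best is not None
        best_cfg, best_report = best
        for row in rows:
            row["best"] = row["config"] == best_cfg
        d = self._stage_dir("scan")
        (d / "scan.json").write_text(json.dumps(rows, indent=2))
        pd.DataFrame(
            {"id": self.ctx["matrix_std"].row_ids, "mse": best_report.per_compound_mse}
        ).to_csv(d / "per_compound_mse.csv", index=False)
        (d / "best.json").write_text(json.dumps(best_cfg))
        self.ctx["best_cfg"] = best_cfg
        self.ctx["per_mse"] = dict(
            zip(self.ctx["matrix_std"].row_ids, best_report.per_compound_mse)
        )
        return ["scan/scan.json", "scan/per_compound_mse.csv", "scan/best.json"]

    def _load_scan(self) -> None:
        d = self.run_dir / "scan"
        self.ctx["best_cfg"] = json.loads((d / "best.json").read_text())
        df = pd.read_csv(d / "per_compound_mse.csv")
        self.ctx["per_mse"] = dict(zip(df.id.astype(str), df.mse))

    # -- stage: prune --
    def _run_prune(self) -> list[str]:
        thr = self.config.prune_threshold
        retained = [i for i, m in self.ctx["per_mse"].items() if m <= thr]
        d = self._stage_dir("prune")
        (d / "retained_ids.json").write_text(json.dumps(retained))
        self.ctx["retained_ids"] = retained
        logger.info("pruned to %d / %d compounds", len(retained), len(self.ctx["per_mse"]))
        return ["prune/retained_ids.json"]

    def _load_prune(self) -> None:
        self.ctx["retained_ids"] = json.loads(
            (self.run_dir / "prune" / "retained_ids.json").read_text()
        )

    # -- stage: reselect --
    def _run_reselect(self) -> list[str]:
        cfg = self.config
        matrix = self.ctx["matrix_raw"]
        keep_rows = [i for i, rid in enumerate(matrix.row_ids) if rid in set(self.ctx["retained_ids"])]
        pruned = descriptors.DescriptorMatrix(
            row_ids=[matrix.row_ids[i] for i in keep_rows],
            columns=list(matrix.columns),
            values=matrix.values[keep_rows],
        )
        pruned, _ = descriptors.drop_zero_variance(pruned)
        pruned, _ = descriptors.drop_correlated(pruned, cfg.r_threshold)
        selected, report = descriptors.select_representatives(
            pruned, target_k=cfg.target_k, seed=cfg.seed
        )
        std, scaler = descriptors.standardize(selected)
        d = self._stage_dir("reselect")
        selected.to_csv(d / "matrix.csv")
        scaler.to_json(d / "scaler.json")
        (d / "selection.json").write_text(
            json.dumps({"retained": report.retained, "target_k": report.target_k})
        )
        self.ctx["final_matrix"] = std
        self.ctx["final_scaler"] = scaler
        self.ctx["final_columns"] = selected.column_names
        return ["reselect/matrix.csv", "reselect/scaler.json", "reselect/selection.json"]

    def _load_reselect(self) -> None:
        d = self.run_dir / "reselect"
        selected = descriptors.DescriptorMatrix.from_csv(d / "matrix.csv")
        scaler = descriptors.Standardizer.from_json(d / "scaler.json")
        self.ctx["final_matrix"] = scaler.transform(selected)
        self.ctx["final_scaler"] = scaler
        self.ctx["final_columns"] = selected.column_names

    # -- stage: train_ensemble --
    def _run_train_ensemble(self) -> list[str]:
        cfg = self.config
        X = self.ctx["final_matrix"].values
        Y = self._targets(self.ctx["final_matrix"])
        params = scg.MLPParams(
            n_inputs=X.shape[1], max_epochs=cfg.final_max_epochs,
            weight_decay=cfg.weight_decay_per_sample * X.shape[0],
            **{k: v for k, v in self.ctx["best_cfg"].items()},
        )
        ens = ensemble.train_ensemble(
            X, Y, params,
            n_members=cfg.n_members,
            base_seed=cfg.seed + 100,
            theta_active=cfg.theta_active,
            theta_inactive=cfg.theta_inactive,
        )
        d = self._stage_dir("train_ensemble")
        for i, member in enumerate(ens.members):
            member.to_json(d / f"member_{i:02d}.json")
        (d / "ensemble.json").write_text(
            json.dumps(
                {
                    "n_members": len(ens.members),
                    "theta_active": ens.theta_active,
                    "theta_inactive": ens.theta_inactive,
                    "aggregation": ens.aggregation,
                }
            )
        )
        self.ctx["ensemble"] = ens
        return [f"train_ensemble/member_{i:02d}.json" for i in range(len(ens.members))] + [
            "train_ensemble/ensemble.json"
        ]

    def _load_train_ensemble(self) -> None:
        d = self.run_dir / "train_ensemble"
        meta = json.loads((d / "ensemble.json").read_text())
        members = [
            scg.MLPModel.from_json(d / f"member_{i:02d}.json")
            for i in range(meta["n_members"])
        ]
        self.ctx["ensemble"] = ensemble.EnsembleModel(
            members=members,
            theta_active=meta["theta_active"],
            theta_inactive=meta["theta_inactive"],
            aggregation=meta["aggregation"],
        )

    # -- stage: screen --
    def _library_records(self) -> list:
        cfg = self.config
        if cfg.fixture is not None:
            spec = dataclasses.replace(cfg.fixture, seed=cfg.seed)
            records, truth = fixtures.gen_screen_library(spec)
            (self._stage_dir("screen") / "library_truth.json").write_text(
                json.dumps(truth)
            )
            return records
        if cfg.library_file is None:
            raise ValueError("no screening library configured")
        return chemlib.read_compound_table(cfg.library_file)

    def _run_screen(self) -> list[str]:
        cfg = self.config
        library = self._library_records()
        self.ctx["library"] = library
        lib_matrix = descriptors.compute_descriptors(library, cfg.blocks)
        col_idx = [lib_matrix.column_names.index(c) for c in self.ctx["final_columns"]]
        lib_sel = lib_matrix.subset_columns(col_idx)
        lib_std = self.ctx["final_scaler"].transform(lib_sel)
        table = ensemble.screen_library(
            self.ctx["ensemble"], lib_std.values, ids=lib_std.row_ids
        )
        smiles = {r.id: r.structure for r in library}
        table["smiles"] = [smiles[i] for i in table["id"]]
        d = self._stage_dir("screen")
        table.to_csv(d / "hits.csv", index=False)
        self.ctx["hit_table"] = table
        outputs = ["screen/hits.csv"]
        if (d / "library_truth.json").exists():
            outputs.append("screen/library_truth.json")
        return outputs

    def _load_screen(self) -> None:
        d = self.run_dir / "screen"
        self.ctx["hit_table"] = pd.read_csv(d / "hits.csv", dtype={"id": str})
        self.ctx["library"] = None

    # -- stage: prioritize --
    def _run_prioritize(self) -> list[str]:
        cfg = self.config
        table = self.ctx["hit_table"]
        hits = table[table.is_hit]
        d = self._stage_dir("prioritize")
        rules = (
            prioritize.FilterRuleSet.from_file(cfg.rules_file)
            if cfg.rules_file
            else prioritize.LEAD_LIKE_RULES
        )
        hit_records = [
            chemlib.make_record(str(rid), smi)
            for rid, smi in zip(hits["id"], hits["smiles"])
        ]
        hit_records = [r for r in hit_records if r is not None]
        outputs = []
        if hit_records:
            props = prioritize.compute_properties(hit_records)
            passed, rejections = prioritize.apply_filters(props, rules)
            pd.DataFrame(
                {"id": props.index, "passed": [str(i) in set(passed) for i in props.index]}
            ).to_csv(d / "filtered.csv", index=False)
            (d / "rejections.json").write_text(json.dumps(rejections))
            outputs += ["prioritize/filtered.csv", "prioritize/rejections.json"]
            passed_records = [r for r in hit_records if r.id in set(passed)]
            if passed_records:
                fp_matrix = descriptors.compute_descriptors(
                    passed_records, blocks=("pharmfp",)
                )
                n_select = min(cfg.n_select, len(passed_records))
                k = cfg.n_clusters or max(1, min(n_select, len(passed_records)) // 3) or 1
                k = min(max(k, 1), len(passed_records))
                assignment = prioritize.cluster_pharmacophores(
                    fp_matrix.values, n_clusters=k, seed=cfg.seed,
                    ids=fp_matrix.row_ids,
                )
                assignment.to_dataframe().to_csv(d / "clusters.csv", index=False)
                selection = prioritize.diversity_sample(assignment, n_select)
                pd.DataFrame({"id": selection}).to_csv(d / "selection.csv", index=False)
                outputs += ["prioritize/clusters.csv", "prioritize/selection.csv"]
        if not outputs:
            (d / "empty.json").write_text(json.dumps({"n_hits": int(len(hits))}))
            outputs = ["prioritize/empty.json"]
        return outputs

    def _load_prioritize(self) -> None:
        pass


def run_workflow(config: RunConfig) -> dict:
    """Execute the eight-stage workflow; returns the run manifest."""
    return Workflow(config).run()


def evaluate_screen(run_dir: str | Path) -> dict:
    """Precision/recall of the hit set against a fixture's planted truth."""
    run_dir = Path(run_dir)
    table = pd.read_csv(run_dir / "screen" / "hits.csv", dtype={"id": str})
    truth = json.loads((run_dir / "screen" / "library_truth.json").read_text())
    hit_ids = set(table.loc[table.is_hit, "id"])
    true_ids = {k for k, v in truth.items() if v}
    tp = len(hit_ids & true_ids)
    precision = tp / len(hit_ids) if hit_ids else float("nan")
    recall = tp / len(true_ids) if true_ids else float("nan")
    return {
        "n_hits": len(hit_ids),
        "n_true_actives": len(true_ids),
        "tp": tp,
        "precision": precision,
        "recall": recall,
    }
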
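"""End-to-end orchestration: align -> activity -> snapshots -> stream ->
communities -> candidate features -> SVM-RFE -> subcellular features ->
train -> evaluate, with per-stage content-hash caching.

Every stage writes its artifacts under the output directory and records a
hash of its inputs (upstream artifacts plus the configuration keys it
depends on) in ``manifest.json``; rerunning with identical inputs and
configuration reuses the cached artifacts, so reports are byte-identical
across reruns. All stochastic stages draw only from the configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import classifier as clf_mod
from . import communities as comm_mod
from . import dynamics as dyn_mod
from . import evaluation as eval_mod
from . import feature_selection as fs_mod
from . import io as io_mod

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_stages", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs; defaults are the method-faithful values."""

    network_path: str = ""
    expression_path: str = ""
    localization_path: str = ""
    labels_path: str = ""
    out_dir: str = "essprot_out"
    first_snapshot_static: bool = True
    observation_window: int = 1
    membership: str = "all"  # or "core"
    svm_C: float = 1.0
    svm_lam: float = 1e-6
    svm_tol: float = 1e-6
    k_communities: int = 64
    subcellular_top_n: int = 1024
    subcellular_exclude_lo: int = 11
    subcellular_exclude_hi: int = 64
    community_hidden: tuple[int, ...] = (32, 16)
    subcellular_hidden: tuple[int, ...] = (256, 64, 16)
    head_hidden: tuple[int, ...] = (16,)
    learning_rate: float = 0.01
    epochs: int | None = None
    min_epochs: int = 200
    coverage_P: float = 0.001
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k in ("community_hidden", "subcellular_hidden", "head_hidden"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for k in ("community_hidden", "subcellular_hidden", "head_hidden"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    dataset: io_mod.AlignedDataset
    dynamic: dyn_mod.DynamicNetwork | None
    stream: dyn_mod.InteractionStream
    candidates: list[frozenset[str]]
    ranking: fs_mod.RfeRanking
    selected: list[int]
    community_features: np.ndarray
    subcellular_features: np.ndarray
    subcellular_terms: list[str]
    train_idx: np.ndarray
    test_idx: np.ndarray
    model: clf_mod.TwoBranchClassifier
    prediction: clf_mod.Prediction
    report: eval_mod.MetricReport
    catalog: comm_mod.CommunityCatalog | None = field(default=None, repr=False)


def _split_and_select(
    dataset: io_mod.AlignedDataset,
    candidates: list[frozenset[str]],
    cfg: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray, fs_mod.RfeRanking, list[int], np.ndarray, np.ndarray, list[str]]:
    nodes = dataset.nodes
    y = dataset.labels
    membership = comm_mod.build_membership_matrix(nodes, candidates)
    train_idx, test_idx = clf_mod.split_dataset(
        y, clf_mod.SplitSpec(cfg.train_fraction, cfg.stratified, cfg.seed)
    )
    svm_cfg = fs_mod.SvmConfig(C=cfg.svm_C, lam=cfg.svm_lam, tol=cfg.svm_tol)
    if membership.shape[1] == 0:
        # no communities observed: the community branch degenerates to width 0
        logger.warning("no candidate communities; community features are empty")
        ranking = fs_mod.RfeRanking(ranked=(), criteria_history=(), surviving_trace=())
        selected: list[int] = []
    else:
        # RFE sees only the (imbalanced) training split
        ranking = fs_mod.rfe_rank(membership[train_idx], y[train_idx], svm_cfg)
        selected = fs_mod.select_top_communities(ranking, cfg.k_communities)
    X_com = membership[:, selected]
    spec = fs_mod.SubcellularFeatureSpec(
        top_n=cfg.subcellular_top_n,
        exclude_lo=cfg.subcellular_exclude_lo,
        exclude_hi=cfg.subcellular_exclude_hi,
    )
    X_sub, terms = fs_mod.subcellular_features(dataset.localization, nodes, spec)
    return train_idx, test_idx, ranking, selected, X_com, X_sub, terms


def run_stages(
    dataset: io_mod.AlignedDataset,
    cfg: PipelineConfig | None = None,
    dynamic: dyn_mod.DynamicNetwork | None = None,
) -> PipelineResult:
    """Run the whole pipeline in memory on an aligned dataset.

    ``dynamic`` overrides the snapshot stage (used by snapshot-detachment
    ablation); otherwise snapshots are built from the expression matrix.
    """
    cfg = cfg or PipelineConfig()
    if dynamic is None:
        profiles = dyn_mod.compute_activity_profiles(dataset)
        dynamic = dyn_mod.build_snapshots(dataset, profiles, cfg.first_snapshot_static)
    stream = dyn_mod.build_stream(dynamic)
    catalog = comm_mod.run_stream(stream, observation_window=cfg.observation_window)
    candidates = comm_mod.collect_candidate_features(catalog, membership=cfg.membership)
    logger.info(
        "nodes=%d edges=%d events=%d communities_observed=%d candidates=%d",
        len(dataset.network.nodes),
        len(dataset.network.edges),
        len(stream.events),
        len(catalog.history),
        len(candidates),
    )
    train_idx, test_idx, ranking, selected, X_com, X_sub, terms = _split_and_select(
        dataset, candidates, cfg
    )
    y = dataset.labels
    model = clf_mod.train_model(
        X_com[train_idx],
        X_sub[train_idx],
        y[train_idx],
        spec=clf_mod.ModelSpec(cfg.community_hidden, cfg.subcellular_hidden, cfg.head_hidden),
        cfg=clf_mod.TrainConfig(
            epochs=cfg.epochs,
            learning_rate=cfg.learning_rate,
            seed=cfg.seed,
            coverage_P=cfg.coverage_P,
            min_epochs=cfg.min_epochs,
        ),
    )
    X_all = np.hstack([X_com, X_sub])
    nodes = dataset.nodes
    pred = clf_mod.predict_scores(model, X_all[test_idx], [nodes[i] for i in test_idx])
    report = eval_mod.compute_metrics(y[test_idx], pred.scores)
    return PipelineResult(
        dataset=dataset,
        dynamic=dynamic,
        stream=stream,
        candidates=candidates,
        ranking=ranking,
        selected=selected,
        community_features=X_com,
        subcellular_features=X_sub,
        subcellular_terms=terms,
        train_idx=train_idx,
        test_idx=test_idx,
        model=model,
        prediction=pred,
        report=report,
        catalog=catalog,
    )


# ---------------------------------------------------------------------------
# cached, file-backed pipeline

def _sha(*parts: str | bytes) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode() if isinstance(p, str) else p)
        h.update(b"\x00")
    return h.hexdigest()


def _file_sha(path: Path) -> str:
    return _sha(path.read_bytes())


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict[str, Any] = {}
        if path.exists():
            try:
                self.data = json.loads(path.read_text())
            except json.JSONDecodeError:
                self.data = {}

    def fresh(self, stage: str, input_hash: str, outputs: list[Path]) -> bool:
        rec = self.data.get(stage)
        return (
            rec is not None
            and rec.get("input_hash") == input_hash
            and all(p.exists() for p in outputs)
        )

    def record(self, stage: str, input_hash: str, outputs: list[Path]) -> None:
        self.data[stage] = {"input_hash": input_hash, "outputs": [str(p) for p in outputs]}
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-backed run with per-stage caching under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("essprot")
    root.addHandler(log_handler)
    manifest = _Manifest(out / "manifest.json")
    try:
        return _run_pipeline_inner(cfg, out, manifest)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _stage_error(stage: str, exc: Exception) -> RuntimeError:
    return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")


def _run_pipeline_inner(cfg: PipelineConfig, out: Path, manifest: _Manifest) -> PipelineResult:
    # ---- stage: align ----
    aligned_dir = out / "aligned"
    aligned_dir.mkdir(exist_ok=True)
    a_paths = {
        "network": aligned_dir / "network.tsv",
        "expression": aligned_dir / "expression.tsv",
        "localization": aligned_dir / "localization.tsv",
        "labels": aligned_dir / "labels.txt",
    }
    try:
        in_hash = _sha(
            *[_file_sha(Path(p)) for p in (cfg.network_path, cfg.expression_path, cfg.localization_path, cfg.labels_path)]
        )
    except (OSError, FileNotFoundError) as exc:
        raise _stage_error("align", exc) from exc
    if manifest.fresh("align", in_hash, list(a_paths.values())):
        logger.info("stage align: cache hit")
    else:
        try:
            with open(cfg.network_path) as fh:
                network = io_mod.read_ppi_edge_list(fh)
            with open(cfg.expression_path) as fh:
                expression = io_mod.read_expression_matrix(fh)
            with open(cfg.localization_path) as fh:
                localization = io_mod.read_localization_table(fh)
            with open(cfg.labels_path) as fh:
                labels = io_mod.read_label_list(fh)
            ds = io_mod.align_dataset(network, expression, localization, labels)
        except Exception as exc:  # noqa: BLE001
            raise _stage_error("align", exc) from exc
        with open(a_paths["network"], "w") as fh:
            io_mod.write_ppi_edge_list(ds.network, fh)
        with open(a_paths["expression"], "w") as fh:
            io_mod.write_expression_matrix(ds.expression, fh)
        with open(a_paths["localization"], "w") as fh:
            io_mod.write_localization_table(ds.localization, fh)
        with open(a_paths["labels"], "w") as fh:
            nodes = ds.nodes
            io_mod.write_label_list(
                io_mod.LabelSet(frozenset(n for i, n in enumerate(nodes) if ds.labels[i])), fh
            )
        manifest.record("align", in_hash, list(a_paths.values()))
    dataset = _load_aligned(a_paths)

    # ---- stage: dynamic network + stream ----
    stream_path = out / "stream.tsv"
    snaps_path = out / "snapshots.tsv"
    dyn_hash = _sha(
        _file_sha(a_paths["network"]),
        _file_sha(a_paths["expression"]),
        f"first_static={cfg.first_snapshot_static}",
    )
    if manifest.fresh("dynamic", dyn_hash, [stream_path, snaps_path]):
        logger.info("stage dynamic: cache hit")
        with open(stream_path) as fh:
            stream = dyn_mod.read_stream(fh)
        dynamic = None
    else:
        try:
            profiles = dyn_mod.compute_activity_profiles(dataset)
            dynamic = dyn_mod.build_snapshots(dataset, profiles, cfg.first_snapshot_static)
            stream = dyn_mod.build_stream(dynamic)
        except Exception as exc:  # noqa: BLE001
            raise _stage_error("dynamic", exc) from exc
        with open(stream_path, "w") as fh:
            dyn_mod.write_stream(stream, fh)
        with open(snaps_path, "w") as fh:
            dyn_mod.write_snapshots(dynamic, fh)
        manifest.record("dynamic", dyn_hash, [stream_path, snaps_path])

    # ---- stage: communities ----
    cand_path = out / "candidates.tsv"
    catalog_path = out / "catalog.tsv"
    comm_hash = _sha(_file_sha(stream_path), f"window={cfg.observation_window}", f"membership={cfg.membership}")
    catalog = None
    if manifest.fresh("communities", comm_hash, [cand_path, catalog_path]):
        logger.info("stage communities: cache hit")
        with open(cand_path) as fh:
            candidates = comm_mod.read_candidates(fh)
    else:
        try:
            catalog = comm_mod.run_stream(stream, observation_window=cfg.observation_window)
            candidates = comm_mod.collect_candidate_features(catalog, membership=cfg.membership)
        except Exception as exc:  # noqa: BLE001
            raise _stage_error("communities", exc) from exc
        with open(catalog_path, "w") as fh:
            comm_mod.write_catalog(catalog, fh)
        with open(cand_path, "w") as fh:
            comm_mod.write_candidates(candidates, fh)
        manifest.record("communities", comm_hash, [cand_path, catalog_path])
    logger.info("candidates=%d", len(candidates))

    # ---- stage: feature selection ----
    sel_paths = {
        "split": out / "split.json",
        "ranking": out / "ranking.tsv",
        "community": out / "community_features.tsv",
        "subcellular": out / "subcellular_features.tsv",
    }
    sel_hash = _sha(
        _file_sha(cand_path),
        _file_sha(a_paths["labels"]),
        _file_sha(a_paths["localization"]),
        json.dumps(
            [cfg.svm_C, cfg.svm_lam, cfg.svm_tol, cfg.k_communities, cfg.subcellular_top_n,
             cfg.subcellular_exclude_lo, cfg.subcellular_exclude_hi, cfg.train_fraction,
             cfg.stratified, cfg.seed]
        ),
    )
    nodes = dataset.nodes
    if manifest.fresh("select", sel_hash, list(sel_paths.values())):
        logger.info("stage select: cache hit")
        split = json.loads(sel_paths["split"].read_text())
        train_idx = np.asarray(split["train"], dtype=int)
        test_idx = np.asarray(split["test"], dtype=int)
        with open(sel_paths["ranking"]) as fh:
            ranking = fs_mod.read_ranking(fh)
        _, com_cols, X_com = io_mod.read_feature_matrix(open(sel_paths["community"]))
        selected = [int(c.split("_")[1]) for c in com_cols]
        _, terms, X_sub = io_mod.read_feature_matrix(open(sel_paths["subcellular"]))
    else:
        try:
            train_idx, test_idx, ranking, selected, X_com, X_sub, terms = _split_and_select(
                dataset, candidates, cfg
            )
        except Exception as exc:  # noqa: BLE001
            raise _stage_error("select", exc) from exc
        sel_paths["split"].write_text(
            json.dumps({"train": train_idx.tolist(), "test": test_idx.tolist()})
        )
        with open(sel_paths["ranking"], "w") as fh:
            fs_mod.write_ranking(ranking, fh)
        with open(sel_paths["community"], "w") as fh:
            io_mod.write_feature_matrix(nodes, [f"com_{j}" for j in selected], X_com, fh)
        with open(sel_paths["subcellular"], "w") as fh:
            io_mod.write_feature_matrix(nodes, terms, X_sub, fh)
        manifest.record("select", sel_hash, list(sel_paths.values()))
    logger.info("selected_communities=%d subcellular_terms=%d", len(selected), len(terms))

    # ---- stage: train ----
    model_path = out / "model.json"
    train_hash = _sha(
        _file_sha(sel_paths["community"]),
        _file_sha(sel_paths["subcellular"]),
        _file_sha(sel_paths["split"]),
        json.dumps(
            [list(cfg.community_hidden), list(cfg.subcellular_hidden), list(cfg.head_hidden),
             cfg.learning_rate, cfg.epochs, cfg.min_epochs, cfg.coverage_P, cfg.seed]
        ),
    )
    y = dataset.labels
    if manifest.fresh("train", train_hash, [model_path]):
        logger.info("stage train: cache hit")
        with open(model_path) as fh:
            model = clf_mod.load_model(fh)
    else:
        try:
            model = clf_mod.train_model(
                X_com[train_idx],
                X_sub[train_idx],
                y[train_idx],
                spec=clf_mod.ModelSpec(cfg.community_hidden, cfg.subcellular_hidden, cfg.head_hidden),
                cfg=clf_mod.TrainConfig(
                    epochs=cfg.epochs,
                    learning_rate=cfg.learning_rate,
                    seed=cfg.seed,
                    coverage_P=cfg.coverage_P,
                    min_epochs=cfg.min_epochs,
                ),
            )
        except Exception as exc:  # noqa: BLE001
            raise _stage_error("train", exc) from exc
        with open(model_path, "w") as fh:
            clf_mod.save_model(model, fh)
        manifest.record("train", train_hash, [model_path])

    # ---- stage: evaluate ----
    pred_path = out / "predictions.tsv"
    report_path = out / "report.tsv"
    eval_hash = _sha(train_hash, _file_sha(model_path))
    X_all = np.hstack([X_com, X_sub])
    try:
        pred = clf_mod.predict_scores(model, X_all[test_idx], [nodes[i] for i in test_idx])
        report = eval_mod.compute_metrics(y[test_idx], pred.scores)
    except Exception as exc:  # noqa: BLE001
        raise _stage_error("evaluate", exc) from exc
    if not manifest.fresh("evaluate", eval_hash, [pred_path, report_path]):
        with open(pred_path, "w") as fh:
            io_mod.write_predictions(pred.proteins, pred.scores, pred.labels, fh)
        with open(report_path, "w") as fh:
            eval_mod.write_report({"COM+SUB": report}, fh)
        manifest.record("evaluate", eval_hash, [pred_path, report_path])
    else:
        logger.info("stage evaluate: cache hit")

    return PipelineResult(
        dataset=dataset,
        dynamic=dynamic,
        stream=stream,
        candidates=candidates,
        ranking=ranking,
        selected=list(selected),
        community_features=X_com,
        subcellular_features=X_sub,
        subcellular_terms=list(terms),
        train_idx=train_idx,
        test_idx=test_idx,
        model=model,
        prediction=pred,
        report=report,
        catalog=catalog,
    )


def _load_aligned(paths: dict[str, Path]) -> io_mod.AlignedDataset:
    with open(paths["network"]) as fh:
        network = io_mod.read_ppi_edge_list(fh)
    with open(paths["expression"]) as fh:
        expression = io_mod.read_expression_matrix(fh)
    with open(paths["localization"]) as fh:
        localization = io_mod.read_localization_table(fh)
    with open(paths["labels"]) as fh:
        labels = io_mod.read_label_list(fh)
    return io_mod.align_dataset(network, expression, localization, labels)
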
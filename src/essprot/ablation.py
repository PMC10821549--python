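"""Ablation harnesses: per-branch feature contributions and snapshot detachment.

``ablate_branches`` retrains the classifier three times on one fixed
split/seed — community features only, subcellular features only, both — to
measure what each feature family contributes. ``detach_snapshot`` removes one
snapshot from the dynamic network, rebuilds the stream, communities and
features, retrains with unchanged parameters, and evaluates; sweeping all
timepoints shows whether any single network state is dispensable.
"""

from __future__ import annotations

import numpy as np

from . import classifier as clf_mod
from . import dynamics as dyn_mod
from . import evaluation as eval_mod
from .io import AlignedDataset
from .pipeline import PipelineConfig, run_stages, _split_and_select

__all__ = ["ablate_branches", "detach_snapshot", "detach_sweep"]


def ablate_branches(
    dataset: AlignedDataset, cfg: PipelineConfig | None = None
) -> dict[str, eval_mod.MetricReport]:
    """Train COM-only, SUB-only and COM+SUB variants on the identical split."""
    cfg = cfg or PipelineConfig()
    profiles = dyn_mod.compute_activity_profiles(dataset)
    dynamic = dyn_mod.build_snapshots(dataset, profiles, cfg.first_snapshot_static)
    stream = dyn_mod.build_stream(dynamic)
    from . import communities as comm_mod

    catalog = comm_mod.run_stream(stream, observation_window=cfg.observation_window)
    candidates = comm_mod.collect_candidate_features(catalog, membership=cfg.membership)
    train_idx, test_idx, _, _, X_com, X_sub, _ = _split_and_select(dataset, candidates, cfg)
    y = dataset.labels
    spec = clf_mod.ModelSpec(cfg.community_hidden, cfg.subcellular_hidden, cfg.head_hidden)
    tcfg = clf_mod.TrainConfig(
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        seed=cfg.seed,
        coverage_P=cfg.coverage_P,
        min_epochs=cfg.min_epochs,
    )
    empty = np.zeros((len(y), 0))
    variants = {
        "COM": (X_com, empty),
        "SUB": (empty, X_sub),
        "COM+SUB": (X_com, X_sub),
    }
    reports: dict[str, eval_mod.MetricReport] = {}
    for name, (Xc, Xs) in variants.items():
        model = clf_mod.train_model(Xc[train_idx], Xs[train_idx], y[train_idx], spec=spec, cfg=tcfg)
        X_all = np.hstack([Xc, Xs])
        scores = model.predict_proba(X_all[test_idx])[:, 1]
        reports[name] = eval_mod.compute_metrics(y[test_idx], scores)
    return reports


def detach_snapshot(
    dataset: AlignedDataset, t: int, cfg: PipelineConfig | None = None
) -> eval_mod.MetricReport:
    """Drop snapshot ``t`` (1-based), rerun the full pipeline, evaluate."""
    cfg = cfg or PipelineConfig()
    profiles = dyn_mod.compute_activity_profiles(dataset)
    dynamic = dyn_mod.build_snapshots(dataset, profiles, cfg.first_snapshot_static)
    T = dynamic.n_timesteps
    if T < 3:
        raise ValueError("snapshot detachment needs at least 3 timesteps")
    if not 1 <= t <= T:
        raise ValueError(f"t must be in [1, {T}]")
    snaps = tuple(s for i, s in enumerate(dynamic.snapshots, start=1) if i != t)
    reduced = dyn_mod.DynamicNetwork(static=dynamic.static, snapshots=snaps)
    result = run_stages(dataset, cfg, dynamic=reduced)
    return result.report


def detach_sweep(
    dataset: AlignedDataset, cfg: PipelineConfig | None = None
) -> dict[str, eval_mod.MetricReport]:
    """Detach each snapshot in turn; keys are 'detach-T<t>'."""
    cfg = cfg or PipelineConfig()
    T = dataset.expression.n_timepoints
    return {f"detach-T{t}": detach_snapshot(dataset, t, cfg) for t in range(1, T + 1)}
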
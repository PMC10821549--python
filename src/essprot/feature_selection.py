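"""Feature selection: linear SVM-RFE over community features, and the
rank-filtered subcellular-localization feature matrix.

The SVM solves the soft-margin dual

    min_alpha  (1/2) sum_hk y_h y_k alpha_h alpha_k (x_h . x_k + lam * d_hk)
               - sum_k alpha_k
    s.t.       0 <= alpha_k <= C,   sum_k alpha_k y_k = 0

(d_hk the Kronecker delta; lam a tiny ridge keeping the kernel
well-conditioned). The weight vector is w = sum_k alpha_k y_k x_k. RFE
repeatedly trains on the surviving features, scores each feature i by
c_i = w_i^2, and removes the argmin (ties broken by smallest column index)
until no feature remains; features are ranked best-first by reverse removal
order.

Subcellular localization terms are ranked by annotated-protein count
(descending, ties lexicographic); of the top 1024 terms, ranks 11-64 are
excluded (their contribution is marginal), leaving at most 970 binary
columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.svm import SVC

from .io import LocalizationTable

logger = logging.getLogger(__name__)

__all__ = [
    "SvmConfig",
    "SvmModel",
    "RfeRanking",
    "SubcellularFeatureSpec",
    "LinearSvmRfe",
    "train_linear_svm",
    "kkt_residual",
    "rfe_rank",
    "select_top_communities",
    "rank_localization_terms",
    "subcellular_features",
    "write_ranking",
    "read_ranking",
]


@dataclass(frozen=True)
class SvmConfig:
    """Soft-margin bound C, kernel-diagonal ridge lam, solver tolerance."""

    C: float = 1.0
    lam: float = 1e-6
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")


@dataclass(frozen=True)
class SvmModel:
    """Dual coefficients, primal weight vector and bias of a trained SVM."""

    alpha: np.ndarray  # per-sample dual coefficients in [0, C]
    w: np.ndarray  # one weight per feature
    bias: float


@dataclass(frozen=True)
class RfeRanking:
    """Full feature ordering (best first) with per-round criteria and traces."""

    ranked: tuple[int, ...]
    criteria_history: tuple[tuple[float, ...], ...]
    surviving_trace: tuple[tuple[int, ...], ...]
    removal_criteria: tuple[float, ...] = field(default=())  # c at removal, worst-first


def train_linear_svm(X: np.ndarray, y: np.ndarray, cfg: SvmConfig | None = None) -> SvmModel:
    """Train the linear soft-margin SVM on samples X and labels y in {-1, +1}.

    The dual above is solved exactly by libsvm on the precomputed kernel
    K = X X^T + lam * I; this function assembles the kernel, recovers the
    full dual-coefficient vector and builds w = sum alpha_k y_k x_k.
    """
    cfg = cfg or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D sample x feature matrix")
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("y must contain both classes, encoded as -1/+1")
    K = X @ X.T + cfg.lam * np.eye(X.shape[0])
    # libsvm's stopping rule bounds the KKT gradient violation by its tol,
    # which tracks (but does not strictly bound) the margin residual we
    # verify; refine with a tighter solver tolerance in the rare case the
    # first solve leaves a residual above cfg.tol
    model: SvmModel | None = None
    for solver_tol in (cfg.tol, cfg.tol / 10.0, cfg.tol / 100.0):
        svc = SVC(C=cfg.C, kernel="precomputed", tol=solver_tol, shrinking=False)
        svc.fit(K, y)
        if getattr(svc, "fit_status_", 0) != 0:
            raise RuntimeError("SVM solver did not converge")
        alpha = np.zeros(X.shape[0])
        # dual_coef_ holds alpha_k * y_k for support vectors
        alpha[svc.support_] = np.abs(svc.dual_coef_.ravel())
        w = X.T @ (alpha * y)
        model = SvmModel(alpha=alpha, w=w, bias=float(svc.intercept_[0]))
        if kkt_residual(model, X, y, cfg) <= cfg.tol:
            break
    assert model is not None
    return model


def kkt_residual(model: SvmModel, X: np.ndarray, y: np.ndarray, cfg: SvmConfig | None = None) -> float:
    """Maximum violation of the dual's KKT conditions.

    Checks the box constraint, the equality constraint sum alpha_k y_k = 0,
    and the complementary-slackness margins: y_k f(x_k) >= 1 for alpha = 0,
    <= 1 for alpha = C, and = 1 for marginal support vectors, where f uses
    the ridge-perturbed kernel.
    """
    cfg = cfg or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    a = model.alpha
    K = X @ X.T + cfg.lam * np.eye(X.shape[0])
    f = K @ (a * y) + model.bias
    margins = y * f
    res = max(0.0, float(np.max(-a)), float(np.max(a - cfg.C)))
    res = max(res, abs(float(np.sum(a * y))))
    eps = 1e-9 * max(1.0, cfg.C)
    at_lower = a <= eps
    at_upper = a >= cfg.C - eps
    free = ~(at_lower | at_upper)
    if at_lower.any():
        res = max(res, float(np.max(1.0 - margins[at_lower])))
    if at_upper.any():
        res = max(res, float(np.max(margins[at_upper] - 1.0)))
    if free.any():
        res = max(res, float(np.max(np.abs(margins[free] - 1.0))))
    return res


class LinearSvmRfe(BaseEstimator):
    """Recursive feature elimination driven by squared linear-SVM weights.

    Parameters
    ----------
    C, lam, tol
        Soft-margin bound, kernel ridge and solver tolerance of the SVM
        trained each round.
    step
        Features removed per round. The default (1) is the faithful
        one-at-a-time elimination; larger chunks are an explicit speed
        option that changes the ranking.

    Attributes
    ----------
    ranking_ : tuple of int
        Feature indices, best first.
    criteria_history_ : tuple of tuple of float
        Per-round criterion vector c_i = w_i^2 over the surviving set.
    surviving_trace_ : tuple of tuple of int
        The surviving feature-index set at the start of each round.
    """

    def __init__(self, C: float = 1.0, lam: float = 1e-6, tol: float = 1e-6, step: int = 1):
        self.C = C
        self.lam = lam
        self.tol = tol
        self.step = step

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSvmRfe":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must have at least one feature")
        yy = np.where(y > 0, 1.0, -1.0)
        if len(set(yy)) < 2:
            raise ValueError("both classes must be present")
        cfg = SvmConfig(C=self.C, lam=self.lam, tol=self.tol)
        surviving = list(range(X.shape[1]))
        removed: list[int] = []  # worst first
        removal_crit: list[float] = []
        criteria_hist: list[tuple[float, ...]] = []
        surviving_trace: list[tuple[int, ...]] = []
        round_no = 0
        while surviving:
            round_no += 1
            surviving_trace.append(tuple(surviving))
            try:
                model = train_linear_svm(X[:, surviving], yy, cfg)
            except Exception as exc:  # noqa: BLE001 - annotate the round
                raise RuntimeError(f"SVM training failed in RFE round {round_no}") from exc
            c = model.w**2
            criteria_hist.append(tuple(float(v) for v in c))
            k = min(self.step, len(surviving))
            for _ in range(k):
                j = int(np.argmin(c))  # argmin; ties -> smallest column index
                removed.append(surviving[j])
                removal_crit.append(float(c[j]))
                del surviving[j]
                c = np.delete(c, j)
                if c.size == 0:
                    break
        self.ranking_ = tuple(reversed(removed))
        self.criteria_history_ = tuple(criteria_hist)
        self.surviving_trace_ = tuple(surviving_trace)
        self.removal_criteria_ = tuple(removal_crit)
        self.n_features_in_ = X.shape[1]
        return self

    def to_ranking(self) -> RfeRanking:
        return RfeRanking(
            ranked=self.ranking_,
            criteria_history=self.criteria_history_,
            surviving_trace=self.surviving_trace_,
            removal_criteria=self.removal_criteria_,
        )


def rfe_rank(X: np.ndarray, y: np.ndarray, cfg: SvmConfig | None = None) -> RfeRanking:
    """Rank all features of X best-first by SVM-RFE (one removal per round)."""
    cfg = cfg or SvmConfig()
    return LinearSvmRfe(C=cfg.C, lam=cfg.lam, tol=cfg.tol).fit(X, y).to_ranking()


def select_top_communities(ranking: RfeRanking, k: int = 64) -> list[int]:
    """First k ranked features, returned in original column order.

    If fewer than k features exist, all are returned with a warning.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if k > len(ranking.ranked):
        warnings.warn(
            f"requested {k} features but only {len(ranking.ranked)} exist; returning all",
            stacklevel=2,
        )
        k = len(ranking.ranked)
    return sorted(ranking.ranked[:k])


@dataclass(frozen=True)
class SubcellularFeatureSpec:
    """Top-N term selection with the low-contribution rank band removed."""

    top_n: int = 1024
    exclude_lo: int = 11
    exclude_hi: int = 64

    def retained_ranks(self, n_terms: int) -> list[int]:
        top = min(self.top_n, n_terms)
        return [r for r in range(1, top + 1) if not (self.exclude_lo <= r <= self.exclude_hi)]


def rank_localization_terms(table: LocalizationTable, proteins: Sequence[str]) -> list[str]:
    """Terms ordered by annotated-protein count descending, ties lexicographic."""
    universe = set(proteins)
    counts: dict[str, int] = {}
    for p, t in table.records:
        if p in universe:
            counts[t] = counts.get(t, 0) + 1
    return sorted(counts, key=lambda t: (-counts[t], t))


def subcellular_features(
    table: LocalizationTable,
    proteins: Sequence[str],
    spec: SubcellularFeatureSpec | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Binary protein x term matrix over the retained term ranks.

    Returns the matrix and the retained terms in rank order. Fewer terms
    than the cutoffs simply yield fewer columns (logged, not an error).
    """
    spec = spec or SubcellularFeatureSpec()
    ordered = rank_localization_terms(table, proteins)
    ranks = spec.retained_ranks(len(ordered))
    terms = [ordered[r - 1] for r in ranks]
    if len(terms) < spec.top_n - (spec.exclude_hi - spec.exclude_lo + 1):
        logger.info("only %d localization terms available after rank filtering", len(terms))
    annotations: dict[str, set[str]] = {}
    for p, t in table.records:
        annotations.setdefault(p, set()).add(t)
    mat = np.zeros((len(proteins), len(terms)), dtype=float)
    for i, p in enumerate(proteins):
        ann = annotations.get(p)
        if not ann:
            continue
        for j, t in enumerate(terms):
            if t in ann:
                mat[i, j] = 1.0
    return mat, terms


def write_ranking(ranking: RfeRanking, sink: IO[str]) -> None:
    """TSV "rank  feature_index  criterion_at_removal" (rank 1 = best)."""
    sink.write("rank\tfeature_index\tcriterion_at_removal\n")
    n = len(ranking.ranked)
    crit_by_feature = {}
    for pos, feat in enumerate(reversed(ranking.ranked)):  # worst-first order
        crit_by_feature[feat] = ranking.removal_criteria[pos] if ranking.removal_criteria else float("nan")
    for rank, feat in enumerate(ranking.ranked, start=1):
        sink.write(f"{rank}\t{feat}\t{crit_by_feature[feat]:.10g}\n")
    assert n == len(crit_by_feature)


def read_ranking(source: IO[str]) -> RfeRanking:
    ranked: list[int] = []
    crits: list[float] = []
    header = True
    for line in source:
        line = line.rstrip("\n")
        if header:
            header = False
            continue
        if not line:
            continue
        _, feat, crit = line.split("\t")
        ranked.append(int(feat))
        crits.append(float(crit))
    return RfeRanking(
        ranked=tuple(ranked),
        criteria_history=(),
        surviving_trace=(),
        removal_criteria=tuple(reversed(crits)),
    )
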
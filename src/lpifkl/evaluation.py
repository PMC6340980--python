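"""Cross-validation protocols, regulariser grid search, and ranking metrics.

Two evaluation protocols are provided:

* 5-fold cross-validation over the positive pairs: each fold's positives are
  masked to 0 in the training view, the interaction-profile kernels and the
  fusion weights are rebuilt from the masked matrix, and the masked positives
  are scored against every never-interacting pair.
* local leave-one-protein-out: one protein's entire interaction column is
  masked, the model retrained, and the column scored over all lncRNAs.

Metrics are AUPR (trapezoidal precision–recall integration) and AUC
(Mann–Whitney with ties counted 1/2); AUPR is the headline number because
true interactions are sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import InteractionMatrix
from .fastkl import FastKLFusion, KernelBank, build_target, fuse
from .krr import KroneckerKernelRidge
from .pipeline import LPIDataset, PipelineConfig, build_banks, build_static_kernels

SINGLE_KERNEL_CHOICES = ("GIP", "SW", "SF", "EXP_GO")
KERNEL_CHOICES = SINGLE_KERNEL_CHOICES + ("mean", "fastkl")


@dataclass(frozen=True)
class FoldPlan:
    """Seeded partition of the positive pairs into near-equal folds."""

    n_folds: int = 5
    seed: int = 0

    def assign(self, positives: list[tuple[int, int]]) -> dict[tuple[int, int], int]:
        if len(positives) < self.n_folds:
            raise ValueError(
                f"{len(positives)} positive pairs cannot fill {self.n_folds} folds"
            )
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(positives))
        return {positives[int(k)]: int(i % self.n_folds) for i, k in enumerate(order)}


@dataclass
class EvaluationReport:
    aupr: float
    auc: float
    per_fold: list[tuple[float, float]]
    pooled_scores: list[tuple[tuple[int, int], float, int]]
    weights_lnc: list[np.ndarray] = field(default_factory=list)
    weights_pro: list[np.ndarray] = field(default_factory=list)


@dataclass(frozen=True)
class GridSpec:
    """Candidate regulariser grids; selection criterion is pooled AUPR."""

    lambda_l_grid: tuple[float, ...]
    lambda_p_grid: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.lambda_l_grid or not self.lambda_p_grid:
            raise ValueError("grids must be non-empty")
        if min(self.lambda_l_grid) <= 0 or min(self.lambda_p_grid) <= 0:
            raise ValueError("all regulariser candidates must be positive")


def default_grid() -> GridSpec:
    """Logarithmic 2^-7..2^7 grid on both regularisers."""
    vals = tuple(float(2.0**e) for e in range(-7, 8))
    return GridSpec(vals, vals)


def aupr_auc(scores, labels=None) -> tuple[float, float]:
    """(AUPR, AUC) for a pooled score list.

    Accepts either ``aupr_auc(list_of_(score, label))`` or two parallel arrays.
    AUC is the Mann–Whitney statistic with tied score pairs counted 1/2; AUPR
    integrates the precision–recall curve trapezoidally across all distinct
    thresholds, anchoring recall=0 at the precision of the highest threshold.
    """
    if labels is None:
        pairs = list(scores)
        s = np.array([p[-2] for p in pairs], dtype=float)
        y = np.array([p[-1] for p in pairs], dtype=int)
    else:
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels, dtype=int)
    P = int((y == 1).sum())
    N = int((y == 0).sum())
    if P == 0 or N == 0:
        raise ValueError("need at least one positive and one negative")

    # AUC via midranks (ties = 1/2)
    from scipy.stats import rankdata

    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - P * (P + 1) / 2.0) / (P * N)

    # PR sweep over distinct thresholds, descending
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted == 1)
    k = np.arange(1, len(s) + 1)
    # last index of each distinct threshold block
    boundary = np.nonzero(np.diff(s_sorted, append=-np.inf) != 0)[0]
    recall = tp[boundary] / P
    precision = tp[boundary] / k[boundary]
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    aupr = float(np.trapezoid(precision, recall))
    return aupr, float(auc)


def _fuse_for_choice(
    bank_l: KernelBank,
    bank_p: KernelBank,
    F_view: np.ndarray,
    config: PipelineConfig,
    choice: str,
):
    """Fused (K_lnc, K_pro, w_lnc, w_pro) for one kernel-selection strategy."""
    if choice == "fastkl":
        fus_l = FastKLFusion(config.fastkl_lambda, config.project_simplex)
        fus_p = FastKLFusion(config.fastkl_lambda, config.project_simplex)
        K_l = fus_l.fit_transform(bank_l, build_target(F_view, "lnc"))
        K_p = fus_p.fit_transform(bank_p, build_target(F_view, "pro"))
        return K_l.values, K_p.values, fus_l.weights_, fus_p.weights_
    if choice == "mean":
        w_l = np.full(bank_l.J, 1.0 / bank_l.J)
        w_p = np.full(bank_p.J, 1.0 / bank_p.J)
        return fuse(bank_l, w_l).values, fuse(bank_p, w_p).values, w_l, w_p
    if choice in SINGLE_KERNEL_CHOICES:
        name_l = "EXP" if choice == "EXP_GO" else choice
        name_p = "GO" if choice == "EXP_GO" else choice
        w_l = np.array([1.0 if k.name == name_l else 0.0 for k in bank_l.kernels])
        w_p = np.array([1.0 if k.name == name_p else 0.0 for k in bank_p.kernels])
        if w_l.sum() != 1.0 or w_p.sum() != 1.0:
            raise ValueError(f"kernel {choice!r} not present in the bank")
        return fuse(bank_l, w_l).values, fuse(bank_p, w_p).values, w_l, w_p
    raise ValueError(f"unknown kernel choice {choice!r}")


def cross_validate(
    dataset: LPIDataset,
    folds: FoldPlan | None = None,
    config: PipelineConfig | None = None,
    kernel_choice: str = "fastkl",
    static=None,
) -> EvaluationReport:
    """Masked 5-fold CV: per fold, rebuild interaction kernels and fusion
    weights from the fold's training view, fit, and score the held-out
    positives against all never-interacting pairs."""
    folds = folds or FoldPlan()
    config = config or PipelineConfig()
    F = dataset.interactions
    positives = F.positive_pairs()
    assignment = folds.assign(positives)
    static_l, static_p = static if static is not None else build_static_kernels(dataset, config)
    negatives = [
        (int(i), int(j)) for i, j in zip(*np.nonzero(F.values == 0.0))
    ]

    pooled: list[tuple[tuple[int, int], float, int]] = []
    per_fold: list[tuple[float, float]] = []
    weights_l, weights_p = [], []
    for f in range(folds.n_folds):
        fold_pairs = [p for p, g in assignment.items() if g == f]
        if not fold_pairs:
            raise ValueError(f"fold {f} holds no positive pairs")
        F_masked = F.with_mask(fold_pairs)
        bank_l, bank_p = build_banks(F_masked, static_l, static_p, config)
        K_l, K_p, w_l, w_p = _fuse_for_choice(
            bank_l, bank_p, F_masked.train_view(), config, kernel_choice
        )
        weights_l.append(w_l)
        weights_p.append(w_p)
        model = KroneckerKernelRidge(config.lambda_l, config.lambda_p).fit(
            K_l, K_p, F_masked.train_view()
        )
        F_star = model.predict()
        fold_scores = [((i, j), float(F_star[i, j]), 1) for i, j in fold_pairs]
        fold_scores += [((i, j), float(F_star[i, j]), 0) for i, j in negatives]
        per_fold.append(aupr_auc(fold_scores))
        pooled.extend(fold_scores)

    aupr, auc = aupr_auc(pooled)
    return EvaluationReport(aupr, auc, per_fold, pooled, weights_l, weights_p)


def local_loocv(
    dataset: LPIDataset,
    config: PipelineConfig | None = None,
    kernel_choice: str = "fastkl",
    static=None,
) -> EvaluationReport:
    """Leave-one-protein-out: mask one protein's whole column, retrain, score
    that column over all lncRNAs; pool (score, label) across proteins."""
    config = config or PipelineConfig()
    F = dataset.interactions
    m, n = F.values.shape
    if n < 2:
        raise ValueError("local LOOCV needs at least 2 proteins")
    static_l, static_p = static if static is not None else build_static_kernels(dataset, config)

    pooled: list[tuple[tuple[int, int], float, int]] = []
    per_protein: list[tuple[float, float]] = []
    rankings: list[list[tuple[int, int, float]]] = []
    for j in range(n):
        col_pairs = [(i, j) for i in range(m)]
        F_masked = F.with_mask(col_pairs)
        if not F_masked.train_view().any():
            raise ValueError("masking this protein leaves no training signal")
        bank_l, bank_p = build_banks(F_masked, static_l, static_p, config)
        K_l, K_p, _, _ = _fuse_for_choice(
            bank_l, bank_p, F_masked.train_view(), config, kernel_choice
        )
        model = KroneckerKernelRidge(config.lambda_l, config.lambda_p).fit(
            K_l, K_p, F_masked.train_view()
        )
        col = model.predict()[:, j]
        labels = F.values[:, j].astype(int)
        pooled.extend(((i, j), float(col[i]), int(labels[i])) for i in range(m))
        if 0 < labels.sum() < m:
            per_protein.append(aupr_auc(list(zip(col, labels))))
        order = np.argsort(-col, kind="stable")
        rankings.append([(int(i), j, float(col[i])) for i in order])

    aupr, auc = aupr_auc(pooled)
    report = EvaluationReport(aupr, auc, per_protein, pooled)
    report.rankings = rankings
    return report


def grid_search(
    dataset: LPIDataset,
    grid: GridSpec | None = None,
    folds: FoldPlan | None = None,
    config: PipelineConfig | None = None,
    kernel_choice: str = "fastkl",
) -> tuple[tuple[float, float], list[tuple[float, float, float, float]]]:
    """Pick (lambda_l, lambda_p) maximising pooled CV AUPR.

    Kernel fusion and the two eigendecompositions are done once per fold and
    reused across the whole grid; ties break toward the smaller lambda_l,
    then the smaller lambda_p, independent of grid ordering.
    Returns ((best_lambda_l, best_lambda_p), [(ll, lp, aupr, auc), ...]).
    """
    grid = grid or default_grid()
    folds = folds or FoldPlan()
    config = config or PipelineConfig()
    F = dataset.interactions
    positives = F.positive_pairs()
    assignment = folds.assign(positives)
    static_l, static_p = build_static_kernels(dataset, config)
    negatives = [(int(i), int(j)) for i, j in zip(*np.nonzero(F.values == 0.0))]

    fold_models = []
    for f in range(folds.n_folds):
        fold_pairs = [p for p, g in assignment.items() if g == f]
        F_masked = F.with_mask(fold_pairs)
        bank_l, bank_p = build_banks(F_masked, static_l, static_p, config)
        K_l, K_p, _, _ = _fuse_for_choice(
            bank_l, bank_p, F_masked.train_view(), config, kernel_choice
        )
        model = KroneckerKernelRidge().fit(K_l, K_p, F_masked.train_view())
        fold_models.append((fold_pairs, model))

    results = []
    for ll in grid.lambda_l_grid:
        for lp in grid.lambda_p_grid:
            pooled = []
            for fold_pairs, model in fold_models:
                model.set_params(lambda_l=ll, lambda_p=lp)
                F_star = model.predict()
                pooled += [(float(F_star[i, j]), 1) for i, j in fold_pairs]
                pooled += [(float(F_star[i, j]), 0) for i, j in negatives]
            aupr, auc = aupr_auc(pooled)
            results.append((float(ll), float(lp), aupr, auc))
    best = min(results, key=lambda r: (-r[2], r[0], r[1]))
    return (best[0], best[1]), results
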
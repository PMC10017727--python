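"""Cross-validated evaluation: RMSE/CC metrics, repeated nested CV with
stage-stratified folds, ROI ranking by averaged weights, genome-wide SNP
screening, and fixed-hyperparameter sensitivity grids.

Hyperparameters are selected by inner k-fold CV on each outer training part,
minimising the mean inner-test RMSE (averaged across modalities for the
multi-task variants), so no information from an outer test fold ever touches
model selection or standardization.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    VARIANTS,
    ModelFit,
    MultiModalDataset,
    RegularizationConfig,
    fit,
    predict,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "CVResult",
    "ScreenResult",
    "compute_metrics",
    "stratified_folds",
    "nested_cv",
    "rank_rois",
    "screen_snps",
    "sensitivity_grid",
]

#: half-decade ladder 1e-5, 3e-5, ..., 1, 3 used for both lambda1 and lambda2
DEFAULT_LAMBDA_GRID = tuple(
    float(f"{b}e{e}") for e in range(-5, 1) for b in (1, 3)
)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Root-mean-squared error and Pearson correlation of predictions.

    A zero-variance prediction vector has undefined correlation; it is
    reported as cc = 0.0 (degenerate, logged) rather than NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    if len(y_true) < 2:
        raise ValueError("need at least two observations")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        logger.debug("degenerate (constant) vector in correlation; cc set to 0")
        cc = 0.0
    else:
        cc = float(np.corrcoef(y_true, y_pred)[0, 1])
    return rmse, cc


def stratified_folds(
    stages: Sequence[str], k: int, seed: int
) -> list[np.ndarray]:
    """k disjoint test-index arrays, stratified by stage label.

    Subjects of each stage are shuffled and dealt round-robin so every fold
    gets a near-equal share of every stage.
    """
    stages = np.asarray(stages, dtype=object)
    n = len(stages)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for lab in sorted(set(stages)):
        idx = np.flatnonzero(stages == lab)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[(pos + offset) % k].append(int(i))
        offset += len(idx)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class CVResult:
    """Metrics and averaged weights from repeated nested cross-validation."""

    metrics: pd.DataFrame            # repeat, fold, modality, split, rmse, cc
    selected: pd.DataFrame           # repeat, fold, lambda1, lambda2
    mean_abs_weights: pd.DataFrame   # rows = ROI names, cols = modalities, |w| averaged
    mean_weights: pd.DataFrame       # signed average of the same weights
    fold_assignments: list[list[np.ndarray]]
    fold_weights: list[np.ndarray]   # refit W per (repeat, fold), in fit order
    variant: str
    seeds: list[int]

    def summary(self, split: str = "test") -> pd.DataFrame:
        """Mean +/- sd of RMSE and CC per modality over repeats x folds."""
        sub = self.metrics[self.metrics["split"] == split]
        return sub.groupby("modality")[["rmse", "cc"]].agg(["mean", "std"])


def _fit_eval(
    train: MultiModalDataset,
    test: MultiModalDataset,
    cfg: RegularizationConfig,
) -> tuple[ModelFit, list[tuple[float, float]], list[tuple[float, float]]]:
    model = fit(train, cfg=cfg)
    tr_pred = predict(model, train.X)
    te_pred = predict(model, test.X)
    tr = [compute_metrics(train.y, p) for p in tr_pred]
    te = [compute_metrics(test.y, p) for p in te_pred]
    return model, tr, te


def _select_lambdas(
    train: MultiModalDataset,
    k: int,
    grid1: Sequence[float],
    grid2: Sequence[float],
    variant: str,
    seed: int,
    max_iter: int,
    tol: float,
) -> tuple[float, float]:
    """Inner k-fold CV on the training part; pick the (lambda1, lambda2)
    minimising mean inner-test RMSE (averaged over modalities)."""
    folds = stratified_folds(train.stages, k, seed)
    all_idx = np.arange(train.n_subjects)
    use_lap = VARIANTS[variant][1]
    combos = list(itertools.product(grid1, grid2 if use_lap else [0.0]))
    scores = np.zeros(len(combos))
    counts = np.zeros(len(combos))
    for f, test_idx in enumerate(folds):
        tr_idx = np.setdiff1d(all_idx, test_idx)
        inner_tr = train.subset(tr_idx)
        inner_te = train.subset(test_idx)
        for c, (l1, l2) in enumerate(combos):
            cfg = RegularizationConfig(lambda1=l1, lambda2=l2, variant=variant,
                                       max_iter=max_iter, tol=tol)
            try:
                _, _, te = _fit_eval(inner_tr, inner_te, cfg)
            except FloatingPointError:
                logger.warning("inner fit diverged at lambda=(%g, %g); skipped", l1, l2)
                continue
            scores[c] += float(np.mean([rmse for rmse, _ in te]))
            counts[c] += 1
    valid = counts > 0
    if not np.any(valid):
        raise RuntimeError("all inner-CV fits failed")
    mean_scores = np.where(valid, scores / np.maximum(counts, 1), np.inf)
    best = int(np.argmin(mean_scores))  # ties -> first (smallest lambdas first)
    return combos[best]


def nested_cv(
    data: MultiModalDataset,
    stages: Sequence[str] | None = None,
    variant: str = "MSD-MM",
    grid1: Sequence[float] = DEFAULT_LAMBDA_GRID,
    grid2: Sequence[float] | None = None,
    repeats: int = 5,
    k: int = 5,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> CVResult:
    """Repeated, stage-stratified, nested k-fold cross-validation.

    Each repeat r uses seed + r for its fold split.  Within every outer fold
    an inner k-fold CV on the training part selects (lambda1, lambda2) from
    the grids; the model is refit on the full outer-training part and scored
    on both splits per modality.  Weight magnitudes are averaged across all
    outer folds and repeats for ROI ranking.
    """
    if stages is not None:
        data = MultiModalDataset(
            X=data.X, y=data.y, stages=stages, roi_names=data.roi_names,
            modalities=data.modalities, standardized=data.standardized,
        )
    if data.n_subjects < 2 * k:
        raise ValueError("need at least 2*k subjects for nested CV")
    grid2 = tuple(grid2) if grid2 is not None else tuple(grid1)
    use_concat = VARIANTS[variant][0]
    fit_data = data.concatenated() if use_concat else data
    tags = list(fit_data.modalities)
    d_eff = fit_data.n_features

    rows, sel_rows, assignments, fold_weights = [], [], [], []
    w_abs_sum = np.zeros((d_eff, len(tags)))
    w_sum = np.zeros((d_eff, len(tags)))
    n_models = 0
    seeds = [seed + r for r in range(repeats)]
    all_idx = np.arange(data.n_subjects)

    for r, rseed in enumerate(seeds):
        folds = stratified_folds(data.stages, k, rseed)
        assignments.append(folds)
        for f, test_idx in enumerate(folds):
            tr_idx = np.setdiff1d(all_idx, test_idx)
            train, test = fit_data.subset(tr_idx), fit_data.subset(test_idx)
            l1, l2 = _select_lambdas(train, k, grid1, grid2, variant,
                                     seed=rseed * 1000 + f, max_iter=max_iter,
                                     tol=tol)
            cfg = RegularizationConfig(lambda1=l1, lambda2=l2, variant=variant,
                                       max_iter=max_iter, tol=tol)
            model, tr_m, te_m = _fit_eval(train, test, cfg)
            w_abs_sum += np.abs(model.W)
            w_sum += model.W
            fold_weights.append(model.W)
            n_models += 1
            sel_rows.append({"repeat": r, "fold": f, "lambda1": l1, "lambda2": l2})
            for m, tag in enumerate(tags):
                rows.append({"repeat": r, "fold": f, "modality": tag,
                             "split": "train", "rmse": tr_m[m][0], "cc": tr_m[m][1]})
                rows.append({"repeat": r, "fold": f, "modality": tag,
                             "split": "test", "rmse": te_m[m][0], "cc": te_m[m][1]})

    names = list(fit_data.roi_names)
    return CVResult(
        metrics=pd.DataFrame(rows),
        selected=pd.DataFrame(sel_rows),
        mean_abs_weights=pd.DataFrame(w_abs_sum / n_models, index=names, columns=tags),
        mean_weights=pd.DataFrame(w_sum / n_models, index=names, columns=tags),
        fold_assignments=assignments,
        fold_weights=fold_weights,
        variant=variant,
        seeds=seeds,
    )


def rank_rois(cv: CVResult, modality: str, top_k: int | None = None) -> pd.DataFrame:
    """ROIs ordered by cross-validation-averaged absolute weight.

    Returns a table with rank, ROI name, mean \\|weight\\| and signed mean
    weight.  Absolute values are used for ranking so that sign flips across
    folds cannot cancel a consistently selected ROI.
    """
    if modality not in cv.mean_abs_weights.columns:
        raise KeyError(
            f"unknown modality {modality!r}; have {list(cv.mean_abs_weights.columns)}"
        )
    w = cv.mean_abs_weights[modality]
    if top_k is None:
        top_k = len(w)
    if not 1 <= top_k <= len(w):
        raise ValueError(f"top_k must be in [1, {len(w)}]")
    order = w.sort_values(ascending=False, kind="stable").index[:top_k]
    return pd.DataFrame({
        "rank": np.arange(1, top_k + 1),
        "roi": order,
        "mean_abs_weight": w.loc[order].to_numpy(),
        "mean_weight": cv.mean_weights[modality].loc[order].to_numpy(),
    }).set_index("rank")


@dataclass
class ScreenResult:
    """Per-SNP cross-validated association strength."""

    table: pd.DataFrame            # snp, modality, cc_mean, cc_sd, rmse_mean
    skipped: list[str] = field(default_factory=list)

    def ranking(self) -> pd.DataFrame:
        """SNPs sorted by mean test CC averaged over modalities."""
        agg = (self.table.groupby("snp")["cc_mean"].mean()
               .sort_values(ascending=False))
        return agg.to_frame("cc_mean_overall")


def screen_snps(
    data: MultiModalDataset,
    genotypes: pd.DataFrame,
    variant: str = "MSD-MM",
    grid1: Sequence[float] = DEFAULT_LAMBDA_GRID,
    grid2: Sequence[float] | None = None,
    repeats: int = 5,
    k: int = 5,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ScreenResult:
    """Run the full nested-CV pipeline once per SNP column as the response.

    ``genotypes`` is an N x S table of additive codes (columns = SNP ids).
    SNPs with fewer than two distinct values are monomorphic in this sample
    and are skipped with a log entry.  Results report mean +/- sd test CC per
    modality, sorted by mean CC.
    """
    if genotypes.shape[0] != data.n_subjects:
        raise ValueError("genotype table rows must match the number of subjects")
    rows = []
    skipped: list[str] = []
    for snp in genotypes.columns:
        y = genotypes[snp].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            logger.info("SNP %s is monomorphic here; skipped", snp)
            skipped.append(str(snp))
            continue
        snp_data = MultiModalDataset(
            X=data.X, y=y, stages=data.stages, roi_names=data.roi_names,
            modalities=data.modalities, standardized=data.standardized,
        )
        cv = nested_cv(snp_data, variant=variant, grid1=grid1, grid2=grid2,
                       repeats=repeats, k=k, seed=seed, max_iter=max_iter, tol=tol)
        test = cv.metrics[cv.metrics["split"] == "test"]
        for tag, grp in test.groupby("modality"):
            rows.append({
                "snp": str(snp), "modality": tag,
                "cc_mean": float(grp["cc"].mean()),
                "cc_sd": float(grp["cc"].std(ddof=1)),
                "rmse_mean": float(grp["rmse"].mean()),
            })
    table = pd.DataFrame(rows)
    if not table.empty:
        order = (table.groupby("snp")["cc_mean"].transform("mean"))
        table = (table.assign(_o=order)
                 .sort_values(["_o", "snp", "modality"], ascending=[False, True, True])
                 .drop(columns="_o").reset_index(drop=True))
    return ScreenResult(table=table, skipped=skipped)


def sensitivity_grid(
    data: MultiModalDataset,
    variant: str = "MSD-MM",
    grid1: Sequence[float] = DEFAULT_LAMBDA_GRID,
    grid2: Sequence[float] = DEFAULT_LAMBDA_GRID,
    repeats: int = 1,
    k: int = 5,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> dict[str, pd.DataFrame]:
    """Mean test CC over a fixed (lambda1, lambda2) grid, per modality.

    Unlike :func:`nested_cv` there is no inner selection: every grid cell is
    evaluated by plain k-fold CV with those hyperparameters held fixed, which
    is what a parameter-sensitivity heat map shows.  Returns one
    len(grid1) x len(grid2) DataFrame per modality (rows indexed by lambda1).
    """
    use_concat = VARIANTS[variant][0]
    fit_data = data.concatenated() if use_concat else data
    tags = list(fit_data.modalities)
    out = {tag: pd.DataFrame(np.zeros((len(grid1), len(grid2))),
                             index=list(grid1), columns=list(grid2))
           for tag in tags}
    all_idx = np.arange(data.n_subjects)
    for i, l1 in enumerate(grid1):
        for j, l2 in enumerate(grid2):
            cfg = RegularizationConfig(lambda1=l1, lambda2=l2, variant=variant,
                                       max_iter=max_iter, tol=tol)
            ccs = {tag: [] for tag in tags}
            for r in range(repeats):
                folds = stratified_folds(data.stages, k, seed + r)
                for test_idx in folds:
                    tr_idx = np.setdiff1d(all_idx, test_idx)
                    _, _, te = _fit_eval(fit_data.subset(tr_idx),
                                         fit_data.subset(test_idx), cfg)
                    for m, tag in enumerate(tags):
                        ccs[tag].append(te[m][1])
            for tag in tags:
                out[tag].iloc[i, j] = float(np.mean(ccs[tag]))
    return out
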
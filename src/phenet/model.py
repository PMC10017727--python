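"""Diagnosis-aware multi-task group-sparse genotype association model.

The response y is an additively coded SNP (0/1/2).  Each of M phenotype
modalities contributes an N x d feature matrix X^m (d ROIs).  The model
estimates one coefficient vector w^m per modality by minimising

    F(W) = 1/2 sum_m ||y - X^m w^m||^2
         + lambda1 * sum_j ||w_j||_2                      (L2,1 row sparsity)
         + lambda2 * sum_m (w^m)' (X^m)' L^m X^m w^m      (stage Laplacian)

where w_j is the j-th row of W = [w^1 ... w^M] (the coefficients of ROI j
across modalities) and L^m is the graph Laplacian of the same-diagnosis-stage
similarity matrix.  The L2,1 term selects the *same* ROIs in every modality;
the Laplacian quadratic pulls predicted values of same-stage subjects
together.  The solver is an accelerated proximal-gradient (FISTA-type) scheme
with backtracking line search and a monotone function-value restart.

Ablation variants follow the usual naming: SM (single modality, lasso),
CM (concatenated modalities, lasso), MM (multi-task L2,1), each with an
"MSD-" prefix when the stage-Laplacian term is active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "STAGES",
    "VARIANTS",
    "MultiModalDataset",
    "StageGraph",
    "RegularizationConfig",
    "ModelFit",
    "build_similarity",
    "build_laplacian",
    "objective_value",
    "smooth_gradient",
    "prox_l21",
    "lambda_max",
    "fit",
    "predict",
]

STAGES = ("HC", "MD", "SD")

#: variant -> (uses concatenation, uses stage Laplacian)
VARIANTS = {
    "SM": (False, False),
    "MSD-SM": (False, True),
    "CM": (True, False),
    "MSD-CM": (True, True),
    "MM": (False, False),
    "MSD-MM": (False, True),
}


@dataclass
class MultiModalDataset:
    """Aligned per-subject feature matrices, genotype and diagnosis stages.

    Parameters
    ----------
    X : list of ndarray
        M matrices, each N subjects x d features, same shape.
    y : ndarray
        Length-N additive genotype codes in {0, 1, 2} (floats accepted).
    stages : sequence of str
        Length-N diagnosis stage labels, e.g. HC / MD / SD.
    roi_names : sequence of str
        d feature (ROI) names shared by all modalities.
    modalities : sequence of str
        M modality tags, e.g. ("node", "edge").
    standardized : bool
        Whether the columns of X are already z-scored.
    """

    X: list[np.ndarray]
    y: np.ndarray
    stages: Sequence[str]
    roi_names: Sequence[str]
    modalities: Sequence[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.X = [np.asarray(Xm, dtype=float) for Xm in self.X]
        self.y = np.asarray(self.y, dtype=float)
        self.stages = list(self.stages)
        self.roi_names = list(self.roi_names)
        self.modalities = list(self.modalities)
        if len(self.X) < 1:
            raise ValueError("need at least one modality")
        shape = self.X[0].shape
        for m, Xm in enumerate(self.X):
            if Xm.ndim != 2 or Xm.shape != shape:
                raise ValueError(f"modality {m}: shape {Xm.shape} != {shape}")
            if not np.all(np.isfinite(Xm)):
                raise ValueError(f"modality {m}: non-finite features")
        N, d = shape
        if self.y.shape != (N,):
            raise ValueError(f"y must have length {N}")
        if len(self.stages) != N:
            raise ValueError(f"stages must have length {N}")
        if len(self.roi_names) != d:
            raise ValueError(f"roi_names must have length {d}")
        if len(self.modalities) != len(self.X):
            raise ValueError("one modality tag per feature matrix required")

    @property
    def n_subjects(self) -> int:
        return self.X[0].shape[0]

    @property
    def n_features(self) -> int:
        return self.X[0].shape[1]

    @property
    def n_modalities(self) -> int:
        return len(self.X)

    def subset(self, idx: np.ndarray) -> "MultiModalDataset":
        """Row-subset (subjects) of the dataset, e.g. a CV fold."""
        idx = np.asarray(idx)
        return MultiModalDataset(
            X=[Xm[idx] for Xm in self.X],
            y=self.y[idx],
            stages=[self.stages[i] for i in idx],
            roi_names=self.roi_names,
            modalities=self.modalities,
            standardized=self.standardized,
        )

    def concatenated(self) -> "MultiModalDataset":
        """Single-modality view with all feature columns stacked side by side."""
        if self.n_modalities == 1:
            return self
        names = [f"{name}|{tag}" for tag, Xm in zip(self.modalities, self.X)
                 for name in self.roi_names]
        return MultiModalDataset(
            X=[np.hstack(self.X)],
            y=self.y,
            stages=self.stages,
            roi_names=names,
            modalities=["+".join(self.modalities)],
            standardized=self.standardized,
        )


@dataclass
class StageGraph:
    """Same-stage similarity matrix with its degree matrix and Laplacian."""

    S: np.ndarray
    D: np.ndarray
    L: np.ndarray


def build_similarity(stages: Sequence[str]) -> np.ndarray:
    """Binary same-class similarity matrix: S_ij = 1 iff stage_i == stage_j."""
    stages = list(stages)
    if len(stages) == 0:
        raise ValueError("empty stage label vector")
    arr = np.asarray(stages, dtype=object)
    return (arr[:, None] == arr[None, :]).astype(float)


def build_laplacian(S: np.ndarray) -> StageGraph:
    """Graph Laplacian L = D - S of a binary similarity matrix.

    D is diagonal with D_ii = sum_j S_ij.  L annihilates the constant vector
    and is positive semi-definite.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.array_equal(S, S.T):
        raise ValueError("similarity matrix must be symmetric")
    if not np.all(np.isin(S, (0.0, 1.0))):
        raise ValueError("similarity matrix must be binary")
    D = np.diag(S.sum(axis=1))
    return StageGraph(S=S, D=D, L=D - S)


@dataclass
class RegularizationConfig:
    """Hyperparameters and solver settings.

    lambda1 weights the L2,1 row-sparsity penalty, lambda2 the stage-Laplacian
    quadratic.  For variants without the diagnosis term (SM/CM/MM) lambda2 is
    forced to zero at fit time.
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    max_iter: int = 1000
    tol: float = 1e-6
    variant: str = "MSD-MM"

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}")

    @property
    def effective_lambda2(self) -> float:
        return self.lambda2 if VARIANTS[self.variant][1] else 0.0


@dataclass
class ModelFit:
    """Result of one solver run, plus what is needed to predict on new data."""

    W: np.ndarray
    intercepts: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    config: RegularizationConfig
    feature_means: list[np.ndarray]
    feature_scales: list[np.ndarray]
    roi_names: Sequence[str] = field(default_factory=list)
    modalities: Sequence[str] = field(default_factory=list)

    @property
    def n_iter(self) -> int:
        return len(self.objective_trace)

    def selected_rows(self, tol: float = 0.0) -> np.ndarray:
        """Indices of ROI rows with nonzero coefficients in any modality."""
        return np.flatnonzero(np.linalg.norm(self.W, axis=1) > tol)


def _check_dims(W: np.ndarray, data: MultiModalDataset,
                graphs: Sequence[StageGraph] | None) -> None:
    d, M = data.n_features, data.n_modalities
    if W.shape != (d, M):
        raise ValueError(f"W must have shape ({d}, {M}), got {W.shape}")
    if graphs is not None and len(graphs) != M:
        raise ValueError("one stage graph per modality required")


def objective_value(
    W: np.ndarray,
    data: MultiModalDataset,
    graphs: Sequence[StageGraph] | None,
    cfg: RegularizationConfig,
) -> float:
    """Full penalised objective F(W)."""
    W = np.asarray(W, dtype=float)
    _check_dims(W, data, graphs)
    lam2 = cfg.effective_lambda2
    total = 0.0
    for m, Xm in enumerate(data.X):
        r = data.y - Xm @ W[:, m]
        total += 0.5 * float(r @ r)
        if lam2 > 0:
            z = Xm @ W[:, m]
            total += lam2 * float(z @ graphs[m].L @ z)
    total += cfg.lambda1 * float(np.linalg.norm(W, axis=1).sum())
    return total


def smooth_gradient(
    W: np.ndarray,
    data: MultiModalDataset,
    graphs: Sequence[StageGraph] | None,
    cfg: RegularizationConfig,
) -> np.ndarray:
    """Gradient of the smooth part (loss + Laplacian quadratic) wrt W."""
    W = np.asarray(W, dtype=float)
    _check_dims(W, data, graphs)
    lam2 = cfg.effective_lambda2
    G = np.empty_like(W)
    for m, Xm in enumerate(data.X):
        z = Xm @ W[:, m]
        g = Xm.T @ (z - data.y)
        if lam2 > 0:
            g = g + 2.0 * lam2 * (Xm.T @ (graphs[m].L @ z))
        G[:, m] = g
    return G


def prox_l21(V: np.ndarray, tau: float) -> np.ndarray:
    """Proximal operator of tau * sum_j ||v_j||_2 (row-wise group shrinkage).

    Row j maps to max(0, 1 - tau/||v_j||) * v_j; rows with norm <= tau vanish.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    V = np.asarray(V, dtype=float)
    if tau == 0:
        return V.copy()
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norms > 0, np.maximum(0.0, 1.0 - tau / norms), 0.0)
    return scale * V


def lambda_max(data: MultiModalDataset) -> float:
    """Smallest lambda1 for which the all-zero solution is optimal.

    At W = 0 the smooth gradient has columns -(X^m)' y; zero is a minimiser
    iff every row of that stacked gradient has Euclidean norm <= lambda1.
    The Laplacian term is quadratic in X w and vanishes at 0, so it does not
    move this threshold.
    """
    G0 = np.column_stack([Xm.T @ data.y for Xm in data.X])
    return float(np.linalg.norm(G0, axis=1).max())


def _standardize(data: MultiModalDataset) -> tuple[MultiModalDataset, list, list]:
    """Center and unit-scale each feature column (training statistics)."""
    means, scales, Xs = [], [], []
    for Xm in data.X:
        mu = Xm.mean(axis=0)
        sd = Xm.std(axis=0)
        const = sd == 0
        if np.any(const):
            warnings.warn(
                f"{int(const.sum())} constant feature column(s); left at unit scale"
            )
            sd = np.where(const, 1.0, sd)
        means.append(mu)
        scales.append(sd)
        Xs.append((Xm - mu) / sd)
    out = MultiModalDataset(
        X=Xs, y=data.y, stages=data.stages, roi_names=data.roi_names,
        modalities=data.modalities, standardized=True,
    )
    return out, means, scales


def _power_lipschitz(H: np.ndarray, n_iter: int = 50, seed: int = 0) -> float:
    """Largest eigenvalue of a symmetric PSD matrix by power iteration."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(H.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        w = H @ v
        lam = float(v @ w)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 0.0
        v = w / nrm
    return max(lam, float(v @ (H @ v)))


def fit(
    data: MultiModalDataset,
    stages: Sequence[str] | None = None,
    cfg: RegularizationConfig | None = None,
    standardize: bool = True,
) -> ModelFit:
    """Fit the association model by accelerated proximal gradient.

    The variant in ``cfg`` controls the data layout: SM/MSD-SM expect a
    single-modality dataset, CM/MSD-CM concatenate all modalities into one
    feature block (the L2,1 penalty then reduces to the lasso), MM/MSD-MM use
    the multi-task layout.  Variants without the MSD prefix force lambda2 = 0.

    Feature columns are z-scored with training statistics by default; the
    per-modality intercept is mean(y) on the training subjects, so predictions
    stay on the 0-2 genotype scale.

    The solver uses Nesterov momentum over the proximal-gradient step, with a
    backtracking line search initialised from a power-iteration Lipschitz
    estimate and a function-value restart that keeps the recorded objective
    trace non-increasing.  Iteration stops when the relative objective change
    drops below ``cfg.tol``.
    """
    cfg = cfg or RegularizationConfig()
    concat, _use_lap = VARIANTS[cfg.variant]
    if stages is None:
        stages = data.stages
    if len(stages) != data.n_subjects:
        raise ValueError("stages length must match the number of subjects")
    if cfg.variant in ("SM", "MSD-SM") and data.n_modalities != 1:
        raise ValueError(f"variant {cfg.variant} expects a single-modality dataset")
    work = data.concatenated() if concat else data
    lam2 = cfg.effective_lambda2

    if standardize and not work.standardized:
        work, means, scales = _standardize(work)
    else:
        means = [np.zeros(work.n_features) for _ in range(work.n_modalities)]
        scales = [np.ones(work.n_features) for _ in range(work.n_modalities)]

    y = work.y
    N, d, M = work.n_subjects, work.n_features, work.n_modalities
    graphs = None
    L = None
    if lam2 > 0:
        S = build_similarity(stages)
        graphs = [build_laplacian(S) for _ in range(M)]
        L = graphs[0].L

    # Precomputed quadratic form: smooth part is
    #   0.5 * sum_m (w_m' A_m w_m - 2 b_m' w_m + y'y)  with
    #   A_m = X_m'(I + 2*lam2*L)X_m,  b_m = X_m' y.
    A = np.empty((M, d, d))
    B = np.empty((d, M))
    for m, Xm in enumerate(work.X):
        XtX = Xm.T @ Xm
        A[m] = XtX if lam2 == 0 else XtX + 2.0 * lam2 * (Xm.T @ (L @ Xm))
        B[:, m] = Xm.T @ y
    yty = float(y @ y)

    def f_smooth(W: np.ndarray) -> float:
        val = 0.5 * M * yty
        for m in range(M):
            wm = W[:, m]
            val += 0.5 * float(wm @ (A[m] @ wm)) - float(B[:, m] @ wm)
        return val

    def grad_smooth(W: np.ndarray) -> np.ndarray:
        G = np.empty_like(W)
        for m in range(M):
            G[:, m] = A[m] @ W[:, m] - B[:, m]
        return G

    def penalty(W: np.ndarray) -> float:
        return cfg.lambda1 * float(np.linalg.norm(W, axis=1).sum())

    lip = max(max(_power_lipschitz(A[m]) for m in range(M)), 1e-12)
    step = 1.0 / lip

    W = np.zeros((d, M))
    Z = W.copy()
    t = 1.0
    f_W = f_smooth(W) + penalty(W)
    trace = [f_W]
    converged = False

    for it in range(cfg.max_iter):
        g = grad_smooth(Z)
        f_Z = f_smooth(Z)
        # backtracking on the smooth majorization at Z
        s = step
        for _ in range(60):
            W_new = prox_l21(Z - s * g, s * cfg.lambda1)
            diff = W_new - Z
            quad = f_Z + float(np.sum(g * diff)) + float(np.sum(diff * diff)) / (2 * s)
            f_new_smooth = f_smooth(W_new)
            if f_new_smooth <= quad + 1e-12 * max(1.0, abs(quad)):
                break
            s *= 0.5
        f_new = f_new_smooth + penalty(W_new)
        if not np.isfinite(f_new):
            raise FloatingPointError(
                f"objective diverged at iteration {it} (step {s:.3e})"
            )
        if f_new > f_W:
            # monotone safeguard: restart momentum from the best iterate
            Z = W.copy()
            t = 1.0
            g = grad_smooth(Z)
            f_Z = f_smooth(Z)
            s = step
            for _ in range(60):
                W_new = prox_l21(Z - s * g, s * cfg.lambda1)
                diff = W_new - Z
                quad = (f_Z + float(np.sum(g * diff))
                        + float(np.sum(diff * diff)) / (2 * s))
                f_new_smooth = f_smooth(W_new)
                if f_new_smooth <= quad + 1e-12 * max(1.0, abs(quad)):
                    break
                s *= 0.5
            f_new = f_new_smooth + penalty(W_new)
            if f_new > f_W:       # at a (numerical) fixed point
                trace.append(f_W)
                converged = True
                break
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        Z = W_new + ((t - 1.0) / t_new) * (W_new - W)
        rel = abs(f_W - f_new) / max(1.0, abs(f_W))
        W, f_W, t = W_new, f_new, t_new
        trace.append(f_W)
        if rel <= cfg.tol:
            converged = True
            break

    intercepts = np.full(M, float(y.mean()))
    return ModelFit(
        W=W, intercepts=intercepts, objective_trace=np.asarray(trace),
        converged=converged, config=cfg, feature_means=means,
        feature_scales=scales, roi_names=work.roi_names,
        modalities=work.modalities,
    )


def predict(model: ModelFit, X: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Per-modality predicted genotype values for new feature matrices.

    Applies the training-fold standardization, then
    yhat^m = X̃^m w^m + intercept_m.  For concatenated (CM-type) fits pass the
    modalities in training order; they are stacked internally.
    """
    X = [np.asarray(Xm, dtype=float) for Xm in X]
    M = model.W.shape[1]
    if M == 1 and len(X) > 1:
        X = [np.hstack(X)]
    if len(X) != M:
        raise ValueError(f"expected {M} feature matrices, got {len(X)}")
    preds = []
    for m, Xm in enumerate(X):
        if Xm.shape[1] != model.W.shape[0]:
            raise ValueError(
                f"modality {m}: {Xm.shape[1]} columns, expected {model.W.shape[0]}"
            )
        Xt = (Xm - model.feature_means[m]) / model.feature_scales[m]
        preds.append(Xt @ model.W[:, m] + model.intercepts[m])
    return preds
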
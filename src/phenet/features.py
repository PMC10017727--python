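"""Multi-modality phenotype network construction.

Node features are ROI-mean gray-matter densities taken from a co-registered
density volume and an integer atlas.  Edge features are weighted clustering
coefficients of the functional-connectivity (FC) network built from ROI-mean
BOLD time series via Pearson correlation.  Group-level FC summaries and
per-ROI strongest-edge reports support downstream inspection of selected
regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ROITimeSeries",
    "FCNetwork",
    "FeatureVector",
    "extract_node_features",
    "compute_fc",
    "clustering_coefficients",
    "group_mean_fc",
    "top_k_edges",
]


@dataclass
class ROITimeSeries:
    """Mean BOLD signal per ROI for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    series : ndarray of shape (T, d)
        T time points for d ROIs, arbitrary BOLD units.
    roi_names : sequence of str
        d unique ROI labels (e.g. AAL names).
    """

    subject_id: str
    series: np.ndarray
    roi_names: Sequence[str]

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        self.roi_names = list(self.roi_names)
        if self.series.ndim != 2:
            raise ValueError("series must be a 2-D (T, d) array")
        T, d = self.series.shape
        if T < 3:
            raise ValueError(f"need at least 3 time points, got {T}")
        if d < 2:
            raise ValueError(f"need at least 2 ROIs, got {d}")
        if len(self.roi_names) != d:
            raise ValueError("roi_names length does not match series columns")
        if len(set(self.roi_names)) != d:
            raise ValueError("roi_names must be unique")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("series contains non-finite values")

    @property
    def n_rois(self) -> int:
        return self.series.shape[1]


@dataclass
class FCNetwork:
    """Symmetric weighted connectivity matrix for one subject.

    ``weights[i, j]`` is the edge weight between ROI i and j (Pearson r when
    built by :func:`compute_fc`); the diagonal is zero.  ``degrees[i]`` counts
    incident nonzero edges.
    """

    weights: np.ndarray
    roi_names: Sequence[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.roi_names = list(self.roi_names)
        W = self.weights
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if len(self.roi_names) != W.shape[0]:
            raise ValueError("roi_names length does not match weights")
        if not np.all(np.isfinite(W)):
            raise ValueError("weights contain non-finite values")
        if np.max(np.abs(W - W.T), initial=0.0) > 1e-12:
            raise ValueError("weights must be symmetric (tolerance 1e-12)")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Number of nonzero incident edges per node."""
        return np.count_nonzero(self.weights, axis=1)


@dataclass
class FeatureVector:
    """One subject's d ROI-level features for a single modality."""

    values: np.ndarray
    modality: str
    roi_names: Sequence[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_names = list(self.roi_names)
        if self.modality not in ("node", "edge"):
            raise ValueError(f"modality must be 'node' or 'edge', got {self.modality!r}")
        if self.values.ndim != 1 or len(self.values) != len(self.roi_names):
            raise ValueError("values must be 1-D with one entry per ROI")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")


def extract_node_features(
    density_volume: np.ndarray,
    atlas_volume: np.ndarray,
    label_map: dict[int, str],
    subject_id: str = "",
) -> FeatureVector:
    """ROI-mean density over atlas regions.

    The two volumes must already be co-registered in voxel-index space; label
    0 in the atlas is background.  For each ``label -> name`` entry the value
    is the arithmetic mean of ``density_volume`` over voxels where
    ``atlas_volume == label``.
    """
    density = np.asarray(density_volume, dtype=float)
    atlas = np.asarray(atlas_volume)
    if density.shape != atlas.shape:
        raise ValueError(
            f"density volume shape {density.shape} != atlas shape {atlas.shape}"
        )
    if not np.issubdtype(atlas.dtype, np.integer):
        raise ValueError("atlas volume must be an integer label array")
    labels = sorted(label_map)
    missing = [lab for lab in labels if not np.any(atlas == lab)]
    if missing:
        raise KeyError(f"atlas contains no voxels for label(s): {missing}")
    values = np.array([density[atlas == lab].mean() for lab in labels])
    names = [label_map[lab] for lab in labels]
    return FeatureVector(values=values, modality="node", roi_names=names,
                         subject_id=subject_id)


def compute_fc(ts: ROITimeSeries) -> FCNetwork:
    """Pearson-correlation FC network from ROI time series.

    Each ROI series is standardized to zero mean and unit variance before the
    correlation, which leaves Pearson r unchanged but mirrors the usual BOLD
    preprocessing convention.  The diagonal is zeroed.
    """
    X = ts.series
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.roi_names[i] for i in dead]
        raise ValueError(f"zero-variance time series for ROI(s): {names}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 0.0)
    return FCNetwork(weights=R, roi_names=ts.roi_names, subject_id=ts.subject_id)


def _prepare_weights(
    W: np.ndarray, negative_weights: str, proportional_threshold: float | None
) -> np.ndarray:
    if negative_weights == "abs":
        W = np.abs(W)
    elif negative_weights == "clip":
        W = np.maximum(W, 0.0)
    else:
        raise ValueError("negative_weights must be 'abs' or 'clip'")
    if proportional_threshold is not None:
        if not 0.0 < proportional_threshold <= 1.0:
            raise ValueError("proportional_threshold must be in (0, 1]")
        d = W.shape[0]
        off = W[np.triu_indices(d, k=1)]
        keep = max(1, int(round(proportional_threshold * off.size)))
        cut = np.sort(off)[::-1][keep - 1]
        W = np.where(W >= cut, W, 0.0)
        np.fill_diagonal(W, 0.0)
    return W


def clustering_coefficients(
    fc: FCNetwork,
    negative_weights: str = "abs",
    proportional_threshold: float | None = None,
    geometric_mean: bool = False,
) -> FeatureVector:
    """Weighted clustering coefficient per node of an FC network.

    Weights are first made nonnegative (absolute value by default, or clipped
    at zero with ``negative_weights='clip'``) and scaled by the maximum
    off-diagonal weight so that every scaled weight lies in [0, 1].  For node
    i with degree k_i >= 2,

        CC(i) = 2 / (k_i (k_i - 1)) * sum over unordered neighbour pairs
                {j, h} of  w̄_ij * w̄_ih * w̄_jh,

    so a unit-weight triangle scores 1 and the statistic reduces to the
    binary transitivity-style clustering coefficient on 0/1 graphs.  Nodes
    with fewer than two neighbours score 0.  With ``geometric_mean=True`` the
    triple product is replaced by its cube root (the Onnela variant).

    An all-zero network yields an all-zero vector with a logged warning, since
    the max-weight scale is undefined there.
    """
    W = _prepare_weights(fc.weights.copy(), negative_weights, proportional_threshold)
    d = W.shape[0]
    wmax = W.max(initial=0.0)
    if wmax == 0.0:
        logger.warning(
            "all-zero connectivity network (subject %r): clustering coefficients "
            "set to 0", fc.subject_id,
        )
        warnings.warn("all-zero connectivity network: clustering coefficients are 0")
        return FeatureVector(np.zeros(d), "edge", fc.roi_names, fc.subject_id)
    Wb = W / wmax
    if geometric_mean:
        Wb = np.cbrt(Wb)
    cc = np.zeros(d)
    deg = np.count_nonzero(W, axis=1)
    # sum over unordered neighbour pairs {j,h} of w̄_ij w̄_ih w̄_jh equals
    # ((Wb @ Wb) * Wb).diagonal() / 2 restricted to actual neighbours; the
    # matrix form is exact because non-neighbours contribute w̄_ij = 0.
    triples = np.einsum("ij,jh,hi->i", Wb, Wb, Wb) / 2.0
    mask = deg >= 2
    cc[mask] = 2.0 / (deg[mask] * (deg[mask] - 1.0)) * triples[mask]
    return FeatureVector(values=cc, modality="edge", roi_names=fc.roi_names,
                         subject_id=fc.subject_id)


def group_mean_fc(networks: Sequence[FCNetwork]) -> FCNetwork:
    """Element-wise mean connectivity over a group of subjects."""
    if len(networks) == 0:
        raise ValueError("cannot average an empty group of networks")
    names = networks[0].roi_names
    for net in networks[1:]:
        if list(net.roi_names) != list(names):
            raise ValueError("ROI names differ across networks; cannot align")
    mean = np.mean([net.weights for net in networks], axis=0)
    return FCNetwork(weights=mean, roi_names=names, subject_id="group-mean")


def top_k_edges(
    fc: FCNetwork, roi: str, k: int, by_magnitude: bool = False
) -> list[tuple[str, float]]:
    """The k strongest edges incident to one ROI, sorted descending.

    Sorting is by signed weight by default (largest connection values first);
    ``by_magnitude=True`` sorts by \\|weight\\|.  Ties are broken by ROI-name
    order for determinism.
    """
    names = list(fc.roi_names)
    if roi not in names:
        raise KeyError(f"unknown ROI {roi!r}")
    if not 1 <= k <= fc.n_rois - 1:
        raise ValueError(f"k must be in [1, {fc.n_rois - 1}]")
    i = names.index(roi)
    pairs = [(names[j], fc.weights[i, j]) for j in range(fc.n_rois) if j != i]
    key = (lambda p: (-abs(p[1]), p[0])) if by_magnitude else (lambda p: (-p[1], p[0]))
    return sorted(pairs, key=key)[:k]
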
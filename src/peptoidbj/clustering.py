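"""Per-trace featurization and population detection by Gaussian mixture
modeling with silhouette-score model selection.

Each aligned trace is summarized by the concatenation of its own 30 × 30
displacement/conductance histogram (flattened row-major, displacement-major)
and its own 100-bin conductance histogram: a 1000-dimensional feature vector
at the default binning. Candidate mixture sizes k are fitted on Z-scored
features (zero-variance dimensions dropped) with full covariances and
multiple seeded restarts; the silhouette score of the hard assignments in
the standardized feature space selects k, and the ensemble is demoted to a
single population when even the best k ≥ 2 silhouette falls below a
configurable threshold — a guard against over-clustering unimodal data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .histograms import hist1d, hist2d
from .trace_processing import AlignmentSpec, Trace

__all__ = [
    "FeatureSpec",
    "TraceFeature",
    "ClusterModel",
    "featurize_trace",
    "featurize_ensemble",
    "fit_select",
    "cluster_histograms",
]


@dataclass
class FeatureSpec:
    """Binning of the per-trace feature vector: nx × ny 2D bins plus nb 1D
    bins over the alignment windows (defaults 30 × 30 + 100 = 1000).

    ``smooth_sigma_bins_1d`` / ``smooth_sigma_bins_2d`` optionally convolve
    the per-trace histograms with a Gaussian kernel (widths in bins; 0
    disables). Raw count histograms of sparse traces are near-orthogonal
    once conductance plateaus stop sharing bins, so Euclidean distances
    saturate and carry no information about how far apart two plateau
    levels are; a kernel of the order of the between-population separations
    of interest (~1 decade) restores a graded metric. Smoothing is off by
    default for plain featurization and enabled by
    :func:`cluster_feature_spec` for population detection.
    """

    alignment: AlignmentSpec = field(default_factory=AlignmentSpec)
    nx: int = 30
    ny: int = 30
    nb: int = 100
    smooth_sigma_bins_1d: float = 0.0
    smooth_sigma_bins_2d: tuple[float, float] = (0.0, 0.0)

    @property
    def length(self) -> int:
        return self.nx * self.ny + self.nb


def cluster_feature_spec(alignment: AlignmentSpec | None = None) -> FeatureSpec:
    """Feature spec used for population detection: default binning with
    kernel smoothing (σ = 25 of 100 bins in 1D, (2, 8) of 30 × 30 bins in
    2D, i.e. ≈1.4 decades on the conductance axes)."""
    return FeatureSpec(
        alignment=alignment or AlignmentSpec(),
        smooth_sigma_bins_1d=25.0,
        smooth_sigma_bins_2d=(2.0, 8.0),
    )


@dataclass
class TraceFeature:
    trace_id: str
    vector: np.ndarray
    all_outside_window: bool = False


def featurize_trace(trace: Trace, spec: FeatureSpec | None = None) -> TraceFeature:
    """Per-trace histogram feature vector.

    Layout: the flattened 2D histogram first (row-major over displacement
    bins, i.e. entries 0..ny-1 are the conductance bins of the first
    displacement bin), followed by the 1D histogram counts.
    """
    spec = spec or FeatureSpec()
    a = spec.alignment
    d = trace.displacement_nm
    g = trace.log_g
    m2 = (
        (d >= a.clip_displacement_nm[0]) & (d <= a.clip_displacement_nm[1])
        & (g >= a.clip_log_g[0]) & (g <= a.clip_log_g[1])
    )
    counts2d, _, _ = np.histogram2d(
        d[m2], g[m2], bins=(spec.nx, spec.ny),
        range=[a.clip_displacement_nm, a.clip_log_g],
    )
    m1 = (g >= a.clip_log_g[0]) & (g <= a.clip_log_g[1])
    counts1d, _ = np.histogram(g[m1], bins=spec.nb, range=a.clip_log_g)
    counts1d = counts1d.astype(float)
    if spec.smooth_sigma_bins_2d != (0.0, 0.0):
        counts2d = gaussian_filter(counts2d, spec.smooth_sigma_bins_2d)
    if spec.smooth_sigma_bins_1d > 0:
        counts1d = gaussian_filter1d(counts1d, spec.smooth_sigma_bins_1d)
    vec = np.concatenate([counts2d.ravel(order="C"), counts1d]).astype(float)
    return TraceFeature(
        trace_id=trace.trace_id,
        vector=vec,
        all_outside_window=bool(vec.sum() == 0),
    )


def featurize_ensemble(traces, spec: FeatureSpec | None = None):
    spec = spec or FeatureSpec()
    return [featurize_trace(tr, spec) for tr in traces]


@dataclass
class ClusterModel:
    """Fitted candidate mixtures and the silhouette-selected population count.

    ``selected_k`` is 1 ("single population") when the best silhouette over
    k ≥ 2 candidates is below ``threshold``; ``labels`` then collapse to 0.
    Per-candidate entries keep weights, means (in standardized feature
    space), labels and silhouettes for inspection.
    """

    k_candidates: list[int]
    per_k: dict[int, dict]
    selected_k: int
    labels: np.ndarray
    best_silhouette: float
    threshold: float
    seed: int
    kept_dims: np.ndarray
    standardize: bool

    def summary(self) -> dict:
        return {
            "k_candidates": self.k_candidates,
            "selected_k": self.selected_k,
            "best_silhouette": self.best_silhouette,
            "threshold": self.threshold,
            "silhouettes": {k: self.per_k[k]["silhouette"] for k in self.per_k},
            "seed": self.seed,
        }


def fit_select(features: Sequence[TraceFeature] | np.ndarray,
               k_candidates: Sequence[int] = (2, 3, 4),
               seed: int = 0,
               threshold: float = 0.5,
               n_init: int = 10,
               standardize: bool = True,
               reg_covar: float = 1e-6,
               pca_variance: float = 0.999) -> ClusterModel:
    """Fit Gaussian mixtures for each candidate k and select by silhouette.

    Features are Z-scored per dimension (zero-variance dimensions dropped);
    each GMM uses full covariances with diagonal ridge ``reg_covar`` and
    ``n_init`` seeded restarts, keeping the best likelihood. Silhouette is
    computed on the hard labels with Euclidean distance in the standardized
    space. Deterministic for fixed (features, seed).

    As a numerical device the standardized features are rotated onto their
    principal axes and trailing components beyond ``pca_variance`` of the
    total variance are discarded before the EM fit: a rigid rotation leaves
    Euclidean distances (hence the silhouette) essentially unchanged while
    conditioning the covariance estimate and cutting the EM cost in the
    near-empty trailing directions.
    """
    if isinstance(features, np.ndarray):
        x = np.asarray(features, dtype=float)
    else:
        x = np.array([f.vector for f in features], dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two feature vectors")
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if any(k < 2 for k in k_candidates):
        raise ValueError("candidate k must be >= 2")

    sd = x.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not np.any(keep):
        raise ValueError("all features identical: degenerate covariance")
    if standardize:
        z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    else:
        z = x[:, keep]

    if 0.0 < pca_variance < 1.0 and z.shape[1] > 32:
        rot = PCA(n_components=min(z.shape[0] - 1, z.shape[1]),
                  svd_solver="full")
        zr = rot.fit_transform(z)
        n_keep = int(np.searchsorted(
            np.cumsum(rot.explained_variance_ratio_), pca_variance) + 1)
        z = zr[:, :max(n_keep, min(8, zr.shape[1]))]

    per_k: dict[int, dict] = {}
    for k in k_candidates:
        gmm = GaussianMixture(
            n_components=k, covariance_type="full", reg_covar=reg_covar,
            n_init=n_init, random_state=seed, max_iter=200,
        )
        labels = gmm.fit_predict(z)
        if len(np.unique(labels)) < 2:
            sil = -1.0  # collapsed fit: worst possible separation
        else:
            sil = float(silhouette_score(z, labels, metric="euclidean"))
        per_k[k] = {
            "weights": gmm.weights_,
            "means": gmm.means_,
            "covariances": gmm.covariances_,
            "labels": labels,
            "silhouette": sil,
            "converged": bool(gmm.converged_),
        }

    best_k = max(k_candidates, key=lambda k: per_k[k]["silhouette"])
    best_sil = per_k[best_k]["silhouette"]
    if best_sil < threshold:
        selected_k = 1
        labels = np.zeros(x.shape[0], dtype=int)
    else:
        selected_k = best_k
        labels = per_k[best_k]["labels"]
    return ClusterModel(
        k_candidates=k_candidates,
        per_k=per_k,
        selected_k=selected_k,
        labels=labels,
        best_silhouette=best_sil,
        threshold=threshold,
        seed=seed,
        kept_dims=np.flatnonzero(keep),
        standardize=standardize,
    )


def cluster_histograms(traces, model: ClusterModel,
                       spec: AlignmentSpec | None = None) -> dict[int, dict]:
    """Per-cluster ensemble histograms (1D and 2D) from a fitted model whose
    labels follow the ensemble order."""
    if len(traces) != len(model.labels):
        raise ValueError("label count does not match ensemble size")
    spec = spec or AlignmentSpec()
    out: dict[int, dict] = {}
    for lab in sorted(set(int(v) for v in model.labels)):
        members = [tr for tr, l in zip(traces, model.labels) if l == lab]
        out[lab] = {
            "n_traces": len(members),
            "hist1d": hist1d(members, spec),
            "hist2d": hist2d(members, spec),
        }
    return out
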
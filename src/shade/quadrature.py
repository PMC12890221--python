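"""Dummy-point quadrature and logistic design construction.

Fitting the inhomogeneous Poisson intensity of the target cell type is
reframed as binary classification: observed target cells (response 1) are
contrasted with dummy points drawn from a homogeneous Poisson process of
intensity ``lambda_dummy`` (response 0).  Under this construction

    P(y = 1 | v) = lambda(v) / (lambda(v) + lambda_dummy),

so a logistic regression with offset -log(lambda_dummy) estimates
log lambda(v) directly.  Each row carries spatial covariates z(v) and,
per source type A_k, the interaction features

    [q_Ak(v)]_p = sum_{x in X_Ak} phi_p(||v - x||),

summing basis-weighted distances over all source cells within r_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .basis import BasisSystem
from .patterns import MultitypePattern, ObservationWindow, subset_by_type

__all__ = [
    "QuadratureScheme",
    "LogisticDataset",
    "sample_dummy_points",
    "interaction_features",
    "compartment_covariate",
    "build_logistic_dataset",
]

#: dummy intensity = DUMMY_FACTOR x observed target density (quadrature default)
DUMMY_FACTOR = 4.0


@dataclass
class QuadratureScheme:
    dummy_points: np.ndarray  # (n_dummy, 2)
    lambda_dummy: float  # points / um^2
    window: ObservationWindow
    seed: int | None = None

    def __post_init__(self):
        self.dummy_points = np.asarray(self.dummy_points, float).reshape(-1, 2)
        if self.lambda_dummy <= 0:
            raise ValueError("dummy intensity must be positive")
        if self.dummy_points.size and not self.window.contains(self.dummy_points).all():
            raise ValueError("dummy points must lie inside the window")


@dataclass
class LogisticDataset:
    """Design for one image and one target type.

    ``y`` is 1 for observed target cells and 0 for dummy points;
    ``offset`` is -log(lambda_dummy); ``features[k]`` holds the (n, P)
    interaction-feature block of source type k; ``Z`` holds J extra
    spatial covariates (may have zero columns).
    """

    y: np.ndarray
    locations: np.ndarray
    offset: float
    Z: np.ndarray
    features: dict  # source label -> (n, P)
    image_id: str
    lambda_dummy: float
    source_labels: tuple = field(default=None)
    target_label: str | None = None
    covariate_names: tuple = ()

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("responses must be 0/1")
        if self.source_labels is None:
            self.source_labels = tuple(self.features)
        for k, q in self.features.items():
            if not np.all(np.isfinite(q)):
                raise ValueError(f"non-finite interaction features for source {k!r}")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_target(self) -> int:
        return int(self.y.sum())

    def design(self) -> np.ndarray:
        """Dense (n, J + K*P) matrix: covariates then feature blocks in order."""
        blocks = [self.Z] + [self.features[k] for k in self.source_labels]
        return np.hstack(blocks)

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-location audit table."""
        df = pd.DataFrame(
            {"image_id": self.image_id, "x": self.locations[:, 0],
             "y_coord": self.locations[:, 1], "response": self.y,
             "offset": self.offset}
        )
        for j, name in enumerate(self.covariate_names):
            df[f"z_{name}"] = self.Z[:, j]
        for k in self.source_labels:
            for p in range(self.features[k].shape[1]):
                df[f"q_{k}_{p}"] = self.features[k][:, p]
        return df


def sample_dummy_points(
    window: ObservationWindow, lambda_dummy: float, seed=None
) -> QuadratureScheme:
    """Homogeneous Poisson dummy points: count ~ Poisson(lambda * area),
    locations i.i.d. uniform on the window."""
    if lambda_dummy <= 0:
        raise ValueError("dummy intensity must be positive")
    rng = np.random.default_rng(seed)
    n = rng.poisson(lambda_dummy * window.area)
    pts = np.column_stack(
        [rng.uniform(window.x_min, window.x_max, n),
         rng.uniform(window.y_min, window.y_max, n)]
    )
    return QuadratureScheme(pts, lambda_dummy, window, seed=seed)


def interaction_features(
    locations, source: MultitypePattern | np.ndarray, basis: BasisSystem
) -> np.ndarray:
    """Basis-weighted distance sums from each location to all source cells.

    Entry (v, p) is sum over source cells x of phi_p(||v - x||); only
    sources within ``basis.r_max`` of v contribute (compact support).
    Exact Euclidean distances with a KD-tree radius cutoff.
    """
    locations = np.asarray(locations, float).reshape(-1, 2)
    src = source.points if isinstance(source, MultitypePattern) else np.asarray(source, float)
    src = src.reshape(-1, 2)
    out = np.zeros((locations.shape[0], basis.P))
    if src.shape[0] == 0 or locations.shape[0] == 0:
        return out
    tree = cKDTree(src)
    neighbors = tree.query_ball_point(locations, r=basis.r_max)
    loc_idx = np.repeat(np.arange(locations.shape[0]), [len(nb) for nb in neighbors])
    if loc_idx.size == 0:
        return out
    src_idx = np.concatenate([nb for nb in neighbors if nb])
    d = np.linalg.norm(locations[loc_idx] - src[src_idx], axis=1)
    np.add.at(out, loc_idx, basis.design(d))
    return out


def compartment_covariate(
    locations,
    reference: MultitypePattern | np.ndarray,
    bandwidth: float = 50.0,
    threshold_rule: str = "median",
) -> np.ndarray:
    """Binary tissue-compartment indicator from reference-type density.

    A Gaussian-kernel density estimate of the reference cell type (for
    example tumor cells) is evaluated at each location and thresholded:
    locations above the per-image median density get 1 ("inside the
    reference-rich compartment"), the rest 0.  Used to adjust fits for
    architectural confounding such as tumor islands.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    locations = np.asarray(locations, float).reshape(-1, 2)
    ref = reference.points if isinstance(reference, MultitypePattern) else np.asarray(reference, float)
    ref = ref.reshape(-1, 2)
    if ref.shape[0] == 0:
        warnings.warn("empty reference pattern; compartment covariate is all zero")
        return np.zeros(locations.shape[0], dtype=int)
    # truncated Gaussian KDE: contributions beyond 5 bandwidths are negligible
    tree = cKDTree(ref)
    dens = np.zeros(locations.shape[0])
    neighbors = tree.query_ball_point(locations, r=5.0 * bandwidth)
    loc_idx = np.repeat(np.arange(locations.shape[0]), [len(nb) for nb in neighbors])
    if loc_idx.size:
        ref_idx = np.concatenate([nb for nb in neighbors if nb])
        d2 = np.sum((locations[loc_idx] - ref[ref_idx]) ** 2, axis=1)
        np.add.at(dens, loc_idx, np.exp(-0.5 * d2 / bandwidth**2))
    dens /= 2.0 * np.pi * bandwidth**2
    if threshold_rule != "median":
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    return (dens > np.median(dens)).astype(int)


def build_logistic_dataset(
    pattern: MultitypePattern,
    target_label: str,
    source_labels,
    basis: BasisSystem,
    quadrature: QuadratureScheme | None = None,
    extra_covariates=None,
    covariate_names=(),
    seed=None,
) -> LogisticDataset:
    """Assemble the logistic design for one image and one target type.

    ``extra_covariates`` may be a callable mapping an (n, 2) location
    array to an (n, J) covariate matrix, or an already-evaluated matrix
    aligned with target-then-dummy rows.  When ``quadrature`` is omitted,
    dummies are drawn at DUMMY_FACTOR x the observed target density.
    """
    source_labels = tuple(source_labels)
    if target_label in source_labels:
        raise ValueError("target label must not appear among source labels")
    target = subset_by_type(pattern, target_label)
    if quadrature is None:
        lam = DUMMY_FACTOR * max(len(target), 1) / pattern.window.area
        quadrature = sample_dummy_points(pattern.window, lam, seed=seed)
    if quadrature.window != pattern.window:
        raise ValueError("quadrature window must equal the pattern window")

    locations = np.vstack([target.points.reshape(-1, 2), quadrature.dummy_points])
    y = np.concatenate(
        [np.ones(len(target), dtype=int),
         np.zeros(quadrature.dummy_points.shape[0], dtype=int)]
    )
    features = {
        k: interaction_features(locations, subset_by_type(pattern, k), basis)
        for k in source_labels
    }
    if extra_covariates is None:
        Z = np.zeros((locations.shape[0], 0))
    elif callable(extra_covariates):
        Z = np.asarray(extra_covariates(locations), float).reshape(locations.shape[0], -1)
    else:
        Z = np.asarray(extra_covariates, float).reshape(locations.shape[0], -1)
    return LogisticDataset(
        y=y,
        locations=locations,
        offset=-np.log(quadrature.lambda_dummy),
        Z=Z,
        features=features,
        image_id=pattern.image_id,
        lambda_dummy=quadrature.lambda_dummy,
        source_labels=source_labels,
        target_label=target_label,
        covariate_names=tuple(covariate_names),
    )
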
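"""Synthetic hierarchical multitype point patterns with known SICs.

The generator mirrors the model's own data-generating assumptions: source
cells are homogeneous Poisson in a square window; target cells follow an
inhomogeneous Poisson process whose log intensity is a per-image baseline
plus basis-expanded interaction features toward the source cells (plus an
optional piecewise-constant compartment offset).  Interaction coefficients
carry the three-level hierarchy: a fixed cohort curve psi*, patient curves
gamma* ~ N(psi*, sigma_patient^2) and image curves
delta* ~ N(gamma*, sigma_image^2), elementwise per basis coefficient.

Target realizations use rejection (thinning) sampling, which is exact:
points from a homogeneous process at lambda_max (a fine-grid supremum
times a 1.2 safety factor) are kept with probability lambda(v)/lambda_max.

Every image draws its randomness from a seed derived deterministically
from the master seed and the image index, so single images are
reproducible in isolation and replicates can run in any order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSystem, evaluate_sic
from .patterns import HierarchyMap, MultitypePattern, ObservationWindow
from .quadrature import interaction_features

__all__ = [
    "SimulationConfig",
    "CompartmentField",
    "bump_coefficients",
    "draw_hier_coefficients",
    "simulate_source",
    "simulate_target",
    "simulate_compartment_field",
    "simulate_study",
]

#: log-intensity offset magnitude per compartment-effect tier
COMPARTMENT_STRENGTH = {"weak": 0.3, "moderate": 0.7, "strong": 1.2}

_GRID_RES = 256
_SAFETY = 1.2


def bump_coefficients(basis: BasisSystem, peak: float = 40.0,
                      height: float = 0.8, width: float = 15.0) -> np.ndarray:
    """Basis coefficients of a single positive bump.

    A Gaussian bump centered at ``peak`` is least-squares projected onto
    the basis and rescaled so the resulting curve's maximum equals
    ``height``; the returned coefficients (not the Gaussian) define the
    ground-truth SIC.  The default — peak near 40 um, height 0.8 —
    is detectable but not trivial at benchmark densities.
    """
    grid = np.linspace(0.0, basis.r_max, 512)
    target = height * np.exp(-0.5 * ((grid - peak) / width) ** 2)
    X = basis.design(grid)
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    cur_max = np.max(np.abs(X @ coef))
    if cur_max > 0:
        coef *= height / cur_max
    return coef


@dataclass
class SimulationConfig:
    """Study-level generator settings.

    Defaults follow the benchmark regime: a 1500x1500 um^2 window,
    40 patients in one cohort with 2 images each, 150 expected source
    cells and 15 expected target cells per image, a single positive
    bump SIC (peak ~40 um, height ~0.8), and mild hierarchical spread
    (sigma_patient = sigma_image = 0.1 per coefficient).
    """

    window_size: float = 1500.0
    n_cohorts: int = 1
    n_patients: int = 40
    images_per_patient: int | tuple = 2  # int, or (lo, hi) drawn per patient
    source_labels: tuple = ("tumor",)
    target_label: str = "T"
    expected_source: dict | int = 150
    expected_target: float = 15
    basis: BasisSystem = field(default_factory=BasisSystem)
    psi_star: dict | None = None  # source label -> length-P coefficients
    sigma_patient: float = 0.1
    sigma_image: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.expected_source, (int, float)):
            self.expected_source = {k: float(self.expected_source)
                                    for k in self.source_labels}
        if self.psi_star is None:
            self.psi_star = {k: bump_coefficients(self.basis)
                             for k in self.source_labels}
        self.psi_star = {k: np.asarray(v, float) for k, v in self.psi_star.items()}
        for k, v in self.psi_star.items():
            if v.shape != (self.basis.P,):
                raise ValueError(f"psi_star[{k!r}] must have length P")
        if self.sigma_patient < 0 or self.sigma_image < 0:
            raise ValueError("hierarchy sds must be nonnegative")
        if min(self.expected_source.values()) < 0 or self.expected_target < 0:
            raise ValueError("expected counts must be nonnegative")

    @property
    def window(self) -> ObservationWindow:
        return ObservationWindow(0.0, self.window_size, 0.0, self.window_size)

    def to_dict(self) -> dict:
        return {
            "window_size": self.window_size,
            "n_cohorts": self.n_cohorts,
            "n_patients": self.n_patients,
            "images_per_patient": (list(self.images_per_patient)
                                   if isinstance(self.images_per_patient, tuple)
                                   else self.images_per_patient),
            "source_labels": list(self.source_labels),
            "target_label": self.target_label,
            "expected_source": dict(self.expected_source),
            "expected_target": self.expected_target,
            "basis": self.basis.to_dict(),
            "psi_star": {k: v.tolist() for k, v in self.psi_star.items()},
            "sigma_patient": self.sigma_patient,
            "sigma_image": self.sigma_image,
            "seed": self.seed,
        }


@dataclass
class CompartmentField:
    """Piecewise-constant log-intensity offsets over Voronoi compartments."""

    seeds: np.ndarray  # (n, 2) compartment centers
    offsets: np.ndarray  # (n,) log-intensity shifts
    window: ObservationWindow
    strength: str = "moderate"

    def __post_init__(self):
        self.seeds = np.asarray(self.seeds, float).reshape(-1, 2)
        self.offsets = np.asarray(self.offsets, float)
        if self.seeds.shape[0] != self.offsets.shape[0]:
            raise ValueError("one offset per compartment")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("offsets must be finite")

    def labels(self, points) -> np.ndarray:
        """Voronoi compartment index (nearest seed) for each point."""
        pts = np.atleast_2d(np.asarray(points, float))
        d2 = ((pts[:, None, :] - self.seeds[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def offset_at(self, points) -> np.ndarray:
        return self.offsets[self.labels(points)]


def draw_hier_coefficients(config: SimulationConfig, seed=None):
    """Draw the true coefficient hierarchy.

    Returns (psi*, gamma*, delta*) where gamma*[patient][source] ~
    N(psi*, sigma_patient^2) and delta*[image][source] ~
    N(gamma*, sigma_image^2) elementwise.  Image keys are "p{n}_i{j}".
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_img = _images_per_patient(config, rng)
    gamma = {}
    delta = {}
    for n in range(config.n_patients):
        pat = f"p{n}"
        gamma[pat] = {
            k: config.psi_star[k] + config.sigma_patient * rng.standard_normal(config.basis.P)
            for k in config.source_labels
        }
        for j in range(n_img[n]):
            img = f"{pat}_i{j}"
            delta[img] = {
                k: gamma[pat][k] + config.sigma_image * rng.standard_normal(config.basis.P)
                for k in config.source_labels
            }
    return dict(config.psi_star), gamma, delta


def _images_per_patient(config, rng) -> list[int]:
    ipp = config.images_per_patient
    if isinstance(ipp, tuple):
        return [int(rng.integers(ipp[0], ipp[1] + 1)) for _ in range(config.n_patients)]
    return [int(ipp)] * config.n_patients


def simulate_source(window: ObservationWindow, expected_count: float,
                    seed=None, label="tumor", image_id="image") -> MultitypePattern:
    """Homogeneous Poisson pattern: Poisson(expected_count) uniform points."""
    if expected_count < 0:
        raise ValueError("expected count must be nonnegative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(expected_count)
    pts = np.column_stack([rng.uniform(window.x_min, window.x_max, n),
                           rng.uniform(window.y_min, window.y_max, n)])
    return MultitypePattern(pts, np.full(n, label, dtype=object), window,
                            image_id=image_id, labels=(label,))


def _log_intensity_fn(sources, delta_star, basis, beta0, compartments):
    def log_lam(points):
        points = np.atleast_2d(points)
        val = np.full(points.shape[0], beta0, dtype=float)
        for k, pat in sources.items():
            val += interaction_features(points, pat, basis) @ delta_star[k]
        if compartments is not None:
            val += compartments.offset_at(points)
        return val
    return log_lam


def simulate_target(sources: dict, delta_star: dict, basis: BasisSystem,
                    beta0: float, window: ObservationWindow, seed=None,
                    compartments: CompartmentField | None = None,
                    label="T", image_id="image",
                    grid_res: int = _GRID_RES) -> MultitypePattern:
    """Inhomogeneous Poisson target realization by thinning.

    log lambda(v) = beta0 + sum_k q_k(v)' delta*_k (+ compartment offset).
    lambda_max is the supremum of lambda over a grid_res x grid_res
    evaluation grid (default 256) times a 1.2 safety factor; the run is
    rejected (RuntimeError) if any accepted point exceeds lambda_max,
    which would signal an inadequate bound.
    """
    rng = np.random.default_rng(seed)
    log_lam = _log_intensity_fn(sources, delta_star, basis, beta0, compartments)
    gx = np.linspace(window.x_min, window.x_max, grid_res)
    gy = np.linspace(window.y_min, window.y_max, grid_res)
    mesh = np.column_stack([np.repeat(gx, grid_res), np.tile(gy, grid_res)])
    grid_log = log_lam(mesh)
    if not np.all(np.isfinite(grid_log)):
        raise ValueError("non-finite intensity on the evaluation grid")
    lam_max = _SAFETY * float(np.exp(grid_log.max()))
    n_cand = rng.poisson(lam_max * window.area)
    cand = np.column_stack([rng.uniform(window.x_min, window.x_max, n_cand),
                            rng.uniform(window.y_min, window.y_max, n_cand)])
    lam = np.exp(log_lam(cand)) if n_cand else np.empty(0)
    if n_cand and np.any(lam > lam_max):
        raise RuntimeError("thinning bound exceeded; intensity peak sharper "
                           "than the evaluation grid resolves")
    keep = rng.uniform(size=n_cand) < lam / lam_max if n_cand else np.empty(0, bool)
    pts = cand[keep]
    return MultitypePattern(pts, np.full(pts.shape[0], label, dtype=object),
                            window, image_id=image_id, labels=(label,))


def simulate_compartment_field(window: ObservationWindow, n_compartments: int,
                               strength: str = "moderate", seed=None) -> CompartmentField:
    """Voronoi partition with symmetric log-intensity offsets.

    Offsets are uniform on +/- the tier magnitude (weak 0.3, moderate 0.7,
    strong 1.2) and centered to mean zero across compartments.
    """
    if n_compartments < 1:
        raise ValueError("need at least one compartment")
    mag = COMPARTMENT_STRENGTH[strength]
    rng = np.random.default_rng(seed)
    seeds = np.column_stack([rng.uniform(window.x_min, window.x_max, n_compartments),
                             rng.uniform(window.y_min, window.y_max, n_compartments)])
    offsets = mag * rng.uniform(-1.0, 1.0, n_compartments)
    if n_compartments > 1:
        offsets -= offsets.mean()
    return CompartmentField(seeds, offsets, window, strength=strength)


def _calibrate_beta0(sources, delta_star, basis, window, expected_target,
                     compartments) -> float:
    """Baseline log-intensity such that the expected target count over the
    window (grid quadrature) equals ``expected_target``."""
    log_lam = _log_intensity_fn(sources, delta_star, basis, 0.0, compartments)
    res = 128
    gx = np.linspace(window.x_min, window.x_max, res)
    gy = np.linspace(window.y_min, window.y_max, res)
    mesh = np.column_stack([np.repeat(gx, res), np.tile(gy, res)])
    mean_factor = float(np.mean(np.exp(log_lam(mesh))))
    return float(np.log(expected_target / (window.area * mean_factor)))


def simulate_study(config: SimulationConfig, null: bool = False,
                   compartment_spec: dict | None = None):
    """Generate a full hierarchical study.

    Returns (patterns, hierarchy, truth).  ``null=True`` forces all
    interaction coefficients to zero (type-I-error mode) while keeping the
    hierarchy and densities.  ``compartment_spec`` optionally adds
    unmeasured tissue compartments: ``{"n": 3, "strength": "moderate"}``.

    ``truth`` records psi*, gamma*, delta*, per-image baselines and seeds,
    and the config, and is JSON-serializable via :func:`truth_to_json`.
    """
    master = np.random.SeedSequence(config.seed)
    coef_seed = np.random.default_rng(master.spawn(1)[0]).integers(0, 2**31 - 1)
    psi, gamma, delta = draw_hier_coefficients(config, seed=int(coef_seed))
    if null:
        zero = np.zeros(config.basis.P)
        psi = {k: zero for k in psi}
        gamma = {n: {k: zero for k in config.source_labels} for n in gamma}
        delta = {m: {k: zero for k in config.source_labels} for m in delta}

    window = config.window
    patterns = []
    img2pat, pat2coh = {}, {}
    truth = {"psi_star": psi, "gamma_star": gamma, "delta_star": delta,
             "beta0": {}, "seeds": {}, "null": null,
             "config": config.to_dict()}
    cohort_of = {f"p{n}": f"c{n % config.n_cohorts}"
                 for n in range(config.n_patients)}
    for idx, img in enumerate(sorted(delta)):
        pat = img.rsplit("_i", 1)[0]
        img2pat[img] = pat
        pat2coh[pat] = cohort_of[pat]
        seed_img = np.random.SeedSequence((config.seed, 1000 + idx))
        rng = np.random.default_rng(seed_img)
        comp = None
        if compartment_spec:
            comp = simulate_compartment_field(
                window, compartment_spec.get("n", 3),
                compartment_spec.get("strength", "moderate"),
                seed=np.random.SeedSequence((config.seed, 500000 + idx)))
        sources = {
            k: simulate_source(window, config.expected_source[k],
                               seed=rng.integers(0, 2**31 - 1), label=k,
                               image_id=img)
            for k in config.source_labels
        }
        beta0 = _calibrate_beta0(sources, delta[img], config.basis, window,
                                 config.expected_target, comp)
        target = simulate_target(sources, delta[img], config.basis, beta0,
                                 window, seed=rng.integers(0, 2**31 - 1),
                                 compartments=comp, label=config.target_label,
                                 image_id=img)
        pts = np.vstack([p.points for p in sources.values()] + [target.points])
        types = np.concatenate([p.types for p in sources.values()] + [target.types])
        labels = tuple(config.source_labels) + (config.target_label,)
        patterns.append(MultitypePattern(pts, types, window, image_id=img,
                                         labels=labels))
        truth["beta0"][img] = beta0
        truth["seeds"][img] = 1000 + idx
    hierarchy = HierarchyMap(img2pat, pat2coh)
    return patterns, hierarchy, truth


def true_sic(truth: dict, basis: BasisSystem, grid, level="cohort",
             unit=None, source=None) -> np.ndarray:
    """Evaluate a ground-truth SIC stored in a truth record."""
    source = source or list(truth["psi_star"])[0]
    if level == "cohort":
        coefs = truth["psi_star"][source]
    elif level == "patient":
        coefs = truth["gamma_star"][unit][source]
    else:
        coefs = truth["delta_star"][unit][source]
    return evaluate_sic(np.asarray(coefs, float), basis, np.asarray(grid, float))


def truth_to_json(truth: dict, path):
    """Serialize a truth record (coefficients, baselines, config, seeds)."""
    def conv(obj):
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        json.dump(conv(truth), fh, indent=2)


def truth_from_json(path) -> dict:
    with open(path) as fh:
        truth = json.load(fh)
    truth["psi_star"] = {k: np.asarray(v) for k, v in truth["psi_star"].items()}
    truth["gamma_star"] = {n: {k: np.asarray(v) for k, v in d.items()}
                           for n, d in truth["gamma_star"].items()}
    truth["delta_star"] = {m: {k: np.asarray(v) for k, v in d.items()}
                           for m, d in truth["delta_star"].items()}
    return truth
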
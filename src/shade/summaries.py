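"""Curve reconstruction, simultaneous credible bands, and summaries.

Simultaneous bands are built by the max-standardized-deviation rule: with
posterior curve draws f_1..f_S on a grid, compute the pointwise mean m(s)
and sd sd(s), take c* as the empirical level-quantile over draws of
max_s |f(s) - m(s)| / sd(s), and report m +/- c* sd.  Unlike pointwise
intervals, the resulting envelope has joint coverage over the whole
distance range, so "the band excludes zero somewhere" is a calibrated
detection rule across all distances at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BasisSystem

__all__ = [
    "CredibleBand",
    "SummaryMeasures",
    "sic_draws",
    "simultaneous_band",
    "detect_interaction",
    "summary_measures",
    "heterogeneity_mad",
]


@dataclass
class CredibleBand:
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95
    level_tag: str = "cohort"
    source: str | None = None
    target: str | None = None
    multiplier: float = np.nan  # the simultaneous critical value c*

    def __post_init__(self):
        if not (np.all(self.lower <= self.mean + 1e-12)
                and np.all(self.mean <= self.upper + 1e-12)):
            raise ValueError("band envelopes must bracket the mean")

    def contains(self, curve) -> bool:
        """Whether a curve lies inside the band at every grid point."""
        curve = np.asarray(curve, float)
        return bool(np.all((curve >= self.lower) & (curve <= self.upper)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"source": self.source, "target": self.target, "level": self.level,
             "level_tag": self.level_tag, "distance_um": self.grid,
             "mean": self.mean, "lower": self.lower, "upper": self.upper}
        )

    def plot(self, ax=None, color="C0", label=None):
        """Mean curve with the simultaneous envelope shaded; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        name = label or (f"{self.source} → {self.target}"
                         if self.source and self.target else self.level_tag)
        ax.fill_between(self.grid, self.lower, self.upper, alpha=0.25,
                        color=color, lw=0)
        ax.plot(self.grid, self.mean, color=color, label=name)
        ax.axhline(0.0, color="k", lw=0.8, ls="--")
        ax.set_xlabel("distance (µm)")
        ax.set_ylabel("SIC (log-intensity)")
        ax.legend(frameon=False)
        return ax


@dataclass
class SummaryMeasures:
    peak_location: float  # um
    peak_magnitude: float  # signed SIC value at the peak of |mean|
    persistence: float  # fraction of the interval where the band excludes 0
    strength: float  # integral of |mean| over the excluded-zero region

    def __post_init__(self):
        if not (0.0 <= self.persistence <= 1.0) or self.strength < 0:
            raise ValueError("invalid summary measures")


def sic_draws(results, level, unit, source, basis: BasisSystem, grid) -> np.ndarray:
    """Reconstruct per-draw SIC curves for one hierarchy unit.

    Thin functional wrapper over ``results.coefficient_draws`` so curve
    reconstruction can be used independently of the Results object.
    """
    coefs = results.coefficient_draws(level, unit, source)
    return coefs @ basis.design(np.asarray(grid, float)).T


def simultaneous_band(curve_draws, grid, level=0.95, level_tag="cohort",
                      source=None, target=None) -> CredibleBand:
    """Simultaneous credible band from a (draws x grid) curve matrix."""
    curve_draws = np.asarray(curve_draws, float)
    if curve_draws.ndim != 2 or curve_draws.shape[0] < 2:
        raise ValueError("need a (draws, grid) matrix with at least 2 draws")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    grid = np.asarray(grid, float)
    mean = curve_draws.mean(axis=0)
    sd = curve_draws.std(axis=0, ddof=1)
    pos = sd > 0
    if np.any(pos):
        z = np.abs(curve_draws[:, pos] - mean[pos]) / sd[pos]
        c_star = float(np.quantile(z.max(axis=1), level))
    else:
        c_star = 0.0  # all draws identical: zero-width band
    half = c_star * sd
    return CredibleBand(grid=grid, mean=mean, lower=mean - half,
                        upper=mean + half, level=level, level_tag=level_tag,
                        source=source, target=target, multiplier=c_star)


def detect_interaction(band: CredibleBand, interval) -> dict:
    """Detection verdict: does the band exclude zero anywhere in [a, b]?

    Returns ``detected`` plus the dominant ``sign`` ("positive",
    "negative", "mixed" or "none") and the grid masks where each occurs.
    """
    a, b = interval
    in_int = (band.grid >= a) & (band.grid <= b)
    if not np.any(in_int):
        raise ValueError("interval does not intersect the band grid")
    pos = in_int & (band.lower > 0)
    neg = in_int & (band.upper < 0)
    detected = bool(pos.any() or neg.any())
    if pos.any() and neg.any():
        sign = "mixed"
    elif pos.any():
        sign = "positive"
    elif neg.any():
        sign = "negative"
    else:
        sign = "none"
    return {"detected": detected, "sign": sign,
            "positive_at": band.grid[pos], "negative_at": band.grid[neg]}


def summary_measures(curve_draws, band: CredibleBand, interval) -> SummaryMeasures:
    """Prioritization summaries of one SIC over interval I.

    Peak: argmax of |mean| on grid-intersect-I with its signed value.
    Persistence: fraction of I where the simultaneous band excludes zero.
    Strength: trapezoidal integral of |mean| over the excluded-zero region.
    """
    a, b = interval
    if b <= a:
        raise ValueError("empty interval")
    mask = (band.grid >= a) & (band.grid <= b)
    if not np.any(mask):
        raise ValueError("interval does not intersect the band grid")
    grid = band.grid[mask]
    mean = band.mean[mask]
    i_peak = int(np.argmax(np.abs(mean)))
    excl = (band.lower[mask] > 0) | (band.upper[mask] < 0)
    persistence = float(np.trapezoid(excl.astype(float), grid) / (b - a))
    strength = float(np.trapezoid(np.abs(mean) * excl, grid))
    return SummaryMeasures(
        peak_location=float(grid[i_peak]),
        peak_magnitude=float(mean[i_peak]),
        persistence=persistence,
        strength=strength,
    )


def heterogeneity_mad(results, basis: BasisSystem, grid) -> pd.DataFrame:
    """Between- and within-patient heterogeneity of SIC deviations.

    For each source type: between-patient MAD is the median, over patients
    and grid points, of |posterior-mean patient SIC - posterior-mean SIC of
    the patient's cohort|; within-patient MAD is the median, over images
    and grid points, of |posterior-mean image SIC - posterior-mean SIC of
    the image's patient|.  Posterior means (not draws) enter the
    deviations.  Entries are NaN when fewer than 2 patients (between) or
    no patient with >= 2 images (within) are available.
    """
    grid = np.asarray(grid, float)
    model = results.model
    hier = model.hierarchy
    rows = []
    target = model.datasets[0].target_label
    for src in model.source_labels:
        mean_curve = {}
        for level, ids in (("cohort", model.cohort_ids),
                           ("patient", model.patient_ids),
                           ("image", model.image_ids)):
            for u in ids:
                mean_curve[(level, u)] = sic_draws(
                    results, level, u, src, basis, grid).mean(axis=0)
        between = [
            np.abs(mean_curve[("patient", n)]
                   - mean_curve[("cohort", hier.patient_to_cohort[n])])
            for n in model.patient_ids
        ]
        within = [
            np.abs(mean_curve[("image", m)]
                   - mean_curve[("patient", hier.patient(m))])
            for m in model.image_ids
            if len([i for i in hier.images_of_patient(hier.patient(m))
                    if i in model.image_ids]) >= 2
        ]
        rows.append({
            "source": src,
            "target": target,
            "between_patient_mad": (float(np.median(np.concatenate(between)))
                                    if len(model.patient_ids) >= 2 else np.nan),
            "within_patient_mad": (float(np.median(np.concatenate(within)))
                                   if within else np.nan),
        })
    return pd.DataFrame(rows)
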
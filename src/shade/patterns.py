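"""Hierarchically organized multitype point patterns.

A study is a collection of images, each a multitype point pattern (cell
centroids in um with categorical cell-type labels) observed in a
rectangular window, plus a two-level hierarchy map: image -> patient and
patient -> cohort.  Coordinates are continuous; windows are closed
axis-aligned rectangles (points on the boundary are inside).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ObservationWindow",
    "MultitypePattern",
    "HierarchyMap",
    "SchemaError",
    "HierarchyError",
    "load_cell_table",
    "write_cell_table",
    "subset_by_type",
    "validate_study",
]


class SchemaError(ValueError):
    """The cell table is missing required columns."""


class HierarchyError(ValueError):
    """The image/patient/cohort mapping is inconsistent."""


@dataclass(frozen=True)
class ObservationWindow:
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("window must have positive extent in both axes")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def widths(self) -> tuple[float, float]:
        return (self.x_max - self.x_min, self.y_max - self.y_min)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return (
            (pts[:, 0] >= self.x_min)
            & (pts[:, 0] <= self.x_max)
            & (pts[:, 1] >= self.y_min)
            & (pts[:, 1] <= self.y_max)
        )


@dataclass
class MultitypePattern:
    """Cell centroids + type labels for one image."""

    points: np.ndarray  # (n, 2) in um
    types: np.ndarray  # (n,) strings
    window: ObservationWindow
    image_id: str = "image"
    labels: tuple = None  # declared label set

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.types = np.asarray(self.types, dtype=object)
        if self.points.shape[0] != self.types.shape[0]:
            raise ValueError("points and types must be parallel")
        if self.points.size and not self.window.contains(self.points).all():
            bad = np.flatnonzero(~self.window.contains(self.points))[0]
            raise ValueError(
                f"point {tuple(self.points[bad])} lies outside the window "
                f"of image {self.image_id!r}"
            )
        if self.labels is None:
            self.labels = tuple(sorted(set(self.types.tolist())))

    def __len__(self) -> int:
        return self.points.shape[0]

    def counts(self) -> dict:
        """Per-type point counts N_type (zero entries for unused labels)."""
        out = {lab: 0 for lab in self.labels}
        for lab in self.types:
            out[lab] = out.get(lab, 0) + 1
        return out


@dataclass
class HierarchyMap:
    """image -> patient and patient -> cohort assignments."""

    image_to_patient: dict = field(default_factory=dict)
    patient_to_cohort: dict = field(default_factory=dict)

    def patient(self, image_id) -> str:
        try:
            return self.image_to_patient[image_id]
        except KeyError:
            raise HierarchyError(f"image {image_id!r} has no patient") from None

    def cohort(self, image_id) -> str:
        pat = self.patient(image_id)
        try:
            return self.patient_to_cohort[pat]
        except KeyError:
            raise HierarchyError(f"patient {pat!r} has no cohort") from None

    @property
    def images(self) -> list:
        return list(self.image_to_patient)

    @property
    def patients(self) -> list:
        return list(self.patient_to_cohort)

    @property
    def cohorts(self) -> list:
        seen = []
        for c in self.patient_to_cohort.values():
            if c not in seen:
                seen.append(c)
        return seen

    def images_of_patient(self, patient_id) -> list:
        return [m for m, n in self.image_to_patient.items() if n == patient_id]

    def patients_of_cohort(self, cohort_id) -> list:
        return [n for n, g in self.patient_to_cohort.items() if g == cohort_id]


_DEFAULT_SCHEMA = {
    "x": "x",
    "y": "y",
    "cell_type": "cell_type",
    "image_id": "image_id",
    "patient_id": "patient_id",
    "cohort_id": "cohort_id",
}


def load_cell_table(
    path,
    schema: dict | None = None,
    windows: dict | None = None,
    window_path=None,
) -> tuple[list[MultitypePattern], HierarchyMap]:
    """Read a delimited cell table into per-image patterns + hierarchy map.

    Parameters
    ----------
    path : str or file-like
        CSV with columns x, y, cell_type, image_id, patient_id, cohort_id
        (names remappable through ``schema``).
    windows : dict, optional
        image_id -> ObservationWindow.  Missing images fall back to the
        per-image bounding box; supply true image extents when possible
        because intensity integrals depend on window area.
    window_path : optional
        CSV with columns image_id, x_min, x_max, y_min, y_max.
    """
    sch = dict(_DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path)
    missing = [c for c in sch.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table is missing columns {missing}")

    windows = dict(windows or {})
    if window_path is not None:
        wdf = pd.read_csv(window_path)
        for _, row in wdf.iterrows():
            windows[str(row["image_id"])] = ObservationWindow(
                row["x_min"], row["x_max"], row["y_min"], row["y_max"]
            )

    # hierarchy consistency: every image exactly one patient, patient one cohort
    img2pat = {}
    pat2coh = {}
    for _, row in df.iterrows():
        m = str(row[sch["image_id"]])
        n = str(row[sch["patient_id"]])
        g = str(row[sch["cohort_id"]])
        if img2pat.setdefault(m, n) != n:
            raise HierarchyError(f"image {m!r} is mapped to two patients")
        if pat2coh.setdefault(n, g) != g:
            raise HierarchyError(f"patient {n!r} is mapped to two cohorts")

    labels = tuple(sorted(df[sch["cell_type"]].astype(str).unique()))
    patterns = []
    for m, sub in df.groupby(sch["image_id"], sort=True):
        m = str(m)
        pts = sub[[sch["x"], sch["y"]]].to_numpy(dtype=float)
        if m in windows:
            win = windows[m]
            if not win.contains(pts).all():
                raise ValueError(f"image {m!r} has points outside its declared window")
        else:
            win = ObservationWindow(
                pts[:, 0].min(), pts[:, 0].max(), pts[:, 1].min(), pts[:, 1].max()
            )
        patterns.append(
            MultitypePattern(
                points=pts,
                types=sub[sch["cell_type"]].astype(str).to_numpy(dtype=object),
                window=win,
                image_id=m,
                labels=labels,
            )
        )
    return patterns, HierarchyMap(img2pat, pat2coh)


def write_cell_table(path, patterns, hierarchy: HierarchyMap, window_path=None):
    """Serialize patterns + hierarchy back to the CSV dialect of load_cell_table."""
    rows = []
    for pat in patterns:
        n = hierarchy.patient(pat.image_id)
        g = hierarchy.cohort(pat.image_id)
        for (x, y), t in zip(pat.points, pat.types):
            rows.append(
                {"x": x, "y": y, "cell_type": t, "image_id": pat.image_id,
                 "patient_id": n, "cohort_id": g}
            )
    pd.DataFrame(rows, columns=list(_DEFAULT_SCHEMA.values())).to_csv(path, index=False)
    if window_path is not None:
        wrows = [
            {"image_id": p.image_id, "x_min": p.window.x_min, "x_max": p.window.x_max,
             "y_min": p.window.y_min, "y_max": p.window.y_max}
            for p in patterns
        ]
        pd.DataFrame(wrows).to_csv(window_path, index=False)


def subset_by_type(pattern: MultitypePattern, label: str) -> MultitypePattern:
    """Points of one cell type, same window and image identity."""
    if label not in pattern.labels:
        raise ValueError(f"unknown cell type {label!r}; declared: {pattern.labels}")
    keep = pattern.types == label
    return MultitypePattern(
        points=pattern.points[keep],
        types=pattern.types[keep],
        window=pattern.window,
        image_id=pattern.image_id,
        labels=pattern.labels,
    )


def validate_study(patterns, hierarchy: HierarchyMap) -> dict:
    """Consistency report for a study: counts per level, orphan detection.

    Raises HierarchyError on images without patients or patients without
    cohorts; otherwise returns a dict with images-per-patient,
    patients-per-cohort, and per-image per-type counts.
    """
    per_image_counts = {}
    for pat in patterns:
        hierarchy.cohort(pat.image_id)  # raises on orphans
        per_image_counts[pat.image_id] = pat.counts()
    imgs_per_patient = {
        n: len(hierarchy.images_of_patient(n)) for n in hierarchy.patients
    }
    pats_per_cohort = {
        g: len(hierarchy.patients_of_cohort(g)) for g in hierarchy.cohorts
    }
    totals = {}
    for c in per_image_counts.values():
        for lab, k in c.items():
            totals[lab] = totals.get(lab, 0) + k
    return {
        "n_images": len(patterns),
        "n_patients": len(hierarchy.patients),
        "n_cohorts": len(hierarchy.cohorts),
        "images_per_patient": imgs_per_patient,
        "patients_per_cohort": pats_per_cohort,
        "per_image_counts": per_image_counts,
        "per_type_totals": totals,
    }
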
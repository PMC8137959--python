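"""Synthetic stand-ins for every pipeline input.

Real inputs are (a) per-nucleus binary masks produced by a segmentation
network, (b) ROI annotation tables, (c) a per-patient clinical table
with overall survival (OS, years) and follow-up status (FUS, 1 =
deceased), and (d) raster slide images.  This module generates all four
with known ground truth:

* masks rasterized from analytic shapes (disk, ellipse, rectangle,
  star-convex blob) by the pixel-center-in-shape rule, so areas and
  extents are checkable in closed form;
* survival times drawn from a Cox model with exponential baseline via
  inverse-CDF sampling, with independent exponential censoring, so the
  true coefficients are known;
* a shape -> hazard coupling: each patient's nucleus axis-ratio
  distribution shifts with their linear predictor, so geometric features
  carry prognostic signal end-to-end.

All randomness flows through a single ``numpy.random.default_rng(seed)``
generator; identical seeds give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import shapely

from .patches import ROIAnnotation


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeSpec:
    """Analytic shape to rasterize onto a pixel grid.

    ``a`` and ``b`` are the half-axes (or half-width/half-height) in
    pixels with a >= b > 0; ``theta`` the orientation in degrees,
    counter-clockwise in image coordinates (x = column, y = row, y
    down), in [-180, 180); ``center`` in (x, y) pixels.  Blob shapes
    additionally use ``seed``, ``irregularity`` and ``n_vertices``.
    """

    kind: str  # disk | ellipse | rectangle | blob
    a: float
    b: float
    grid: tuple[int, int]  # (height, width)
    center: Optional[tuple[float, float]] = None
    theta: float = 0.0
    seed: int = 0
    irregularity: float = 0.3
    n_vertices: int = 24

    def __post_init__(self):
        if self.kind not in ("disk", "ellipse", "rectangle", "blob"):
            raise SyntheticError(f"unknown shape kind {self.kind!r}")
        if not (self.a >= self.b > 0):
            raise SyntheticError(f"require a >= b > 0, got a={self.a}, b={self.b}")
        if not (-180.0 <= self.theta < 180.0):
            raise SyntheticError(f"theta must be in [-180, 180), got {self.theta}")

    @property
    def center_xy(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        h, w = self.grid
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    @property
    def bounding_radius(self) -> float:
        if self.kind == "rectangle":
            return math.hypot(self.a, self.b)
        if self.kind == "blob":
            return self.a * (1.0 + self.irregularity)
        return self.a


def gen_blob_outline(
    seed: Union[int, np.random.Generator],
    mean_radius: float,
    irregularity: float,
    n_vertices: int,
) -> np.ndarray:
    """Star-convex closed polygon around the origin.

    Vertices sit at equally spaced polar angles with radii drawn
    uniformly in ``[mean_radius*(1-irregularity), mean_radius*(1+irregularity)]``;
    with irregularity 0 this is a regular n-gon.  Returns an (n, 2)
    array of (x, y) vertices in angle order (closed implicitly).
    """
    if n_vertices < 8:
        raise SyntheticError(f"need n_vertices >= 8, got {n_vertices}")
    if not (0 <= irregularity < 1):
        raise SyntheticError(f"need 0 <= irregularity < 1, got {irregularity}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phi = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    radii = mean_radius * (1.0 + irregularity * rng.uniform(-1.0, 1.0, size=n_vertices))
    return np.c_[radii * np.cos(phi), radii * np.sin(phi)]


def gen_mask(spec: ShapeSpec) -> np.ndarray:
    """Rasterize an analytic shape: pixel on iff its center lies inside.

    The resulting foreground is a single 8-connected component with a
    >= 2 pixel clear margin to the grid border (enforced as a
    precondition on the spec and asserted on the output).
    """
    h, w = spec.grid
    cx, cy = spec.center_xy
    r = spec.bounding_radius
    if cx - r < 2 or cy - r < 2 or cx + r > w - 3 or cy + r > h - 3:
        raise SyntheticError(
            f"shape (bounding radius {r:.1f} at ({cx:.1f},{cy:.1f})) does not fit "
            f"in grid {h}x{w} with a 2-pixel margin"
        )

    yy, xx = np.mgrid[0:h, 0:w]
    x = xx - cx
    y = yy - cy
    th = math.radians(spec.theta)
    # rotate into the shape's frame
    xr = x * math.cos(th) + y * math.sin(th)
    yr = -x * math.sin(th) + y * math.cos(th)

    if spec.kind == "disk":
        inside = x * x + y * y <= spec.a**2
    elif spec.kind == "ellipse":
        inside = (xr / spec.a) ** 2 + (yr / spec.b) ** 2 <= 1.0
    elif spec.kind == "rectangle":
        inside = (np.abs(xr) <= spec.a) & (np.abs(yr) <= spec.b)
    else:  # blob: star-convex polygon, anisotropically scaled by b/a
        poly = gen_blob_outline(spec.seed, spec.a, spec.irregularity, spec.n_vertices)
        geom = shapely.Polygon(poly)
        # undo anisotropic scaling: shape frame has y compressed by b/a
        pts_x = xr.ravel()
        pts_y = yr.ravel() * (spec.a / spec.b)
        inside = shapely.contains_xy(geom, pts_x, pts_y).reshape(h, w)

    mask = inside.astype(np.uint8)
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise SyntheticError("rasterized shape touches the grid border")
    from skimage.measure import label as _label

    _, n_comp = _label(mask, connectivity=2, return_num=True)
    if n_comp != 1:
        # very thin shapes can pinch apart under pixel-center sampling
        raise SyntheticError(
            f"rasterized shape broke into {n_comp} components (too thin: b={spec.b:.2f})"
        )
    return mask


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def _default_shape_effect(lp: float) -> float:
    """Mean nucleus axis ratio (minor/major) for a patient with linear
    predictor ``lp``: higher risk -> more elongated nuclei."""
    return float(np.clip(0.80 - 0.12 * lp, 0.30, 0.95))


@dataclass
class CohortConfig:
    """Conditions for a synthetic patient cohort.

    Defaults mirror the validation cohort scale (170 patients) with an
    exponential baseline hazard of 0.15/year and independent exponential
    censoring at 0.08/year (roughly a third of patients censored).
    ``beta`` are the true Cox coefficients on standard-normal covariates
    (``covariate_kinds`` may switch individual covariates to Bernoulli
    0/1).  Nucleus populations are star-convex blobs with diameters in
    the 10-60 px band; each patient's mean axis ratio is
    ``shape_effect(linear predictor)``.
    """

    n_patients: int = 170
    nuclei_per_patient: Union[int, tuple[int, int]] = 30
    beta: Sequence[float] = (0.8, 0.5, 0.0)
    baseline_rate: float = 0.15  # 1/years
    censor_rate: float = 0.08  # 1/years
    covariate_kinds: Optional[Sequence[str]] = None  # 'normal' | 'binary'
    shape_effect: Callable[[float], float] = _default_shape_effect
    ratio_sd: float = 0.08  # per-nucleus spread of the axis ratio
    mean_radius: float = 12.0  # px (≈ 24 px diameter at 0.25 µm/px)
    radius_jitter: float = 0.35  # relative spread of per-nucleus size
    irregularity: float = 0.15
    n_vertices: int = 24
    grid: tuple[int, int] = (72, 72)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise SyntheticError("need n_patients >= 2")
        if self.baseline_rate <= 0:
            raise SyntheticError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise SyntheticError("censor_rate must be >= 0")
        kinds = self.covariate_kinds
        if kinds is not None and len(kinds) != len(self.beta):
            raise SyntheticError(
                f"covariate_kinds length {len(kinds)} != beta length {len(self.beta)}"
            )


def gen_survival_table(config: CohortConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Clinical table only: covariates, OS, FUS (no nucleus masks).

    Survival time ``T = -log(U) / (baseline_rate * exp(x . beta))`` with
    U ~ Uniform(0,1); censoring ``C ~ Exp(censor_rate)``;
    ``OS = min(T, C)`` and ``FUS = 1`` iff the event was observed
    (T <= C).  Also carries the latent linear predictor in a
    ``_linpred`` column for generator-internal use (dropped on save).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_patients
    beta = np.asarray(config.beta, dtype=float)
    p = len(beta)
    kinds = config.covariate_kinds or ("normal",) * p

    X = np.empty((n, p))
    for k, kind in enumerate(kinds):
        if kind == "normal":
            X[:, k] = rng.normal(size=n)
        elif kind == "binary":
            X[:, k] = rng.integers(0, 2, size=n).astype(float)
        else:
            raise SyntheticError(f"unknown covariate kind {kind!r}")

    lp = X @ beta
    u = rng.uniform(size=n)
    T = -np.log(u) / (config.baseline_rate * np.exp(lp))
    if config.censor_rate > 0:
        C = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        C = np.full(n, np.inf)
    OS = np.minimum(T, C)
    FUS = (T <= C).astype(int)

    df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})
    for k in range(p):
        df[f"cov_{k}"] = X[:, k]
    df["OS"] = OS
    df["FUS"] = FUS
    df["_linpred"] = lp
    return df


def gen_cohort(
    config: CohortConfig,
) -> tuple[dict[str, list[tuple[str, int, np.ndarray]]], pd.DataFrame]:
    """Full synthetic cohort: nucleus masks plus clinical table.

    Returns ``(masks, clinical)`` where ``masks`` maps patient_id to a
    list of ``(patch_id, cell_number, mask)`` tuples (cell numbers are
    deliberately non-consecutive, as in the source data where non-tumor
    cells are discarded) and ``clinical`` has columns patient_id,
    cov_0..cov_{p-1}, OS, FUS.
    """
    rng = np.random.default_rng(config.seed)
    clinical = gen_survival_table(config, rng)

    if isinstance(config.nuclei_per_patient, int):
        lo = hi = config.nuclei_per_patient
    else:
        lo, hi = config.nuclei_per_patient

    masks: dict[str, list[tuple[str, int, np.ndarray]]] = {}
    for _, row in clinical.iterrows():
        pid = row["patient_id"]
        n_nuc = int(lo if lo == hi else rng.integers(lo, hi + 1))
        ratio_mean = config.shape_effect(float(row["_linpred"]))
        cells: list[tuple[str, int, np.ndarray]] = []
        cell_no = 0
        for i in range(n_nuc):
            cell_no += int(rng.integers(1, 4))  # non-consecutive numbering
            # retry degenerate draws (a too-thin blob can pinch apart)
            for _attempt in range(20):
                radius = config.mean_radius * float(
                    np.clip(1.0 + config.radius_jitter * rng.uniform(-1, 1), 0.3, 2.0)
                )
                ratio = float(np.clip(rng.normal(ratio_mean, config.ratio_sd), 0.3, 0.98))
                spec = ShapeSpec(
                    kind="blob",
                    a=radius,
                    b=radius * ratio,
                    grid=config.grid,
                    theta=float(rng.uniform(-180.0, 180.0)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    irregularity=config.irregularity,
                    n_vertices=config.n_vertices,
                )
                try:
                    mask = gen_mask(spec)
                    break
                except SyntheticError:
                    continue
            else:
                raise SyntheticError(f"could not generate a valid nucleus for {pid}")
            patch_id = f"{pid}_HE_0_{i // 16}"
            cells.append((patch_id, cell_no, mask))
        masks[pid] = cells

    return masks, clinical.drop(columns=["_linpred"])


# ---------------------------------------------------------------------------
# slides
# ---------------------------------------------------------------------------


def gen_slide(
    width: int,
    height: int,
    tissue_regions: Sequence[tuple[int, int, int, int]],
    seed: int = 0,
    stain: str = "HE",
    tma_id: str = "TMA001",
    patient_ids: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, list[ROIAnnotation]]:
    """Synthetic slide raster with annotated tissue rectangles.

    Pixels outside every tissue region are near-white (all channels in
    [245, 255]); pixels inside are textured mid-range noise (all
    channels in [70, 200]), so the downstream whiteness filter keeps
    exactly the tissue tiling.  Each region becomes one ROIAnnotation
    ``(x0, y0, x1, y1)`` using the upper-left / lower-right convention.
    """
    rng = np.random.default_rng(seed)
    img = rng.integers(245, 256, size=(height, width, 3), dtype=np.int64).astype(np.uint8)
    rois = []
    for k, (x0, y0, x1, y1) in enumerate(tissue_regions):
        if not (0 <= x0 < x1 <= width and 0 <= y0 < y1 <= height):
            raise SyntheticError(f"tissue region {k} out of bounds")
        tex = rng.integers(70, 201, size=(y1 - y0, x1 - x0, 3), dtype=np.int64)
        img[y0:y1, x0:x1] = tex.astype(np.uint8)
        pid = patient_ids[k] if patient_ids is not None else f"P{k:04d}"
        rois.append(
            ROIAnnotation(
                patient_id=pid, tma_id=tma_id, stain=stain, x0=x0, y0=y0, x1=x1, y1=y1
            )
        )
    return img, rois
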
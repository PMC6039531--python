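"""Synthetic cohort generator with known ground truth.

Real inputs to this pipeline are 40X H&E whole-slide images: several tissue
samples on a near-white glass background, tumor regions with more or less
ragged boundaries and internal holes, and occasional one-patch satellite
specks (tumor spread through air spaces, STAS).  This module emulates those
inputs at heatmap-cell granularity — each cell stands for one image patch —
and then renders cells to pixel textures, so the ground-truth geometry of
every generated region is exact by construction.

Survival outcomes follow a proportional-hazards model driven by chosen
shape features, ``T = -ln(U) / (h0 * exp(x' beta))``, with independent
exponential censoring whose rate is solved numerically to hit a target
censored fraction.  Every generator is a pure function of its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from ._constants import NON_MALIGNANT, TUMOR, WHITE

__all__ = [
    "ShapeSpec",
    "CohortSpec",
    "DegenerateShapeError",
    "gen_tumor_mask",
    "gen_label_map",
    "render_slide",
    "gen_survival",
    "simulate_cohort",
]


class DegenerateShapeError(ValueError):
    """The requested shape cannot be hosted (too small for holes/satellites)."""


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one synthetic tumor shape.

    base_radius : mean boundary radius in cells (>= 2)
    aspect : elongation of the supporting ellipse (>= 1)
    roughness : amplitude of the radial boundary perturbation (>= 0);
        0 gives a smooth ellipse
    n_harmonics : number of cosine harmonics in the perturbation
    n_holes : one-cell holes punched strictly inside the body
    n_satellites : one-cell specks disjoint from the body (STAS-like)
    seed : RNG seed; same spec + same seed => identical mask
    """

    base_radius: float = 8.0
    aspect: float = 1.0
    roughness: float = 0.0
    n_harmonics: int = 6
    n_holes: int = 0
    n_satellites: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.base_radius < 2:
            raise ValueError("base_radius must be >= 2")
        if self.aspect < 1:
            raise ValueError("aspect must be >= 1")
        if self.roughness < 0:
            raise ValueError("roughness must be >= 0")
        if min(self.n_harmonics, self.n_holes, self.n_satellites) < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated patient cohort.

    The survival model is proportional hazards on patient-level shape
    features: hazard ``h0 * exp(x' beta)`` with ``beta`` given per feature
    in log-hazard units on the raw (cell) feature scale.  Defaults drive
    risk through boundary roughness (``pa_ratio_main``) and total tumor
    burden (``area_sum``), the two feature families the survival analysis
    is designed to detect.
    """

    n_patients: int = 150
    tissues_per_image: int = 1
    radius_range: tuple[float, float] = (6.0, 16.0)
    aspect_range: tuple[float, float] = (1.0, 1.8)
    roughness_range: tuple[float, float] = (0.0, 0.6)
    hole_range: tuple[int, int] = (0, 4)
    satellite_range: tuple[int, int] = (0, 3)
    beta: dict[str, float] = field(
        default_factory=lambda: {"pa_ratio_main": 0.08, "area_sum": 0.0017}
    )
    baseline_hazard: float = 5e-5  # events per day
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")


_CHEB3 = np.ones((3, 3), dtype=bool)


def _dilate_cheb(mask: np.ndarray, radius: int) -> np.ndarray:
    from scipy.ndimage import binary_dilation

    if radius <= 0:
        return mask.copy()
    return binary_dilation(mask, structure=np.ones((2 * radius + 1,) * 2, bool))


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import label

    labels, n = label(mask, structure=_CHEB3)
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (1 + int(np.argmax(sizes)))


def _greedy_separated(candidates: np.ndarray, k: int, min_cheb: int,
                      rng: np.random.Generator) -> list[tuple[int, int]]:
    """Pick k candidate cells with pairwise Chebyshev distance >= min_cheb."""
    order = rng.permutation(len(candidates))
    chosen: list[tuple[int, int]] = []
    for idx in order:
        r, c = map(int, candidates[idx])
        if any(max(abs(r - r2), abs(c - c2)) < min_cheb for r2, c2 in chosen):
            continue
        chosen.append((r, c))
        if len(chosen) == k:
            break
    return chosen


def gen_tumor_mask(spec: ShapeSpec) -> np.ndarray:
    """Rasterize one tumor shape as a boolean grid.

    The body boundary is the radial function
    ``r(theta) = base_radius * (1 + sum_k a_k cos(k theta + phi_k))``
    with harmonic amplitudes scaled by ``roughness``, applied to an ellipse
    with the given aspect.  The body is a single 8-connected component;
    holes are then punched strictly interior (one cell each, mutually
    non-adjacent), and satellites are added as one-cell specks at Chebyshev
    distance 2 from the body so they stay 8-disjoint.
    """
    rng = np.random.default_rng(spec.seed)
    k = np.arange(1, spec.n_harmonics + 1)
    if spec.n_harmonics > 0:
        amps = spec.roughness * rng.uniform(-1.0, 1.0, spec.n_harmonics) / np.sqrt(k)
        phases = rng.uniform(0.0, 2 * np.pi, spec.n_harmonics)
    else:
        amps = np.zeros(0)
        phases = np.zeros(0)

    rmax = spec.base_radius * spec.aspect * (1.0 + np.abs(amps).sum())
    half = int(np.ceil(rmax)) + 3
    size = 2 * half + 1
    cy = cx = half
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - cy
    dx = (xx - cx) / spec.aspect
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    perturb = np.zeros_like(theta)
    for a, kk, ph in zip(amps, k, phases):
        perturb += a * np.cos(kk * theta + ph)
    r_theta = spec.base_radius * np.clip(1.0 + perturb, 0.3, None)
    body = rho <= r_theta
    body = _largest_component(body)

    mask = body.copy()
    if spec.n_holes > 0:
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(body, structure=_CHEB3)
        holes = _greedy_separated(np.argwhere(interior), spec.n_holes, 2, rng)
        if len(holes) < spec.n_holes:
            raise DegenerateShapeError(
                f"shape too small for {spec.n_holes} holes "
                f"(placed {len(holes)})"
            )
        for r, c in holes:
            mask[r, c] = False

    if spec.n_satellites > 0:
        ring = _dilate_cheb(body, 2) & ~_dilate_cheb(body, 1)
        # keep away from the grid border so later dilation stays in frame
        ring[:2, :] = ring[-2:, :] = False
        ring[:, :2] = ring[:, -2:] = False
        sats = _greedy_separated(np.argwhere(ring), spec.n_satellites, 3, rng)
        if len(sats) < spec.n_satellites:
            raise DegenerateShapeError(
                f"not enough room for {spec.n_satellites} satellites "
                f"(placed {len(sats)})"
            )
        for r, c in sats:
            mask[r, c] = True
    return mask


@dataclass
class LabelMapTruth:
    """Ground-truth bookkeeping for one generated label map."""

    n_samples: int
    sample_offsets: list[tuple[int, int]]
    n_tumor_regions: list[int]  # per sample: 1 body + satellites
    n_holes: list[int]


def gen_label_map(specs, canvas: tuple[int, int] | None = None, rim: int = 2,
                  positions=None):
    """Place tissue samples on a white canvas and label every cell.

    Each sample is a tumor mask wrapped in a non-malignant rim (Chebyshev
    dilation of ``rim`` cells), so satellites sit inside the tissue and
    punched holes read as non-malignant cells enclosed by tumor.  Samples
    are packed left-to-right unless explicit top-left ``positions`` are
    given; any overlap of tissue extents or violation of the one-cell white
    margin is an error.  ``canvas=None`` sizes the canvas to fit.

    Returns ``(label_map, truth)`` with labels 0=tumor, 1=non-malignant,
    2=white.
    """
    specs = list(specs)
    if not specs:
        canvas = tuple(int(v) for v in (canvas or (8, 8)))
        return np.full(canvas, WHITE, dtype=np.int8), LabelMapTruth(0, [], [], [])

    masks = [gen_tumor_mask(s) for s in specs]
    tissues = [_dilate_cheb(m, rim) for m in masks]
    if canvas is None:
        height = max(t.shape[0] for t in tissues) + 2
        width = sum(t.shape[1] + 1 for t in tissues) + 1
        canvas = (height, width)
    canvas = tuple(int(v) for v in canvas)
    labels = np.full(canvas, WHITE, dtype=np.int8)

    if positions is None:
        positions = []
        row_r = 1
        col_c = 1
        row_height = 0
        for t in tissues:
            h, w = t.shape
            if col_c + w + 1 > canvas[1]:
                row_r += row_height + 1
                col_c = 1
                row_height = 0
            positions.append((row_r, col_c))
            col_c += w + 1
            row_height = max(row_height, h)
    occupied = np.zeros(canvas, dtype=bool)
    truth = LabelMapTruth(len(specs), [], [], [])
    for spec, mask, tissue, (r0, c0) in zip(specs, masks, tissues, positions):
        h, w = tissue.shape
        if r0 < 1 or c0 < 1 or r0 + h > canvas[0] - 1 or c0 + w > canvas[1] - 1:
            raise ValueError(
                "tissue sample does not fit the canvas with a 1-cell margin"
            )
        window = occupied[r0:r0 + h, c0:c0 + w]
        if (window & tissue).any():
            raise ValueError("tissue samples overlap")
        window |= tissue
        sub = labels[r0:r0 + h, c0:c0 + w]
        sub[tissue] = NON_MALIGNANT
        sub[mask] = TUMOR
        truth.sample_offsets.append((r0, c0))
        truth.n_tumor_regions.append(1 + spec.n_satellites)
        truth.n_holes.append(spec.n_holes)
    return labels, truth


# class-conditional texture parameters: (background RGB, blob RGB, n_blobs)
_TEXTURES = {
    WHITE: ((248, 246, 248), None, 0),
    NON_MALIGNANT: ((234, 186, 208), (168, 110, 170), 5),
    TUMOR: ((214, 160, 196), (96, 48, 132), 32),
}


def _render_patch(cls: int, size: int, rng: np.random.Generator) -> np.ndarray:
    base, blob, n_blobs = _TEXTURES[cls]
    patch = np.empty((size, size, 3), dtype=np.float64)
    patch[:] = base
    patch += rng.normal(0.0, 4.0, patch.shape)
    if n_blobs:
        yy, xx = np.mgrid[0:size, 0:size]
        radius = max(size / 12.0, 1.0)
        centers = rng.uniform(0, size, (n_blobs, 2))
        for cy, cx in centers:
            inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            patch[inside] = blob + rng.normal(0.0, 6.0, 3)
    return np.clip(patch, 0, 255).astype(np.uint8)


def render_slide(label_map: np.ndarray, patch_size: int = 32,
                 seed: int = 0) -> np.ndarray:
    """Render a label grid to an RGB image, one texture tile per cell.

    White cells render near-white (mean intensity above any sensible white
    threshold); tumor cells carry dense dark-purple blobs on a pink ground;
    non-malignant cells sparse purple blobs on a lighter pink ground.  The
    three class-conditional color statistics are separable by the reference
    patch classifier.  Deterministic in ``seed``.
    """
    if patch_size < 8:
        raise ValueError("patch_size must be >= 8")
    label_map = np.asarray(label_map)
    rng = np.random.default_rng(seed)
    h, w = label_map.shape
    img = np.empty((h * patch_size, w * patch_size, 3), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            img[
                i * patch_size:(i + 1) * patch_size,
                j * patch_size:(j + 1) * patch_size,
            ] = _render_patch(int(label_map[i, j]), patch_size, rng)
    return img


def render_patch_set(n_per_class: int, patch_size: int = 32, seed: int = 0):
    """Render a labeled patch set, ``n_per_class`` patches of each class.

    Returns ``(patches, labels)`` with patches uint8 of shape
    ``(3 * n_per_class, patch_size, patch_size, 3)`` and integer labels in
    the fixed class order.  Used to train and evaluate patch classifiers.
    """
    rng = np.random.default_rng(seed)
    patches = []
    labels = []
    for cls in (TUMOR, NON_MALIGNANT, WHITE):
        for _ in range(n_per_class):
            patches.append(_render_patch(cls, patch_size, rng))
            labels.append(cls)
    return np.stack(patches), np.asarray(labels)


def _solve_censor_rate(hazards: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate c with E[censored fraction] = censor_rate.

    With event hazard h_i and independent Exp(c) censoring,
    P(censored_i) = c / (c + h_i); solve mean_i over a wide log bracket.
    """

    def frac(log_c):
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - censor_rate

    lo, hi = np.log(hazards.min()) - 20, np.log(hazards.max()) + 20
    return float(np.exp(brentq(frac, lo, hi, xtol=1e-12)))


def gen_survival(features: np.ndarray, cohort: CohortSpec):
    """Draw (time, event) per patient from the proportional-hazards model.

    ``features`` must have one column per entry of ``cohort.beta`` (in
    order).  Event times are ``-ln(U) / (h0 * exp(x' beta))``; censoring is
    exponential with rate calibrated so the expected censored fraction
    matches ``cohort.censor_rate``; ``event = 1`` iff the event precedes
    censoring.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    beta = np.asarray(list(cohort.beta.values()), dtype=float)
    if features.shape[1] != beta.size:
        raise ValueError(
            f"features have {features.shape[1]} columns but beta has "
            f"{beta.size} entries"
        )
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    rng = np.random.default_rng(cohort.seed)
    hazards = cohort.baseline_hazard * np.exp(features @ beta)
    t_event = rng.exponential(1.0 / hazards)
    if cohort.censor_rate == 0.0:
        return t_event, np.ones(len(t_event), dtype=int)
    if cohort.censor_rate == 1.0:
        return t_event * 0.5, np.zeros(len(t_event), dtype=int)
    c = _solve_censor_rate(hazards, cohort.censor_rate)
    t_cens = rng.exponential(1.0 / c, size=len(t_event))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def _draw_clinical(n: int, rng: np.random.Generator):
    """Clinical covariates with realistic mixes, independent of the hazard."""
    import pandas as pd

    return pd.DataFrame(
        {
            "age": np.round(rng.normal(65.0, 8.0, n), 1),
            "sex": rng.choice(["male", "female"], n, p=[0.5, 0.5]),
            "smoking": rng.choice(["ever", "never"], n, p=[0.6, 0.4]),
            "stage": rng.choice(
                ["I", "II", "III", "IV"], n, p=[0.60, 0.20, 0.13, 0.07]
            ),
        }
    )


def simulate_cohort(cohort: CohortSpec, canvas: tuple[int, int] | None = None,
                    prob_noise: float = 0.15):
    """Simulate a full cohort at label-map granularity.

    For each patient: draw shape specs, build the ground-truth label map,
    run the real region/feature pipeline on it (tumor-class probability on
    tumor cells is ``1 - prob_noise * U`` so the mean-probability feature
    varies), aggregate to the patient level, and finally draw survival from
    the chosen true features.

    Returns ``(features_df, clinical_df, label_maps, specs_per_patient)``
    where ``clinical_df`` has patient_id, time_days, event, age, sex,
    smoking, stage.
    """
    import pandas as pd

    from .features import FEATURE_NAMES, patient_aggregate, tissue_feature_vector
    from .regions import extract_tumor_regions, segment_tissue_regions

    rng = np.random.default_rng(cohort.seed)
    rows = []
    label_maps = []
    all_specs = []
    for pid in range(cohort.n_patients):
        specs = []
        for t in range(cohort.tissues_per_image):
            specs.append(
                ShapeSpec(
                    base_radius=rng.uniform(*cohort.radius_range),
                    aspect=rng.uniform(*cohort.aspect_range),
                    roughness=rng.uniform(*cohort.roughness_range),
                    n_holes=int(rng.integers(cohort.hole_range[0],
                                             cohort.hole_range[1] + 1)),
                    n_satellites=int(rng.integers(cohort.satellite_range[0],
                                                  cohort.satellite_range[1] + 1)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
        labels, _truth = gen_label_map(specs, canvas)
        label_maps.append(labels)
        all_specs.append(specs)

        prob = np.zeros(labels.shape + (3,))
        prob[..., 2] = 1.0
        tumor_cells = labels == TUMOR
        tp = 1.0 - prob_noise * rng.uniform(0.0, 1.0, int(tumor_cells.sum()))
        prob[tumor_cells, 0] = tp
        prob[tumor_cells, 2] = 0.0
        prob[tumor_cells, 1] = 1.0 - tp
        nm = labels == NON_MALIGNANT
        prob[nm, 1] = 1.0
        prob[nm, 2] = 0.0

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vectors = []
            for tissue in segment_tissue_regions(labels):
                regs = extract_tumor_regions(tissue, labels)
                vec = tissue_feature_vector(tissue, regs, prob)
                if vec is not None:
                    vectors.append(vec)
            agg = patient_aggregate(vectors)
        if agg is None:
            agg = {name: np.nan for name in FEATURE_NAMES}
        agg["patient_id"] = f"P{pid:04d}"
        rows.append(agg)

    features_df = pd.DataFrame(rows).set_index("patient_id")[list(FEATURE_NAMES)]
    true_cols = features_df[list(cohort.beta.keys())].to_numpy()
    time, event = gen_survival(
        true_cols, replace(cohort, seed=int(rng.integers(0, 2**31 - 1)))
    )
    clinical = _draw_clinical(cohort.n_patients, rng)
    clinical.insert(0, "patient_id", features_df.index)
    clinical.insert(1, "time_days", np.maximum(np.round(time, 2), 0.01))
    clinical.insert(2, "event", event)
    return features_df, clinical, label_maps, all_specs
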
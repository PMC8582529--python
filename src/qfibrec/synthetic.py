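"""Seeded synthetic SHG/TPEF-like imagery and synthetic patient cohorts.

Two generators, both fully deterministic per seed:

``generate_sample``
    Renders a two-channel tile mosaic (channel 1: collagen signal, channel 2:
    cell-structure background) with known ground truth: straight thick fibers
    of controlled length/width/orientation and larger elliptical aggregate
    patches, placed inside one of three disjoint region masks (portal, septal,
    fibrillar).  The ground-truth fiber list and the rendered collagen
    footprint are carried on the sample so downstream measurements can be
    checked exactly.

``generate_cohort``
    Produces an n-patient feature table over the full 176-feature taxonomy
    together with outcome records.  A latent risk index is a linear
    combination of a planted subset of min-max-normalized features plus
    Gaussian noise; the top ``prevalence_early`` fraction by latent index is
    labelled as early recurrence.  Survival times are exponential with
    log-rate linear in the latent index, with independent uniform censoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter, binary_dilation

from .taxonomy import (
    DEFAULT_TAXONOMY,
    FeatureTaxonomy,
    REGIONS,
    REGION_WORD,
    STRING_SUMMARIES,
    PATTERNS,
    cell_suffix,
)

# ---------------------------------------------------------------------------
# image generator
# ---------------------------------------------------------------------------


@dataclass
class SimImageParams:
    """Geometry and content of one synthetic two-channel mosaic.

    Defaults render one 5x5 mosaic of 512 px tiles at 2 um/px (a desk-scale
    stand-in for multi-tile whole-section scans).  Fiber sizes default to
    areas well below the aggregation threshold so the fiber/patch pattern
    split is unambiguous.
    """

    tile_px: int = 512
    pixel_size_um: float = 2.0
    n_tiles: int = 5  # tiles per mosaic side
    fibers_per_region: Mapping[str, int] = field(
        default_factory=lambda: {"portal": 6, "septal": 4, "fibrillar": 10}
    )
    fiber_length_range_um: tuple[float, float] = (15.0, 50.0)
    fiber_width_range_um: tuple[float, float] = (2.0, 4.0)
    aggregate_patch_count: int = 2
    patch_area_range_um2: tuple[float, float] = (450.0, 900.0)
    fiber_intensity: float = 200.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.tile_px <= 0 or self.n_tiles <= 0:
            raise ValueError("tile_px and n_tiles must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for lo, hi, what in (
            (*self.fiber_length_range_um, "fiber_length_range_um"),
            (*self.fiber_width_range_um, "fiber_width_range_um"),
            (*self.patch_area_range_um2, "patch_area_range_um2"),
        ):
            if not lo < hi:
                raise ValueError(f"{what}: min must be < max, got ({lo}, {hi})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        tile_um = self.tile_px * self.pixel_size_um
        if self.fiber_length_range_um[1] > tile_um:
            raise ValueError(
                f"inconsistent geometry: max fiber length "
                f"{self.fiber_length_range_um[1]} um exceeds tile size {tile_um} um"
            )
        unknown = set(self.fibers_per_region) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown regions in fibers_per_region: {sorted(unknown)}")


@dataclass
class GroundTruthFiber:
    """One planted collagen structure (straight fiber or aggregate patch)."""

    centerline: np.ndarray  # (k, 2) ordered (row, col) subpixel coordinates
    length_um: float
    width_um: float
    orientation_deg: float  # in [0, 180)
    region: str
    pattern: str  # 'aggregated' or 'distributed'

    def arc_length_px(self) -> float:
        d = np.diff(self.centerline.astype(float), axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())

    def centerline_pixels(self) -> np.ndarray:
        """Centerline rounded to integer pixel indices."""
        return np.round(self.centerline).astype(int)


@dataclass
class SyntheticSample:
    """Two-channel synthetic image with ground truth bookkeeping."""

    shg: np.ndarray
    tpef: np.ndarray
    region_masks: dict[str, np.ndarray]
    truth_fibers: list[GroundTruthFiber]
    pixel_size_um: float
    truth_mask: np.ndarray | None = None  # rendered collagen footprint

    @property
    def shape(self) -> tuple[int, int]:
        return self.shg.shape


def _region_stripes(size: int) -> dict[str, np.ndarray]:
    """Three disjoint vertical stripes covering the whole frame."""
    masks = {}
    b1, b2 = size // 3, 2 * size // 3
    cols = np.arange(size)
    for region, (lo, hi) in zip(REGIONS, ((0, b1), (b1, b2), (b2, size))):
        m = np.zeros((size, size), dtype=bool)
        m[:, lo:hi] = True
        masks[region] = m
    assert sum(m.sum() for m in masks.values()) == size * size
    return masks


def _stripe_bounds(size: int) -> dict[str, tuple[int, int]]:
    b1, b2 = size // 3, 2 * size // 3
    return {"portal": (0, b1), "septal": (b1, b2), "fibrillar": (b2, size)}


def _segment_footprint(
    size: int, cy: float, cx: float, theta_deg: float, length_px: float, width_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean footprint of a thick straight segment, plus its centerline pixels."""
    th = np.deg2rad(theta_deg)
    # image convention: x = columns, y = rows (y grows downward); orientation is
    # measured from the +x axis
    dx, dy = np.cos(th), -np.sin(th)
    hx, hy = dx * length_px / 2, dy * length_px / 2
    p0 = np.array([cy - hy, cx - hx])
    p1 = np.array([cy + hy, cx + hx])
    half_w = max(width_px, 1.0) / 2.0

    pad = int(np.ceil(half_w)) + 2
    r_lo = max(0, int(np.floor(min(p0[0], p1[0]))) - pad)
    r_hi = min(size, int(np.ceil(max(p0[0], p1[0]))) + pad + 1)
    c_lo = max(0, int(np.floor(min(p0[1], p1[1]))) - pad)
    c_hi = min(size, int(np.ceil(max(p0[1], p1[1]))) + pad + 1)
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
    # flat-capped ribbon: perpendicular distance to the axis within the half
    # width AND axial projection within [0, L]
    v = p1 - p0
    vv = v @ v
    w_r, w_c = rr - p0[0], cc - p0[1]
    t = (w_r * v[0] + w_c * v[1]) / max(vv, 1e-12)
    tc = np.clip(t, 0.0, 1.0)
    perp = np.hypot(w_r - tc * v[0], w_c - tc * v[1])
    local = (t >= 0.0) & (t <= 1.0) & (perp <= width_px / 2.0 - 1e-9)

    foot = np.zeros((size, size), dtype=bool)
    foot[r_lo:r_hi, c_lo:c_hi] = local

    n_pts = max(int(np.ceil(length_px)), 2)
    ts = np.linspace(0.0, 1.0, n_pts)
    centerline = p0[None, :] + ts[:, None] * v  # subpixel (row, col) coordinates
    return foot, centerline


def _ellipse_footprint(
    size: int, cy: float, cx: float, theta_deg: float, a_px: float, b_px: float
) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    pad = int(np.ceil(a_px)) + 2
    r_lo = max(0, int(np.floor(cy)) - pad)
    r_hi = min(size, int(np.ceil(cy)) + pad + 1)
    c_lo = max(0, int(np.floor(cx)) - pad)
    c_hi = min(size, int(np.ceil(cx)) + pad + 1)
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
    u = (cc - cx) * np.cos(th) - (rr - cy) * np.sin(th)
    v = (cc - cx) * np.sin(th) + (rr - cy) * np.cos(th)
    local = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    foot = np.zeros((size, size), dtype=bool)
    foot[r_lo:r_hi, c_lo:c_hi] = local
    return foot


def _place(
    rng: np.random.Generator,
    size: int,
    bounds: tuple[int, int],
    half_extent_x,
    half_extent_y,
    occupancy: np.ndarray,
    render,
    max_tries: int = 200,
):
    """Rejection-sample a placement whose footprint avoids existing structures."""
    lo, hi = bounds
    for _ in range(max_tries):
        theta = rng.uniform(0.0, 180.0)
        ex, ey = half_extent_x(theta), half_extent_y(theta)
        if lo + ex >= hi - ex or ey >= size - ey:
            continue
        cx = rng.uniform(lo + ex, hi - ex)
        cy = rng.uniform(ey, size - ey)
        out = render(cy, cx, theta)
        foot = out[0] if isinstance(out, tuple) else out
        grown = binary_dilation(foot, iterations=3)
        if not (grown & occupancy).any():
            occupancy |= grown
            return cy, cx, theta, out
    raise RuntimeError(
        "could not place structure without overlap; "
        "reduce fiber counts or sizes for this geometry"
    )


def generate_sample(params: SimImageParams) -> SyntheticSample:
    """Render a seeded synthetic two-channel mosaic with ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    size = params.tile_px * params.n_tiles
    px = params.pixel_size_um

    shg = np.zeros((size, size), dtype=np.float64)
    occupancy = np.zeros((size, size), dtype=bool)
    truth_mask = np.zeros((size, size), dtype=bool)
    truth: list[GroundTruthFiber] = []
    stripe = _stripe_bounds(size)

    # aggregate patches first (largest structures place most easily early)
    for i in range(params.aggregate_patch_count):
        region = REGIONS[i % len(REGIONS)]
        area = rng.uniform(*params.patch_area_range_um2) / px**2  # px^2
        aspect = rng.uniform(1.5, 3.0)
        b = np.sqrt(area / (np.pi * aspect))
        a = aspect * b
        margin = a + 3

        cy, cx, theta, foot = _place(
            rng,
            size,
            stripe[region],
            lambda th, m=margin: m,
            lambda th, m=margin: m,
            occupancy,
            lambda cy, cx, th: _ellipse_footprint(size, cy, cx, th, a, b),
        )
        shg[foot] = np.maximum(shg[foot], params.fiber_intensity * rng.uniform(0.8, 1.2))
        truth_mask |= foot
        # centerline along the major axis
        th = np.deg2rad(theta)
        dx, dy = np.cos(th), -np.sin(th)
        n_pts = max(int(2 * a), 2)
        ts = np.linspace(-a, a, n_pts)
        pts = np.c_[cy + ts * dy, cx + ts * dx]
        truth.append(
            GroundTruthFiber(
                centerline=pts,
                length_um=2 * a * px,
                width_um=2 * b * px,
                orientation_deg=theta % 180.0,
                region=region,
                pattern="aggregated",
            )
        )

    for region in REGIONS:
        n_fibers = int(params.fibers_per_region.get(region, 0))
        for _ in range(n_fibers):
            length = rng.uniform(*params.fiber_length_range_um) / px
            width = max(rng.uniform(*params.fiber_width_range_um) / px, 1.0)
            margin = width / 2 + 2

            def hx(th, L=length, m=margin):
                return abs(np.cos(np.deg2rad(th))) * L / 2 + m

            def hy(th, L=length, m=margin):
                return abs(np.sin(np.deg2rad(th))) * L / 2 + m

            cy, cx, theta, (foot, centerline) = _place(
                rng,
                size,
                stripe[region],
                hx,
                hy,
                occupancy,
                lambda cy, cx, th: _segment_footprint(size, cy, cx, th, length, width),
            )
            shg[foot] = np.maximum(
                shg[foot], params.fiber_intensity * rng.uniform(0.8, 1.2)
            )
            truth_mask |= foot
            truth.append(
                GroundTruthFiber(
                    centerline=centerline,
                    length_um=length * px,
                    width_um=width * px,
                    orientation_deg=theta % 180.0,
                    region=region,
                    pattern="distributed",
                )
            )

    if params.noise_sd > 0:
        shg = np.clip(shg + rng.normal(0.0, params.noise_sd, shg.shape), 0.0, None)

    # cell-structure channel: smooth texture with holes at collagen sites
    tex = rng.normal(0.0, 1.0, shg.shape)
    tex = gaussian_filter(tex, sigma=max(size / 40, 4))
    sd = tex.std()
    tpef = 60.0 + 25.0 * (tex / sd if sd > 0 else tex)
    tpef[truth_mask] = 0.0
    tpef = np.clip(tpef, 0.0, None)

    return SyntheticSample(
        shg=shg,
        tpef=tpef,
        region_masks=_region_stripes(size),
        truth_fibers=truth,
        pixel_size_um=px,
        truth_mask=truth_mask,
    )


# ---------------------------------------------------------------------------
# sample I/O: 2-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------


def _rle_encode(mask: np.ndarray) -> list[list[int]]:
    flat = np.asarray(mask, dtype=bool).ravel()
    if not flat.any():
        return []
    padded = np.concatenate([[False], flat, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[::2], changes[1::2]
    return [[int(s), int(e - s)] for s, e in zip(starts, ends)]


def _rle_decode(runs: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in runs:
        flat[start : start + length] = True
    return flat.reshape(shape)


def write_sample(sample: SyntheticSample, stem: str | Path) -> tuple[Path, Path]:
    """Write a sample as 2-page TIFF (SHG, TPEF) plus a JSON sidecar."""
    stem = Path(stem)
    tif_path = stem.with_suffix(".tif")
    json_path = stem.with_suffix(".json")
    stack = np.stack([sample.shg, sample.tpef]).astype(np.float32)
    tifffile.imwrite(tif_path, stack)
    sidecar = {
        "pixel_size_um": sample.pixel_size_um,
        "shape": list(sample.shape),
        "region_masks_rle": {
            r: _rle_encode(m) for r, m in sample.region_masks.items()
        },
        "truth_fibers": [
            {
                "centerline": f.centerline.tolist(),
                "length_um": f.length_um,
                "width_um": f.width_um,
                "orientation_deg": f.orientation_deg,
                "region": f.region,
                "pattern": f.pattern,
            }
            for f in sample.truth_fibers
        ],
    }
    json_path.write_text(json.dumps(sidecar))
    return tif_path, json_path


def read_sample(stem: str | Path) -> SyntheticSample:
    stem = Path(stem)
    stack = tifffile.imread(stem.with_suffix(".tif"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    shape = tuple(meta["shape"])
    masks = {
        r: _rle_decode(runs, shape) for r, runs in meta["region_masks_rle"].items()
    }
    fibers = [
        GroundTruthFiber(
            centerline=np.asarray(f["centerline"], dtype=float),
            length_um=f["length_um"],
            width_um=f["width_um"],
            orientation_deg=f["orientation_deg"],
            region=f["region"],
            pattern=f["pattern"],
        )
        for f in meta["truth_fibers"]
    ]
    return SyntheticSample(
        shg=np.asarray(stack[0], dtype=np.float64),
        tpef=np.asarray(stack[1], dtype=np.float64),
        region_masks=masks,
        truth_fibers=fibers,
        pixel_size_um=float(meta["pixel_size_um"]),
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

#: planted signal used by default: a mix of direct and ratio features that
#: echoes the kind of mixture selected in published collagen risk models
DEFAULT_TRUE_FEATURES = (
    "SHG",
    "NoThickStrS",
    "Fibrillar",
    "StrOrientation",
    "NoShortStr/NoLongStr",
    "SeptalAGG/Septal",
)
DEFAULT_TRUE_COEFFICIENTS = (1.0, 0.9, -0.8, 0.6, -1.0, -0.7)


@dataclass
class CohortSimParams:
    """Statistical design of a synthetic surgical cohort.

    The defaults mirror the study conditions the model-construction stage is
    meant to operate under: 64 patients of whom 22 recur early, a planted
    linear signal in a handful of collagen features, moderate latent noise,
    and a weak AFP/index correlation.
    """

    n: int = 64
    prevalence_early: float = 22 / 64
    true_feature_names: Sequence[str] = DEFAULT_TRUE_FEATURES
    true_coefficients: Sequence[float] = DEFAULT_TRUE_COEFFICIENTS
    noise_sd: float = 0.3
    censor_rate: float = 0.2
    afp_corr: float = 0.2
    severity_corr: float = 0.5  # cross-feature correlation via a severity factor
    seed: int = 0

    def validate(self, taxonomy: FeatureTaxonomy) -> None:
        if self.n < 3:
            raise ValueError("n must be at least 3")
        if not 0 < self.prevalence_early < 1:
            raise ValueError("prevalence_early must lie in (0, 1)")
        if len(self.true_feature_names) != len(self.true_coefficients):
            raise ValueError("true_feature_names and true_coefficients lengths differ")
        unknown = [n for n in self.true_feature_names if n not in taxonomy]
        if unknown:
            raise ValueError(f"unknown feature names: {unknown}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if not -1 <= self.afp_corr <= 1:
            raise ValueError("afp_corr must lie in [-1, 1]")


@dataclass
class CohortRecord:
    """Per-patient outcome and covariate record."""

    patient_id: str
    df_months: float
    recurrence_event: int
    early_recurrence: int
    os_months: float
    death_event: int
    afp_ng_ml: float
    meld: int
    clinical_stage: str
    pathological_stage: str
    vascular_invasion: int
    tumor_size_cm: float
    cirrhosis: int


class CohortData(NamedTuple):
    features: pd.DataFrame  # n x 176, taxonomy order, indexed by patient_id
    records: list[CohortRecord]
    latent_index: np.ndarray  # generator bookkeeping: the planted risk latent


def _simulate_morphological(
    rng: np.random.Generator, n: int, taxonomy: FeatureTaxonomy, severity_corr: float
) -> pd.DataFrame:
    """Plausible-scale morphological features driven by a per-patient severity factor."""
    severity = rng.normal(0.0, 1.0, n)
    rho = severity_corr
    cols = {}
    for name in taxonomy.morphological:
        u = rho * severity + np.sqrt(max(1 - rho**2, 0.0)) * rng.normal(0, 1, n)
        if name == "SHG" or name in REGION_WORD.values() or name.endswith(("AGG", "DIS")):
            # area percentages, a few percent of tissue typically
            vals = 100.0 / (1.0 + np.exp(-(0.8 * u - 2.5)))
        elif name.startswith("No"):
            vals = np.round(np.exp(2.5 + 0.6 * u)).astype(float)  # counts
        elif name.startswith("StrArea"):
            vals = np.exp(6.0 + 0.7 * u)  # summed area, um^2
        elif name.startswith("StrLength"):
            vals = np.exp(3.2 + 0.3 * u)  # mean length, um
        elif name.startswith("StrWidth"):
            vals = np.exp(1.2 + 0.2 * u)  # mean width, um
        elif name.startswith("StrOrientation"):
            vals = 1.0 / (1.0 + np.exp(-0.6 * u))  # anisotropy in (0, 1)
        else:  # pragma: no cover - taxonomy is closed
            vals = u
        cols[name] = vals
    return pd.DataFrame(cols)


def _ratio_table(morph: pd.DataFrame, taxonomy: FeatureTaxonomy) -> pd.DataFrame:
    cols = {}
    for name in taxonomy.relativistic:
        num, den = taxonomy.ratio_parts(name)
        d = morph[den].to_numpy(dtype=float)
        nmr = morph[num].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(d != 0, nmr / np.where(d != 0, d, 1.0), 0.0)
        cols[name] = vals
    return pd.DataFrame(cols)


def generate_cohort(
    params: CohortSimParams, taxonomy: FeatureTaxonomy = DEFAULT_TAXONOMY
) -> CohortData:
    """Simulate a cohort feature table plus outcome records (seeded)."""
    params.validate(taxonomy)
    rng = np.random.default_rng(params.seed)
    n = params.n

    morph = _simulate_morphological(rng, n, taxonomy, params.severity_corr)
    feats = pd.concat([morph, _ratio_table(morph, taxonomy)], axis=1)
    feats = feats[list(taxonomy.all_names)]

    # planted latent risk: linear in min-max-normalized planted features
    sub = feats[list(params.true_feature_names)].to_numpy(dtype=float)
    lo, hi = sub.min(axis=0), sub.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    sub_norm = np.where(hi > lo, (sub - lo) / span, 0.0)
    signal = sub_norm @ np.asarray(params.true_coefficients, dtype=float)
    ssd = signal.std()
    if ssd > 0:
        signal = (signal - signal.mean()) / ssd
    latent = signal + (
        rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else 0.0
    )

    k_early = int(round(n * params.prevalence_early))
    order = np.argsort(-latent, kind="stable")
    early = np.zeros(n, dtype=int)
    early[order[:k_early]] = 1

    z = (latent - latent.mean()) / latent.std() if latent.std() > 0 else latent

    # disease-free interval
    df_months = np.empty(n)
    recurrence = np.empty(n, dtype=int)
    for i in range(n):
        if early[i]:
            df_months[i] = rng.uniform(1.5, 11.5)
            recurrence[i] = 1
        else:
            censored = rng.uniform() < params.censor_rate
            if censored:
                df_months[i] = rng.uniform(12.0, 60.0)
                recurrence[i] = 0
            else:
                # exponential with log-rate linear in the latent index
                scale = 30.0 * np.exp(-0.5 * z[i])
                df_months[i] = 12.0 + rng.exponential(scale)
                recurrence[i] = 1

    # overall survival: exponential after the disease-free interval
    os_true = df_months + rng.exponential(24.0 * np.exp(-0.4 * z), n)
    os_censor = rng.uniform(24.0, 96.0, n)
    death = (os_true <= os_censor).astype(int)
    os_months = np.minimum(os_true, os_censor)

    # AFP correlated with the latent index at ~afp_corr (lognormal scale)
    rho = params.afp_corr
    eps = rng.normal(0.0, 1.0, n)
    a = rho * z + np.sqrt(max(1 - rho**2, 0.0)) * eps
    afp = 20.0 * np.exp(0.6 * a)

    meld = np.clip(6 + rng.poisson(2.0 * np.exp(0.15 * z)), 6, 30)
    stage_latent = 0.5 * z + rng.normal(0, 1, n)
    stage_bins = np.digitize(stage_latent, [-0.5, 0.6, 1.5])
    stages = np.array(["I", "II", "III", "IV"])[stage_bins]
    path_latent = 0.5 * z + rng.normal(0, 1, n)
    path_stages = np.array(["I", "II", "III", "IV"])[
        np.digitize(path_latent, [-0.5, 0.6, 1.5])
    ]
    vascular = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(0.5 - 0.4 * z))).astype(int)
    tumor_size = np.exp(1.2 + 0.3 * rng.normal(0, 1, n))
    cirrhosis = (rng.uniform(size=n) < 0.4).astype(int)

    ids = [f"P{i + 1:03d}" for i in range(n)]
    feats.index = pd.Index(ids, name="patient_id")
    records = [
        CohortRecord(
            patient_id=ids[i],
            df_months=float(df_months[i]),
            recurrence_event=int(recurrence[i]),
            early_recurrence=int(early[i]),
            os_months=float(os_months[i]),
            death_event=int(death[i]),
            afp_ng_ml=float(afp[i]),
            meld=int(meld[i]),
            clinical_stage=str(stages[i]),
            pathological_stage=str(path_stages[i]),
            vascular_invasion=int(vascular[i]),
            tumor_size_cm=float(tumor_size[i]),
            cirrhosis=int(cirrhosis[i]),
        )
        for i in range(n)
    ]
    return CohortData(feats, records, latent)


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    return df.set_index("patient_id")


def write_cohort(records: list[CohortRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")
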
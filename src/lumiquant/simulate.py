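"""Seeded synthetic trajectories, mouse phantoms, and cohort directories.

The generator inverts the fitted model: trajectories are sampled from the
piecewise logistic/exponential kinetics with multiplicative lognormal
measurement noise (additive on log10, matching decade-scale residual
reporting), and change points are placed so the noise-free curve respects
the phase-detection thresholds with margin.  Because a noisy realization
can still straddle a threshold, the noise vector is redrawn (seeded,
deterministic) until the realized series segments into the intended class
-- the in-silico analog of manually confirming automated classifications.
Rate distributions default to the empirical cohort statistics
(k_growth ~ 0.84 +/- 0.43 day^-1, k_relapse ~ 0.60 +/- 0.32 day^-1, and a
bimodal decay-rate population); class frequencies default to the observed
five-class mixture of a >1,000-mouse leukemia cohort.  Series end early
when the noise-free burden reaches 75% of carrying capacity, emulating
sacrifice at tumor-burden endpoints.

Phantom images are stadium-bodied masks with a head ellipse and an
optional thin tail, Gaussian luminescent foci placed in a 3x3 grid of
anatomical cells, and a textured brightfield layer; no anatomical fidelity
is claimed.  Cohort directories are written in the exact dialects the
ingest module reads (brightfield PNG + float32 radiance TIFF, or
pseudocolor PNG + calibration scale in the metadata table), alongside a
ground-truth JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy.ndimage import gaussian_filter

from .imaging import CalibrationScale, CompositeMouseImage, render_pseudocolor
from .kinetics import DynamicParams, growth_curve, piecewise_predict
from .phases import RadianceSeries, segment_phases

__all__ = [
    "SimulationError",
    "SimConfig",
    "TrajectoryTruth",
    "simulate_trajectory",
    "simulate_mouse_image",
    "simulate_cohort",
    "simulate_aligned_stack",
]

#: Five-class mixture observed across a 1,060-mouse leukemia cohort.
DEFAULT_CLASS_MIXTURE = {
    "G": 374 / 1060,
    "GD": 61 / 1060,
    "GDR": 167 / 1060,
    "D": 103 / 1060,
    "DR": 355 / 1060,
}


class SimulationError(RuntimeError):
    """The configuration cannot satisfy threshold-consistency (or a focus
    falls outside the frame)."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Rates are day^-1, radiances photons s^-1 cm^-2 sr^-1 per pixel, days
    are days since tumor injection; ``noise_sd`` is the lognormal
    measurement noise in log10 decades.  Geometry fields are pixels.
    """

    seed: int = 0
    n_mice: int = 20
    day_step: float = 3.5
    min_timepoints: int = 8
    max_timepoints: int = 12
    class_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    k_growth_mean: float = 0.84
    k_growth_sd: float = 0.43
    k_relapse_mean: float = 0.60
    k_relapse_sd: float = 0.32
    #: bimodal decay-rate population: (mean, sd) per mode, equal weights
    k_decay_modes: tuple[tuple[float, float], ...] = ((0.35, 0.10), (0.95, 0.25))
    rate_min: float = 0.05
    k_growth_max: float = 2.0
    log10_T0_range: tuple[float, float] = (4.0, 6.0)
    log10_TB_range: tuple[float, float] = (3.3, 4.5)
    log10_Tinf_range: tuple[float, float] = (8.7, 9.7)
    noise_sd: float = 0.15
    floor: float = 1e3
    # --- imaging geometry ---
    raw_height_range: tuple[int, int] = (84, 124)
    body_aspect: float = 0.42
    tail: bool = True
    tail_length_frac: float = 0.35
    tail_width: int = 3
    focus_sigma_frac: float = 0.06
    mice_per_image: int = 4
    dialect: str = "grayscale"
    scale_min: float = 1e3
    scale_max: float = 1e9
    colormap: str = "turbo"
    region_row_fracs: tuple[float, float] = (1 / 3, 2 / 3)
    region_col_fracs: tuple[float, float] = (1 / 3, 2 / 3)
    #: draw per-mouse focus weights from two zero-sum anatomical contrasts
    #: (head/torso/hind and left/mid/right) instead of random cells, so the
    #: cohort's profile PCA carries the region boundaries in its loadings
    region_factor_foci: bool = False
    tumor_line: str = "NALM6"
    tumor_dose: float = 1e6
    car_construct: str = "CD19.4-1BB"
    car_dose: float = 2e6

    def __post_init__(self) -> None:
        tot = sum(self.class_mixture.values())
        if not np.isclose(tot, 1.0):
            raise ValueError("class mixture must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        for v in (self.k_growth_mean, self.k_relapse_mean, self.rate_min):
            if v <= 0:
                raise ValueError("rates must be positive")


@dataclass
class TrajectoryTruth:
    """Generator ground truth for one mouse's trajectory."""

    mouse_id: str
    label: str
    params: DynamicParams
    days: np.ndarray
    noise_free: np.ndarray
    values: np.ndarray
    D_index: int | None
    R_index: int | None


def _rng_for(cfg: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=tuple(key))
    )


def _trunc_normal(rng, mean, sd, lo, hi):
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _draw_k_decay(rng, cfg: SimConfig) -> float:
    m, s = cfg.k_decay_modes[rng.integers(len(cfg.k_decay_modes))]
    return _trunc_normal(rng, m, s, cfg.rate_min, 3.0)


def simulate_trajectory(
    cfg: SimConfig, index: int, *, label: str | None = None
) -> tuple[RadianceSeries, TrajectoryTruth]:
    """Sample one mouse's noisy radiance series with recorded ground truth.

    The trajectory class is drawn from the configured mixture (or forced
    via ``label``); kinetic parameters and change points are rejection-
    sampled until the noise-free curve respects the segmentation
    thresholds with margin (post-decay drop below 60%, relapse jump above
    3.2-fold, growth staying under half of carrying capacity at the decay
    onset), and the noise vector is redrawn until the realized series
    recovers the intended class.  Deterministic given (seed, index).
    """
    rng = _rng_for(cfg, 1, index)
    if label is None:
        classes = sorted(cfg.class_mixture)
        probs = np.array([cfg.class_mixture[c] for c in classes])
        label = classes[rng.choice(len(classes), p=probs / probs.sum())]

    for _attempt in range(500):
        n = int(rng.integers(cfg.min_timepoints, cfg.max_timepoints + 1))
        days = np.arange(n) * cfg.day_step
        T0 = 10.0 ** rng.uniform(*cfg.log10_T0_range)
        T_inf = 10.0 ** rng.uniform(*cfg.log10_Tinf_range)
        T_B = 10.0 ** rng.uniform(*cfg.log10_TB_range)
        p = DynamicParams(T0=T0, T_inf=T_inf)
        D = R = None
        if label in ("G", "GD", "GDR"):
            kG = _trunc_normal(
                rng, cfg.k_growth_mean, cfg.k_growth_sd,
                cfg.rate_min, cfg.k_growth_max,
            )
            p = dataclasses.replace(p, k_growth=kG)
        if label in ("GD", "GDR"):
            hi_D = n - 5 if label == "GDR" else n - 2
            D = int(rng.integers(1, min(3, hi_D) + 1))
        if label in ("D", "DR"):
            kD = _draw_k_decay(rng, cfg)
            p = dataclasses.replace(
                p, t_decay=float(days[0]), k_decay=kD, T_B=T_B
            )
        if label in ("GD", "GDR"):
            kD = _draw_k_decay(rng, cfg)
            p = dataclasses.replace(
                p, t_decay=float(days[D]), k_decay=kD, T_B=T_B
            )
        if label in ("GDR", "DR"):
            kR = _trunc_normal(
                rng, cfg.k_relapse_mean, cfg.k_relapse_sd, cfg.rate_min, 2.5
            )
            if label == "GDR":
                m = int(rng.integers(3, min(5, n - 2 - D) + 1))
                R = D + m
            else:
                R = int(rng.integers(2, n - 2 + 1))
            p = dataclasses.replace(
                p, t_relapse=float(days[R - 1]), k_relapse=kR
            )

        # --- threshold-consistency of the noise-free curve ---
        if p.k_growth is not None and p.t_decay is not None:
            peak = float(growth_curve(p.t_decay, p.T0, p.k_growth, p.T_inf))
            if peak > 0.5 * T_inf or p.T_B > 0.15 * peak:
                continue
        if not _params_ready(p, label):
            continue
        curve = np.maximum(
            np.asarray(piecewise_predict(days, p, label), dtype=float),
            cfg.floor,
        )
        d0 = D if D is not None else (0 if label in ("D", "DR") else None)
        if d0 is not None:
            if curve[d0 + 1] > 0.6 * curve[d0]:
                continue
        if R is not None:
            if curve[R] < 3.2 * curve[R - 1]:
                continue
        # burden endpoint: sacrifice when the noise-free curve hits 75% Tinf
        over = np.flatnonzero(curve >= 0.75 * T_inf)
        if over.size:
            cut = int(over[0])
            min_len = {"G": 4, "GD": (D or 0) + 3, "GDR": (R or 0) + 1,
                       "D": 3, "DR": (R or 0) + 1}[label]
            if cut < min_len:
                continue
            days, curve = days[:cut], curve[:cut]
            n = cut

        # --- noise, redrawn until the class is recovered ---
        for _try in range(300):
            vals = np.maximum(
                curve * 10.0 ** rng.normal(0.0, cfg.noise_sd, size=n),
                cfg.floor,
            )
            series = RadianceSeries(
                mouse_id=f"m{index:03d}", days=days, values=vals
            )
            seg = segment_phases(series, floor=cfg.floor)
            if seg.label == label and seg.D_index == D and seg.R_index == R:
                truth = TrajectoryTruth(
                    mouse_id=series.mouse_id, label=label, params=p,
                    days=days, noise_free=curve, values=vals,
                    D_index=D, R_index=R,
                )
                return series, truth
            if cfg.noise_sd == 0:
                break
        # fall through: redraw parameters
    raise SimulationError(
        f"could not generate a threshold-consistent {label} trajectory"
    )


def _params_ready(p: DynamicParams, label: str) -> bool:
    from .kinetics import _REQUIRED  # shared requirement table

    return all(getattr(p, nm) is not None for nm in _REQUIRED[label])


# --------------------------------------------------------------------------
# phantom images
# --------------------------------------------------------------------------

def _phantom_mask(h: int, w: int) -> np.ndarray:
    """Stadium-shaped body with a head ellipse, flat hindquarters, left-right
    symmetric (so the principal axis is exactly vertical)."""
    mask = np.zeros((h, w), dtype=bool)
    c = (w - 1) / 2.0
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    r0 = int(0.12 * h)
    body = (rows >= r0) & (np.abs(cols - c) <= w / 2 - 0.5)
    hc, a, b = 0.10 * h, 0.12 * h, 0.32 * w
    head = ((rows - hc) / a) ** 2 + ((cols - c) / b) ** 2 <= 1.0
    mask |= body | head
    return mask


def simulate_mouse_image(
    cfg: SimConfig,
    mouse_id: str,
    day: float,
    mean_radiance: float,
    *,
    rng: np.random.Generator | None = None,
    raw_height: int | None = None,
    region_weights: dict[tuple[int, int], float] | None = None,
    tail: bool | None = None,
    tail_angle: float = 0.0,
) -> tuple[CompositeMouseImage, dict]:
    """Render one phantom mouse at one timepoint.

    Gaussian luminescent foci are placed at the centers of the configured
    3x3 grid cells of the body (weights per cell), and the field is scaled
    so the average radiance over the body mask equals ``mean_radiance``
    exactly; a nonpositive target yields a blank luminescence layer.  The
    returned ground truth records the body mask, tail pixels, cell weights
    and the target mean.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    h = int(raw_height if raw_height is not None else np.mean(cfg.raw_height_range))
    w = max(12, int(round(h * cfg.body_aspect)))
    use_tail = cfg.tail if tail is None else tail
    tail_len = int(cfg.tail_length_frac * h) if use_tail else 0
    H = h + tail_len
    body = np.zeros((H, w), dtype=bool)
    body[:h] = _phantom_mask(h, w)
    tail_mask = np.zeros((H, w), dtype=bool)
    if use_tail:
        c = (w - 1) / 2.0
        half = cfg.tail_width // 2
        for r in range(h, H):
            cc = int(round(c + np.tan(tail_angle) * (r - h)))
            lo, hi = max(cc - half, 0), min(cc + half + 1, w)
            if lo >= hi:
                raise SimulationError("tail leaves the frame")
            tail_mask[r, lo:hi] = True
    mask = body | tail_mask

    brightfield = np.full((H, w), 0.03)
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(H, w)), 3.0)
    brightfield[mask] = np.clip(0.55 + 0.8 * texture[mask], 0.35, 0.9)

    # luminescent foci in the 3x3 body grid
    radiance = np.zeros((H, w))
    if mean_radiance > 0:
        redges = [0, *(int(f * h) for f in cfg.region_row_fracs), h]
        cedges = [0, *(int(f * w) for f in cfg.region_col_fracs), w]
        if region_weights is None:
            k = int(rng.integers(1, 4))
            cells = [(int(a), int(b)) for a, b in
                     zip(rng.integers(0, 3, k), rng.integers(0, 3, k))]
            wts = rng.dirichlet(np.ones(len(cells)))
            region_weights = {}
            for cell, wt in zip(cells, wts):
                region_weights[cell] = region_weights.get(cell, 0.0) + wt
        sigma = cfg.focus_sigma_frac * h
        rr = np.arange(H)[:, None]
        cc = np.arange(w)[None, :]
        field = np.zeros((H, w))
        for (i, j), wt in region_weights.items():
            if not (0 <= i < 3 and 0 <= j < 3):
                raise SimulationError(f"focus cell {(i, j)} outside the frame")
            rs, re = redges[i], redges[i + 1]
            cs, ce = cedges[j], cedges[j + 1]
            r_ctr, c_ctr = (rs + re) / 2.0, (cs + ce) / 2.0
            cell_mask = np.zeros((H, w), dtype=bool)
            cell_mask[rs:re, cs:ce] = True
            cell_body = cell_mask & body
            if not cell_body.any():
                raise SimulationError(f"focus cell {(i, j)} misses the body")
            if not body[int(r_ctr), int(c_ctr)]:
                pts = np.argwhere(cell_body)
                d2 = (pts[:, 0] - r_ctr) ** 2 + (pts[:, 1] - c_ctr) ** 2
                r_ctr, c_ctr = pts[int(np.argmin(d2))]
            field += wt * np.exp(
                -((rr - r_ctr) ** 2 + (cc - c_ctr) ** 2) / (2 * sigma**2)
            )
        field *= mask
        radiance = field * (mean_radiance * mask.sum() / field[mask].sum())

    img = CompositeMouseImage(
        radiance=radiance, mask=mask, brightfield=brightfield,
        mouse_id=mouse_id, acquisition_day=day, bbox=(0, 0, H, w),
    )
    truth = {
        "body_mask": body, "tail_pixels": np.argwhere(tail_mask),
        "region_weights": region_weights, "mean_radiance": mean_radiance,
        "height": h, "frame": (H, w),
    }
    return img, truth


# --------------------------------------------------------------------------
# full cohort directories
# --------------------------------------------------------------------------

def _write_png(path: Path, arr01: np.ndarray) -> None:
    Image.fromarray(
        np.round(np.clip(arr01, 0, 1) * 255).astype(np.uint8)
    ).save(path)


def simulate_cohort(cfg: SimConfig, outdir: str | Path) -> dict:
    """Write a full synthetic experiment directory with ground truth.

    Produces grouped acquisition images (``mice_per_image`` phantoms side
    by side per frame), a metadata CSV in the ingest dialect, and a
    ``ground_truth.json``; returns the ground truth as a dict (with the
    per-mouse trajectory truths under ``"mice"`` and per-image bounding
    boxes under ``"images"``).  Bit-identical across runs for a fixed
    config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cal = CalibrationScale(cfg.scale_min, cfg.scale_max, cfg.colormap)

    mice = []
    for i in range(cfg.n_mice):
        series, truth = simulate_trajectory(cfg, i)
        g = _rng_for(cfg, 2, i)
        mice.append({
            "series": series, "truth": truth,
            "raw_height": int(g.integers(*cfg.raw_height_range)),
            "tail_angle": float(g.uniform(-0.25, 0.25)),
            "region_weights": None,  # drawn per mouse below
        })
        rw: dict[tuple[int, int], float] = {}
        if cfg.region_factor_foci:
            # persistent per-mouse loadings on the two zero-sum contrasts
            contrast = (1.0, -2.0, 1.0)
            a, b = np.clip(g.normal(0.0, 0.12, size=2), -0.2, 0.2)
            for i in range(3):
                for j in range(3):
                    rw[(i, j)] = (1.0 + a * contrast[i] + b * contrast[j]) / 9.0
        else:
            k = int(g.integers(1, 4))
            cells = [(int(a), int(b)) for a, b in
                     zip(g.integers(0, 3, k), g.integers(0, 3, k))]
            wts = g.dirichlet(np.ones(len(cells)))
            for cell, wt in zip(cells, wts):
                rw[cell] = rw.get(cell, 0.0) + wt
        mice[-1]["region_weights"] = rw

    meta_rows = []
    truth_images: dict[str, dict] = {}
    n_groups = (cfg.n_mice + cfg.mice_per_image - 1) // cfg.mice_per_image
    gap, margin = 10, 4
    for gidx in range(n_groups):
        members = mice[gidx * cfg.mice_per_image : (gidx + 1) * cfg.mice_per_image]
        group_id = f"g{gidx:02d}"
        all_days = sorted({float(d) for m in members for d in m["truth"].days})
        for day in all_days:
            present = [m for m in members if day in m["truth"].days]
            rendered = []
            for m in present:
                t = m["truth"]
                val = float(t.values[np.flatnonzero(t.days == day)[0]])
                ridx = mice.index(m)
                didx = int(np.flatnonzero(t.days == day)[0])
                img, itruth = simulate_mouse_image(
                    cfg, t.mouse_id, day, val,
                    rng=_rng_for(cfg, 3, ridx, didx),
                    raw_height=m["raw_height"],
                    region_weights=m["region_weights"],
                    tail_angle=m["tail_angle"],
                )
                rendered.append((m, img))
            H = max(img.radiance.shape[0] for _, img in rendered) + 2 * margin
            W = (
                sum(img.radiance.shape[1] for _, img in rendered)
                + gap * (len(rendered) + 1)
            )
            bf = np.full((H, W), 0.03)
            lum = np.zeros((H, W))
            x = gap
            boxes = {}
            for m, img in rendered:
                hh, ww = img.radiance.shape
                bf[margin : margin + hh, x : x + ww] = np.maximum(
                    bf[margin : margin + hh, x : x + ww], img.brightfield
                )
                lum[margin : margin + hh, x : x + ww] += img.radiance
                rows = np.flatnonzero(img.mask.any(axis=1))
                cols = np.flatnonzero(img.mask.any(axis=0))
                boxes[img.mouse_id] = [
                    int(margin + rows[0]), int(x + cols[0]),
                    int(margin + rows[-1] + 1), int(x + cols[-1] + 1),
                ]
                x += ww + gap
            stem = f"{group_id}_d{day:g}".replace(".", "p")
            bf_file = f"{stem}_bf.png"
            _write_png(outdir / bf_file, bf)
            if cfg.dialect == "grayscale":
                lum_file = f"{stem}_lum.tif"
                tifffile.imwrite(outdir / lum_file, lum.astype(np.float32))
            else:
                lum_file = f"{stem}_lum.png"
                rgb = render_pseudocolor(lum, cal, background=bf)
                Image.fromarray(rgb).save(outdir / lum_file)
            meta_rows.append({
                "experiment_id": "sim", "group_id": group_id,
                "mouse_ids": ";".join(img.mouse_id for _, img in rendered),
                "day": day, "scale_min": cfg.scale_min,
                "scale_max": cfg.scale_max, "colormap": cfg.colormap,
                "tumor_line": cfg.tumor_line, "tumor_dose": cfg.tumor_dose,
                "car_construct": cfg.car_construct, "car_dose": cfg.car_dose,
                "brightfield_file": bf_file, "luminescence_file": lum_file,
            })
            truth_images[lum_file] = {
                "group_id": group_id, "day": day, "bboxes": boxes,
                "order": [img.mouse_id for _, img in rendered],
            }

    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.csv", index=False)
    truth = {
        "config": {"seed": cfg.seed, "n_mice": cfg.n_mice,
                   "noise_sd": cfg.noise_sd, "dialect": cfg.dialect},
        "mice": {
            m["truth"].mouse_id: {
                "label": m["truth"].label,
                "days": [float(d) for d in m["truth"].days],
                "values": [float(v) for v in m["truth"].values],
                "noise_free": [float(v) for v in m["truth"].noise_free],
                "D_index": m["truth"].D_index,
                "R_index": m["truth"].R_index,
                "params": {
                    k: (None if v is None else float(v))
                    for k, v in dataclasses.asdict(m["truth"].params).items()
                },
                "raw_height": m["raw_height"],
                "region_weights": {
                    f"{i},{j}": w for (i, j), w in m["region_weights"].items()
                },
            }
            for m in mice
        },
        "images": truth_images,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth


# --------------------------------------------------------------------------
# aligned stacks with known region structure
# --------------------------------------------------------------------------

def simulate_aligned_stack(
    n_images: int = 30,
    frame: tuple[int, int] = (99, 45),
    *,
    seed: int = 0,
    sigma: float = 4.0,
    amp: float = 3e4,
    base: float = 2e5,
) -> tuple[list[CompositeMouseImage], dict]:
    """Aligned phantom stack whose radiance varies along two latent
    anatomical contrasts, for exercising region demarcation.

    Every image shares a full-envelope mask and carries Gaussian foci at
    the centers of a 3x3 grid of equal cells.  Image-to-image variation
    follows two independent factors with zero-sum (+1, -2, +1) loadings
    across the row bands and the column bands respectively, so the first
    row-profile principal component crosses zero at the two horizontal
    boundaries and the first column-profile component at the two vertical
    boundaries.  Ground truth records those boundaries.
    """
    H, W = frame
    rng = np.random.default_rng(seed)
    r_bounds = (H // 3, 2 * H // 3)
    c_bounds = (W // 3, 2 * W // 3)
    redges = [0, *r_bounds, H]
    cedges = [0, *c_bounds, W]
    centers = [
        ((redges[i] + redges[i + 1]) / 2.0, (cedges[j] + cedges[j + 1]) / 2.0)
        for i in range(3) for j in range(3)
    ]
    rr = np.arange(H)[:, None]
    cc = np.arange(W)[None, :]
    blobs = [
        np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
        for r0, c0 in centers
    ]
    srow = (1.0, -2.0, 1.0)
    scol = (1.0, -2.0, 1.0)
    P = sum(srow[k // 3] * blobs[k] for k in range(9))
    Q = sum(scol[k % 3] * blobs[k] for k in range(9))
    base_field = base * sum(blobs) + 2e3
    mask = np.ones((H, W), dtype=bool)
    bf = np.full((H, W), 0.6)
    images = []
    for i in range(n_images):
        a, b = rng.normal(0.0, 1.0, size=2)
        rad = np.clip(base_field + amp * (a * P + b * Q), 0.0, None)
        images.append(
            CompositeMouseImage(
                radiance=rad, mask=mask, brightfield=bf,
                mouse_id=f"s{i:03d}", acquisition_day=float(i),
                height_normalized=True,
            )
        )
    truth = {"row_boundaries": r_bounds, "col_boundaries": c_bounds}
    return images, truth
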
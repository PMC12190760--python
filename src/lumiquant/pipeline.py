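"""End-to-end orchestration: process a cohort directory, fit kinetics,
run the regional analysis, and write tables.

These functions are the library face of the command-line tool: each takes
a :class:`RunConfig`, consumes the previous stage's outputs, and writes
plain CSV/JSON artifacts with the run's thresholds recorded in provenance
header comments.  The whole pipeline is deterministic given (inputs,
config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, kinetics, regions
from .phases import RadianceSeries, segment_phases

__all__ = ["RunConfig", "ProcessResult", "run_process", "run_fit", "run_regions"]

log = logging.getLogger("lumiquant")


@dataclass
class RunConfig:
    """Configuration for a pipeline run (thresholds are the standard
    defaults: growth ends below 0.75x, relapse starts at 3x, slow/fast
    growth split at 0.85 day^-1, rate outlier cutoff 3 day^-1)."""

    input_dir: str | Path = "."
    metadata: str = "metadata.csv"
    out_dir: str | Path = "out"
    growth_end_ratio: float = 0.75
    relapse_ratio: float = 3.0
    speed_threshold: float = 0.85
    outlier_cutoff: float = 3.0
    prior_kgrowth: tuple[float, float] | None = None
    prior_krelapse: tuple[float, float] | None = None
    noise_sd: float = 0.15
    floor: float = 1e3
    target_height: int = 100
    frame_width: int = 72
    max_slant_deg: float = 10.0
    min_area: int = 150
    row_components: tuple[int, ...] = (2, 3)
    col_components: tuple[int, ...] = (4, 5)
    n_boot: int = 1000
    seed: int = 0
    regions_enabled: bool = True

    def __post_init__(self) -> None:
        for v in (self.growth_end_ratio, self.relapse_ratio,
                  self.speed_threshold, self.outlier_cutoff):
            if v <= 0:
                raise ValueError("thresholds must be positive")


@dataclass
class ProcessResult:
    """Outputs of the imaging stage: the per-mouse per-day radiance table,
    the QC exclusion log, and the aligned image stack keyed by mouse."""

    radiance: pd.DataFrame
    qc_log: pd.DataFrame
    aligned: dict[str, list[tuple[float, imaging.CompositeMouseImage]]] = field(
        default_factory=dict
    )


def _provenance_header(cfg: RunConfig, keys: tuple[str, ...]) -> str:
    d = asdict(cfg)
    return "".join(f"# {k}={d[k]}\n" for k in keys)


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_process(cfg: RunConfig) -> ProcessResult:
    """Quantify every mouse in every acquisition of a cohort directory.

    Each metadata row names a brightfield/luminescence file pair; mice are
    isolated, tails removed, slanted animals excluded, and every kept
    mouse is height-normalized into the common frame before its average
    radiance per pixel is computed.  Unreadable or QC-failing inputs are
    skipped with a log entry rather than aborting the run.  Writes
    ``radiance.csv`` and ``qc_log.csv`` under the output directory.
    """
    input_dir = Path(cfg.input_dir)
    meta_path = input_dir / cfg.metadata
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)
    meta = pd.read_csv(meta_path)
    rows, qc_rows = [], []
    aligned: dict[str, list[tuple[float, imaging.CompositeMouseImage]]] = {}
    for _, m in meta.iterrows():
        pair = (m.get("brightfield_file"), m.get("luminescence_file"))
        try:
            group = imaging.load_group_image(
                input_dir / str(pair[0]), input_dir / str(pair[1]), m.to_dict()
            )
            mice = imaging.split_mice(group, min_area=cfg.min_area)
        except (imaging.ImageQCError, OSError, ValueError) as exc:
            qc_rows.append({"file": str(pair[1]), "mouse_id": "",
                            "reason": str(exc)})
            log.warning("skipping %s: %s", pair[1], exc)
            continue
        for mouse in mice:
            mouse = imaging.remove_tail(mouse)
            if imaging.detect_slant(mouse, cfg.max_slant_deg):
                qc_rows.append({
                    "file": str(pair[1]), "mouse_id": mouse.mouse_id,
                    "reason": f"slanted beyond {cfg.max_slant_deg} degrees",
                })
                continue
            try:
                mouse = imaging.normalize_and_align(
                    mouse, cfg.target_height, frame_width=cfg.frame_width
                )
            except imaging.ImageQCError as exc:
                qc_rows.append({"file": str(pair[1]),
                                "mouse_id": mouse.mouse_id,
                                "reason": str(exc)})
                continue
            rows.append({
                "mouse_id": mouse.mouse_id, "day": group.acquisition_day,
                "avg_radiance": imaging.average_radiance(mouse),
                "n_mask_pixels": int(mouse.mask.sum()),
                "qc_flags": ";".join(mouse.qc_flags),
            })
            aligned.setdefault(mouse.mouse_id, []).append(
                (group.acquisition_day, mouse)
            )
    radiance = pd.DataFrame(
        rows, columns=["mouse_id", "day", "avg_radiance", "n_mask_pixels",
                       "qc_flags"],
    ).sort_values(["mouse_id", "day"], ignore_index=True)
    qc_log = pd.DataFrame(qc_rows, columns=["file", "mouse_id", "reason"])
    if radiance.empty:
        log.warning("no mice survived processing")
    out = Path(cfg.out_dir)
    hdr = _provenance_header(
        cfg, ("target_height", "frame_width", "max_slant_deg", "floor", "seed")
    )
    _write_csv(radiance, out / "radiance.csv", hdr)
    _write_csv(qc_log, out / "qc_log.csv", hdr)
    return ProcessResult(radiance=radiance, qc_log=qc_log, aligned=aligned)


def run_fit(cfg: RunConfig, radiance: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Segment and fit every mouse's radiance series, then MAP-refit
    outlier rates under empirical cohort priors.

    Priors for k_growth and k_relapse are computed from the cohort's own
    unpenalized fits after removing rates above the outlier cutoff (or
    taken from the config overrides); the refit trigger is an unpenalized
    rate above the cutoff or a two-point phase.  Writes ``params.csv``
    and a full-provenance ``fits.json``.  Returns (table, fits by mouse).
    """
    if not {"mouse_id", "day", "avg_radiance"} <= set(radiance.columns):
        raise ValueError("radiance table must have mouse_id, day, avg_radiance")
    fits: dict[str, kinetics.FitResult] = {}
    for mouse_id, sub in radiance.groupby("mouse_id"):
        sub = sub.sort_values("day")
        if len(sub) < 2:
            log.warning("mouse %s has <2 timepoints; skipped", mouse_id)
            continue
        series = RadianceSeries(
            mouse_id=str(mouse_id),
            days=sub["day"].to_numpy(float),
            values=np.maximum(sub["avg_radiance"].to_numpy(float), cfg.floor),
        )
        seg = segment_phases(
            series, cfg.growth_end_ratio, cfg.relapse_ratio, floor=cfg.floor
        )
        fits[str(mouse_id)] = kinetics.fit_trajectory(
            series, seg, floor=cfg.floor, seed=cfg.seed
        )

    priors: dict[str, kinetics.PriorSpec] = {}
    for which, override in (("k_growth", cfg.prior_kgrowth),
                            ("k_relapse", cfg.prior_krelapse)):
        if override is not None:
            priors[which] = kinetics.PriorSpec(*override, cfg.outlier_cutoff)
            continue
        rates = [getattr(f.params, which) for f in fits.values()
                 if getattr(f.params, which) is not None]
        try:
            priors[which] = kinetics.compute_priors(rates, cfg.outlier_cutoff)
        except ValueError:
            log.warning("cohort too small for a %s prior; refit disabled", which)
    fits = {
        mid: kinetics.apply_refits(f, priors, noise_sd=cfg.noise_sd)
        for mid, f in fits.items()
    }

    rows = []
    for mid, f in fits.items():
        p = f.params
        seg = f.segmentation
        t = f.series.days
        row = {
            "mouse_id": mid, "label": f.label,
            "D_day": t[seg.D_index] if seg.D_index is not None else np.nan,
            "R_day": t[seg.R_index] if seg.R_index is not None else np.nan,
            "T0": p.T0, "k_growth": p.k_growth, "t_decay": p.t_decay,
            "k_decay": p.k_decay, "T_B": p.T_B, "t_relapse": p.t_relapse,
            "k_relapse": p.k_relapse, "T_inf": p.T_inf,
            "T1_relapse": p.T1_relapse if p.t_relapse is not None else np.nan,
            "refit_k_growth": f.refit_flags.get("k_growth", False),
            "refit_k_relapse": f.refit_flags.get("k_relapse", False),
            "growth_speed": (
                kinetics.classify_growth_speed(p.k_growth, cfg.speed_threshold)
                if p.k_growth is not None else ""
            ),
            "objective": f.objective,
        }
        for ph in ("growth", "decay", "relapse"):
            sel = f.phase_of_point == ph
            row[f"resid_within_decade_{ph}"] = (
                float(np.mean(np.abs(f.residuals[sel]) < 1.0))
                if sel.any() else np.nan
            )
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("mouse_id", ignore_index=True)
    out = Path(cfg.out_dir)
    hdr = _provenance_header(
        cfg, ("growth_end_ratio", "relapse_ratio", "speed_threshold",
              "outlier_cutoff", "noise_sd", "floor", "seed")
    )
    _write_csv(table, out / "params.csv", hdr)
    prov = {
        "priors": {k: asdict(v) for k, v in priors.items()},
        "fits": {mid: {"flags": f.flags, "provenance": f.provenance,
                       "objective": f.objective}
                 for mid, f in fits.items()},
    }
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "fits.json", "w") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True)
    return table, fits


def run_regions(
    cfg: RunConfig, processed: ProcessResult
) -> dict:
    """Demarcate anatomical regions from the aligned stack and analyze
    per-region dynamics.

    Builds the stack averages, runs row/column profile PCA, demarcates
    the nine-region grid from the configured components' zero crossings,
    quantifies and segments every region series, and computes the
    divergence table and the region correlation matrix.  Writes the grid
    JSON and the per-region/divergence/correlation CSVs.
    """
    stack = [im for seq in processed.aligned.values() for _, im in seq]
    if len(stack) < 10:
        raise ValueError("need >= 10 aligned images for stable region PCA")
    row_pca = regions.profile_pca(stack, "row")
    col_pca = regions.profile_pca(stack, "column")
    grid = regions.demarcate_regions(
        [row_pca.component(i) for i in cfg.row_components],
        [col_pca.component(i) for i in cfg.col_components],
        stack[0].radiance.shape,
        row_envelope=regions.body_envelope(stack, "row"),
        col_envelope=regions.body_envelope(stack, "column"),
    )
    sets = [
        regions.per_region_series(
            mid, seq, grid, floor=cfg.floor,
            growth_end_ratio=cfg.growth_end_ratio,
            relapse_ratio=cfg.relapse_ratio,
        )
        for mid, seq in sorted(processed.aligned.items())
        if len(seq) >= 2
    ]
    divergence, residual_table = regions.divergence_analysis(
        sets, n_boot=cfg.n_boot, seed=cfg.seed
    )
    corr = regions.region_correlation(sets, floor=cfg.floor)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = _provenance_header(
        cfg, ("row_components", "col_components", "n_boot", "floor", "seed")
    )
    with open(out / "region_grid.json", "w") as fh:
        json.dump({
            "shape": list(grid.shape),
            "row_boundaries": list(grid.row_boundaries),
            "col_boundaries": list(grid.col_boundaries),
            "labels": [list(r) for r in grid.labels],
        }, fh, indent=1)
    long_rows = [
        {"mouse_id": s.mouse_id, "day": float(d), "region": nm,
         "radiance": float(v)}
        for s in sets for nm, ser in s.series.items()
        for d, v in zip(ser.days, ser.values)
    ]
    _write_csv(pd.DataFrame(long_rows), out / "region_radiance.csv", hdr)
    _write_csv(divergence, out / "divergence.csv", hdr)
    _write_csv(residual_table, out / "divergence_cells.csv", hdr)
    corr.to_csv(out / "region_correlation.csv")
    return {"grid": grid, "sets": sets, "divergence": divergence,
            "residual_table": residual_table, "correlation": corr}
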
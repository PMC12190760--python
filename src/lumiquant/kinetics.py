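"""Piecewise kinetic modeling of tumor radiance trajectories.

The growth and relapse phases follow logistic growth,

    dT/dt = k T (1 - T / T_inf),

with rate ``k_growth`` (initial phase) or ``k_relapse`` (relapse phase) and
carrying capacity ``T_inf`` (the radiance at the end of the growth or
relapse phase if the carrying capacity is not yet reached).  The decay
phase is exponential relaxation toward a baseline burden ``T_B``,

    dT/dt = -k_decay (T - T_B),

so that T(t) = T_B + (T(t_decay) - T_B) exp(-k_decay (t - t_decay)).
A full trajectory is parametrized by eight quantities: T0, k_growth,
t_decay, k_decay, T_B, t_relapse, k_relapse and T_inf, plus the derived
radiance at relapse onset T1_relapse (the decay curve evaluated at
t_relapse), which makes the piecewise curve continuous at both junctions.

Fitting is per-phase nonlinear least squares on log10 radiance (values
span ~5 decades and residuals are reported in decades), with the phase
boundary times t_decay and t_relapse fixed at the segmentation's boundary
days rather than fit.  Rates flagged as outliers -- an unpenalized rate
above a cutoff, or a phase with only two datapoints -- are refit at their
Gaussian maximum a posteriori value under an empirical prior built from
the cohort's own rate distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .phases import PhaseSegmentation, RadianceSeries, segment_phases

__all__ = [
    "DynamicParams",
    "PriorSpec",
    "FitResult",
    "growth_curve",
    "decay_curve",
    "relapse_curve",
    "piecewise_predict",
    "phase_slices",
    "fit_trajectory",
    "residual_summary",
    "compute_priors",
    "bayesian_refit",
    "needs_refit",
    "apply_refits",
    "killing_rate",
    "classify_growth_speed",
    "compare_growth_relapse",
]

_LN10 = math.log(10.0)


@dataclass
class DynamicParams:
    """The eight kinetic parameters of one trajectory.

    Radiances are in photons s^-1 cm^-2 sr^-1 per pixel, rates in day^-1,
    times in days since tumor injection.  Parameters of absent phases are
    ``None``.  For trajectories without an initial growth phase, ``T0`` is
    the radiance at the start of the decay phase.
    """

    T0: float | None = None
    k_growth: float | None = None
    t_decay: float | None = None
    k_decay: float | None = None
    T_B: float | None = None
    t_relapse: float | None = None
    k_relapse: float | None = None
    T_inf: float | None = None

    def __post_init__(self) -> None:
        for name in ("T0", "T_B", "T_inf"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("k_growth", "k_decay", "k_relapse"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")
        if (
            self.t_decay is not None
            and self.t_relapse is not None
            and not self.t_decay < self.t_relapse
        ):
            raise ValueError("t_decay must precede t_relapse")

    @property
    def T1_relapse(self) -> float:
        """Radiance at relapse onset: the decay curve evaluated at t_relapse."""
        if self.t_relapse is None:
            raise ValueError("no relapse phase")
        return float(decay_curve(self.t_relapse, self))


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian prior on a kinetic rate, with the outlier cutoff that both
    defined the prior population and triggers refitting."""

    mean: float
    sd: float
    outlier_cutoff: float = 3.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("prior sd must be nonnegative")
        if not self.outlier_cutoff > self.mean:
            raise ValueError("outlier_cutoff must exceed the prior mean")


# --------------------------------------------------------------------------
# phase curves (closed-form solutions of the phase ODEs)
# --------------------------------------------------------------------------

def _logistic(t, start_val: float, k: float, T_inf: float, t0: float):
    """Logistic curve through ``start_val`` at ``t0`` with capacity T_inf.

    Written as 1 / ((1/start - 1/T_inf) e^{-k (t-t0)} + 1/T_inf), which is
    overflow-safe for large k (t - t0).
    """
    t = np.asarray(t, dtype=float)
    inv = (1.0 / start_val - 1.0 / T_inf) * np.exp(-k * (t - t0)) + 1.0 / T_inf
    return 1.0 / inv


def growth_curve(t, T0: float, k_growth: float, T_inf: float):
    """Initial-phase logistic growth from T0 at t = 0."""
    return _logistic(t, T0, k_growth, T_inf, 0.0)


def _decay(t, start_val: float, T_B: float, k_decay: float, t0: float):
    t = np.asarray(t, dtype=float)
    return T_B + (start_val - T_B) * np.exp(-k_decay * (t - t0))


def _decay_start(p: DynamicParams) -> float:
    """Radiance at the start of the decay phase (growth junction or T0)."""
    if p.k_growth is not None:
        return float(growth_curve(p.t_decay, p.T0, p.k_growth, p.T_inf))
    return float(p.T0)


def decay_curve(t, params: DynamicParams):
    """Decay-phase curve: exponential relaxation toward the baseline T_B,
    continuous with the growth phase at t_decay."""
    if params.t_decay is None or params.k_decay is None or params.T_B is None:
        raise ValueError("decay parameters are not set")
    return _decay(t, _decay_start(params), params.T_B, params.k_decay, params.t_decay)


def relapse_curve(t, params: DynamicParams):
    """Relapse-phase logistic growth from T1_relapse toward T_inf,
    continuous with the decay phase at t_relapse."""
    if params.t_relapse is None or params.k_relapse is None:
        raise ValueError("relapse parameters are not set")
    return _logistic(
        t, params.T1_relapse, params.k_relapse, params.T_inf, params.t_relapse
    )


_REQUIRED = {
    "G": ("T0", "k_growth", "T_inf"),
    "GD": ("T0", "k_growth", "T_inf", "t_decay", "k_decay", "T_B"),
    "GDR": (
        "T0", "k_growth", "T_inf", "t_decay", "k_decay", "T_B",
        "t_relapse", "k_relapse",
    ),
    "D": ("T0", "t_decay", "k_decay", "T_B"),
    "DR": ("T0", "t_decay", "k_decay", "T_B", "t_relapse", "k_relapse", "T_inf"),
}


def piecewise_predict(t, params: DynamicParams, label: str):
    """Evaluate the piecewise model at times ``t`` for a trajectory class.

    Dispatches to the phase curves; by construction the curve is continuous
    at both junctions.  Raises if ``params`` lacks the fields the class
    requires.
    """
    if label not in _REQUIRED:
        raise ValueError(f"unknown trajectory class {label!r}")
    missing = [n for n in _REQUIRED[label] if getattr(params, n) is None]
    if missing:
        raise ValueError(f"class {label} requires parameters {missing}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t)
    if label == "G":
        out = growth_curve(t, params.T0, params.k_growth, params.T_inf)
    elif label == "GD":
        g = t <= params.t_decay
        out[g] = growth_curve(t[g], params.T0, params.k_growth, params.T_inf)
        out[~g] = decay_curve(t[~g], params)
    elif label == "GDR":
        g = t <= params.t_decay
        d = (~g) & (t <= params.t_relapse)
        r = t > params.t_relapse
        out[g] = growth_curve(t[g], params.T0, params.k_growth, params.T_inf)
        out[d] = decay_curve(t[d], params)
        out[r] = relapse_curve(t[r], params)
    elif label == "D":
        out = decay_curve(t, params)
    else:  # DR
        d = t <= params.t_relapse
        out[d] = decay_curve(t[d], params)
        out[~d] = relapse_curve(t[~d], params)
    return out if out.shape else float(out)


# --------------------------------------------------------------------------
# phase bookkeeping
# --------------------------------------------------------------------------

def phase_slices(seg: PhaseSegmentation, n: int) -> dict[str, tuple[int, int]]:
    """Half-open index ranges of the data used to fit each phase.

    Junction timepoints are shared: the last growth point opens the decay
    range, and the last decay point opens the relapse range (the model
    junctions t_decay and t_relapse sit at those shared points).
    """
    label = seg.label
    if label == "G":
        return {"growth": (0, n)}
    out: dict[str, tuple[int, int]] = {}
    d_start = 0
    if seg.D_index is not None:
        out["growth"] = (0, seg.D_index + 1)
        d_start = seg.D_index
    d_stop = seg.R_index if seg.R_index is not None else n
    out["decay"] = (d_start, d_stop)
    if seg.R_index is not None:
        out["relapse"] = (seg.R_index - 1, n)
    return out


def _phase_membership(seg: PhaseSegmentation, n: int) -> np.ndarray:
    """Primary phase of each timepoint (junctions assigned to the earlier
    phase), used for per-phase residual summaries."""
    phase = np.empty(n, dtype=object)
    if seg.initial_phase == "growth" and seg.D_index is None:
        phase[:] = "growth"
        return phase
    d_start = 0
    if seg.D_index is not None:
        phase[: seg.D_index + 1] = "growth"
        d_start = seg.D_index + 1
    d_stop = seg.R_index if seg.R_index is not None else n
    phase[d_start:d_stop] = "decay"
    if seg.R_index is not None:
        phase[seg.R_index :] = "relapse"
    return phase


@dataclass
class FitResult:
    """A fitted trajectory: parameters, per-point log10 residuals
    (model minus data, one per timepoint), refit flags per rate, and the
    unpenalized least-squares objective."""

    params: DynamicParams
    label: str
    series: RadianceSeries
    segmentation: PhaseSegmentation
    residuals: np.ndarray
    phase_of_point: np.ndarray
    refit_flags: dict[str, bool] = field(default_factory=dict)
    objective: float = 0.0
    flags: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.residuals) != len(self.series):
            raise ValueError("residual count must equal timepoint count")


# --------------------------------------------------------------------------
# per-phase least squares
# --------------------------------------------------------------------------

def _multistart_ls(fun, x0, bounds, rng, n_starts: int):
    """Bounded trust-region least squares from several seeded starts."""
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    x0 = np.clip(np.asarray(x0, float), lo, hi)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        jitter = x0 + rng.normal(0.0, 0.35, size=x0.shape) * np.maximum(
            hi - lo, 1e-6
        ) * 0.25
        starts.append(np.clip(jitter, lo, hi))
    best = None
    for s in starts:
        res = least_squares(
            fun, s, bounds=(lo, hi), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
        )
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    return best


def _fit_growth(t, y, log_vmax: float, rng, n_starts: int, tinf_decades: float):
    """Fit (log10 T0, k, log10 T_inf) to log10 radiance of the growth data.

    T_inf is bounded below by the trajectory's maximum observed radiance
    and above by ``tinf_decades`` decades more; with only two datapoints
    T_inf is pinned at its upper bound (a two-point phase cannot constrain
    a plateau, and the curve is then effectively exponential).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    lo_inf, hi_inf = log_vmax, log_vmax + tinf_decades
    slope = np.polyfit(t, y, 1)[0] if len(t) > 1 else 0.0
    k0 = float(np.clip(slope * _LN10, 1e-3, 9.0))
    a0 = float(y[0] - k0 * t[0] / _LN10)

    if len(t) == 2:
        T_inf = 10.0**hi_inf

        def fun2(x):
            return np.log10(_logistic(t, 10.0 ** x[0], x[1], T_inf, 0.0)) - y

        res = _multistart_ls(
            fun2, [a0, k0],
            ([y.min() - 3.0, 0.0], [y.max() + 3.0, 12.0]),
            rng, n_starts,
        )
        return 10.0 ** res.x[0], float(res.x[1]), T_inf, float(res.cost)

    def fun(x):
        return np.log10(_logistic(t, 10.0 ** x[0], x[1], 10.0 ** x[2], 0.0)) - y

    lo = [y.min() - 3.0, 0.0, lo_inf]
    hi = [y.max() + 3.0, 12.0, hi_inf]
    starts_inf = [hi_inf, lo_inf + 0.3, 0.5 * (lo_inf + hi_inf)]
    best = None
    for i, inf0 in enumerate(starts_inf):
        res = _multistart_ls(
            fun, [a0, k0, inf0], (lo, hi), rng,
            n_starts if i == 0 else max(1, n_starts // 2),
        )
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    return (
        10.0 ** best.x[0], float(best.x[1]), 10.0 ** best.x[2], float(best.cost)
    )


def _fit_decay(t, y, t0: float, start_log10: float | None, floor: float,
               rng, n_starts: int):
    """Fit (k_decay, log10 T_B [, log10 start]) to log10 decay-phase data.

    ``start_log10`` fixes the junction value propagated from the growth
    fit; when the series opens in decay the start value is free.  T_B is
    bounded below by the detection floor and above by the smallest of the
    junction value and the data ceiling.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    lb_tb = math.log10(floor)
    k0 = float(np.clip(-np.polyfit(t, y, 1)[0] * _LN10, 1e-3, 15.0))
    if start_log10 is not None:
        ub_tb = min(y.max(), start_log10 - 1e-3)
        if ub_tb <= lb_tb + 1e-9:
            # decayed straight to the floor: baseline pinned, rate only
            S = 10.0**start_log10

            def fun1(x):
                return np.log10(_decay(t, S, floor, x[0], t0)) - y

            res = _multistart_ls(fun1, [k0], ([0.0], [20.0]), rng, n_starts)
            return float(res.x[0]), floor, None, float(res.cost)

        S = 10.0**start_log10

        def fun(x):
            return np.log10(_decay(t, S, 10.0 ** x[1], x[0], t0)) - y

        tb0 = min(max(y.min() - 0.3, lb_tb), ub_tb)
        res = _multistart_ls(
            fun, [k0, tb0], ([0.0, lb_tb], [20.0, ub_tb]), rng, n_starts
        )
        return float(res.x[0]), 10.0 ** res.x[1], None, float(res.cost)

    # no growth phase: the start value is a free parameter
    def fun(x):
        return np.log10(_decay(t, 10.0 ** x[2], 10.0 ** x[1], x[0], t0)) - y

    ub_tb = y.max()
    tb0 = min(max(y.min() - 0.3, lb_tb), ub_tb)
    res = _multistart_ls(
        fun,
        [k0, tb0, y[0]],
        ([0.0, lb_tb, y.min() - 1.0], [20.0, ub_tb, y.max() + 1.0]),
        rng, n_starts,
    )
    return float(res.x[0]), 10.0 ** res.x[1], 10.0 ** res.x[2], float(res.cost)


def _fit_relapse(t, y, tR: float, T1R: float, log_vmax: float,
                 T_inf_shared: float | None, rng, n_starts: int,
                 tinf_decades: float):
    """Fit k_relapse (and T_inf when no growth phase supplied one) to
    log10 relapse-phase data, anchored at T1_relapse."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    k0 = float(np.clip(np.polyfit(t, y, 1)[0] * _LN10, 1e-3, 9.0))
    if T_inf_shared is not None:
        T_inf = max(T_inf_shared, T1R * 1.0001)

        def fun1(x):
            return np.log10(_logistic(t, T1R, x[0], T_inf, tR)) - y

        res = _multistart_ls(fun1, [k0], ([0.0], [12.0]), rng, n_starts)
        return float(res.x[0]), T_inf, float(res.cost)

    lo_inf = max(log_vmax, math.log10(T1R) + 1e-3)
    hi_inf = lo_inf + tinf_decades

    def fun(x):
        return np.log10(_logistic(t, T1R, x[0], 10.0 ** x[1], tR)) - y

    res = _multistart_ls(
        fun, [k0, hi_inf], ([0.0, lo_inf], [12.0, hi_inf]), rng, n_starts
    )
    return float(res.x[0]), 10.0 ** res.x[1], float(res.cost)


def fit_trajectory(
    series: RadianceSeries,
    seg: PhaseSegmentation | None = None,
    *,
    floor: float = 1e3,
    n_starts: int = 5,
    seed: int = 0,
    tinf_decades: float = 2.0,
    shared_tinf: bool = False,
    joint_polish: bool = True,
) -> FitResult:
    """Fit the piecewise model to one segmented radiance series.

    Each present phase is fit by nonlinear least squares on log10
    radiance, with t_decay and t_relapse fixed at the segmentation's
    boundary days (the shared junction timepoints) and junction values
    propagated forward so the piecewise curve is continuous.  T_inf is
    bounded to [max(values), 10^tinf_decades * max(values)] and fit per
    phase by default: in a sequential piecewise fit the growth phase
    rarely reaches its plateau, so a growth-estimated capacity is weakly
    identified and would bias the relapse rate if shared
    (``shared_tinf=True`` restores sharing).  A phase with fewer than two
    timepoints is skipped with a flag.  Deterministic for a given ``seed``
    (which drives the multi-start jitter).
    """
    if seg is None:
        seg = segment_phases(series, floor=floor)
    t = series.days
    y = np.log10(np.maximum(series.values, floor))
    n = len(series)
    log_vmax = float(y.max())
    rng = np.random.default_rng(seed)
    slices = phase_slices(seg, n)
    flags: list[str] = []
    p = DynamicParams()
    cost = 0.0

    if "growth" in slices:
        i0, i1 = slices["growth"]
        if i1 - i0 >= 2:
            T0, kG, T_inf, c = _fit_growth(
                t[i0:i1], y[i0:i1], log_vmax, rng, n_starts, tinf_decades
            )
            p = replace(p, T0=T0, k_growth=kG, T_inf=T_inf)
            cost += c
        else:
            flags.append("growth_skipped")

    if "decay" in slices:
        i0, i1 = slices["decay"]
        t_decay = float(t[i0])
        if i1 - i0 >= 2:
            start_log10 = (
                float(np.log10(growth_curve(t_decay, p.T0, p.k_growth, p.T_inf)))
                if p.k_growth is not None
                else None
            )
            kD, T_B, S_free, c = _fit_decay(
                t[i0:i1], y[i0:i1], t_decay, start_log10, floor, rng, n_starts
            )
            p = replace(
                p,
                t_decay=t_decay,
                k_decay=kD,
                T_B=T_B,
                T0=p.T0 if S_free is None else S_free,
            )
            cost += c
        else:
            flags.append("decay_skipped")
            # anchor the junction at the observed value so relapse can fit
            p = replace(
                p, t_decay=t_decay, k_decay=0.0, T_B=float(10.0 ** y[i0]),
                T0=p.T0 if p.T0 is not None else float(10.0 ** y[i0]),
            )

    if "relapse" in slices:
        i0, i1 = slices["relapse"]
        t_relapse = float(t[i0])
        if i1 - i0 >= 2:
            probe = replace(p, t_relapse=t_relapse, k_relapse=0.0,
                            T_inf=p.T_inf or 1.0)
            T1R = probe.T1_relapse
            kR, T_inf, c = _fit_relapse(
                t[i0:i1], y[i0:i1], t_relapse, T1R, log_vmax,
                p.T_inf if (shared_tinf and p.k_growth is not None) else None,
                rng, n_starts, tinf_decades,
            )
            p = replace(p, t_relapse=t_relapse, k_relapse=kR, T_inf=T_inf)
            cost += c
        else:
            flags.append("relapse_skipped")

    if joint_polish and not _incomplete(p, seg.label) and seg.label != "G":
        p = _polish_joint(t, y, p, seg.label, floor, log_vmax, tinf_decades)

    model = piecewise_predict(t, p, seg.label) if not _incomplete(p, seg.label) \
        else np.full(n, np.nan)
    with np.errstate(divide="ignore"):
        residuals = np.log10(np.maximum(model, 1e-300)) - y
    return FitResult(
        params=p,
        label=seg.label,
        series=series,
        segmentation=seg,
        residuals=residuals,
        phase_of_point=_phase_membership(seg, n),
        refit_flags={"k_growth": False, "k_relapse": False},
        objective=float(np.nansum(residuals**2)),
        flags=flags,
        provenance={
            "floor": floor, "n_starts": n_starts, "seed": seed,
            "tinf_decades": tinf_decades, "shared_tinf": shared_tinf,
            "joint_polish": joint_polish,
        },
    )


def _incomplete(p: DynamicParams, label: str) -> bool:
    return any(getattr(p, nm) is None for nm in _REQUIRED[label])


def _polish_joint(t, y, p: DynamicParams, label: str, floor: float,
                  log_vmax: float, tinf_decades: float) -> DynamicParams:
    """Joint full-series refinement of the sequential per-phase estimates.

    The sequential pass freezes each junction value at the preceding
    phase's estimate, so its noise leaks into the next phase's rate; a
    single bounded least-squares pass over all free parameters (junction
    times stay fixed, continuity holds by construction) lets every phase's
    data inform the shared quantities.  Initialized at the sequential
    solution, so it can only decrease the objective.
    """
    names: list[str] = ["logT0"]
    if label in ("GD", "GDR"):
        names += ["k_growth", "logTinf", "k_decay", "logTB"]
    elif label == "D":
        names += ["k_decay", "logTB"]
    else:  # DR
        names += ["k_decay", "logTB", "logTinf"]
    if label in ("GDR", "DR"):
        names += ["k_relapse"]

    init = {
        "logT0": math.log10(p.T0), "k_growth": p.k_growth,
        "logTinf": math.log10(p.T_inf) if p.T_inf else log_vmax,
        "k_decay": p.k_decay,
        "logTB": math.log10(p.T_B) if p.T_B else math.log10(floor),
        "k_relapse": p.k_relapse,
    }
    lo = {"logT0": y.min() - 3.0, "k_growth": 0.0, "logTinf": log_vmax,
          "k_decay": 0.0, "logTB": math.log10(floor), "k_relapse": 0.0}
    hi = {"logT0": y.max() + 3.0, "k_growth": 12.0,
          "logTinf": log_vmax + tinf_decades, "k_decay": 20.0,
          "logTB": float(y.max()), "k_relapse": 12.0}

    def build(x) -> DynamicParams:
        d = dict(zip(names, x))
        return replace(
            p,
            T0=10.0 ** d["logT0"],
            k_growth=d.get("k_growth", p.k_growth),
            T_inf=10.0 ** d["logTinf"] if "logTinf" in d else p.T_inf,
            k_decay=d.get("k_decay", p.k_decay),
            T_B=10.0 ** d["logTB"] if "logTB" in d else p.T_B,
            k_relapse=d.get("k_relapse", p.k_relapse),
        )

    def fun(x):
        return np.log10(
            np.maximum(piecewise_predict(t, build(x), label), 1e-300)
        ) - y

    x0 = np.clip(
        np.array([init[nm] for nm in names], dtype=float),
        np.array([lo[nm] for nm in names]),
        np.array([hi[nm] for nm in names]),
    )
    res = least_squares(
        fun, x0,
        bounds=([lo[nm] for nm in names], [hi[nm] for nm in names]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=600,
    )
    if res.cost <= 0.5 * np.sum(fun(x0) ** 2) + 1e-12:
        return build(res.x)
    return p


# --------------------------------------------------------------------------
# residual and population summaries
# --------------------------------------------------------------------------

def residual_summary(
    fits: Iterable[FitResult], *, decade: float = 1.0,
    bins: np.ndarray | None = None,
) -> dict:
    """Per-phase fraction of |log10 residual| below one decade, plus a
    pooled residual histogram."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to summarize")
    res = np.concatenate([f.residuals for f in fits])
    phase = np.concatenate([f.phase_of_point for f in fits])
    ok = np.isfinite(res)
    res, phase = res[ok], phase[ok]
    out: dict = {"fraction_within_decade": {}, "n_points": {}}
    for ph in ("growth", "decay", "relapse"):
        sel = phase == ph
        if sel.any():
            out["fraction_within_decade"][ph] = float(
                np.mean(np.abs(res[sel]) < decade)
            )
            out["n_points"][ph] = int(sel.sum())
    if bins is None:
        bins = np.linspace(-2.0, 2.0, 41)
    hist, edges = np.histogram(res, bins=bins)
    out["histogram"] = {"counts": hist.tolist(), "edges": edges.tolist()}
    return out


def compute_priors(
    rates: Sequence[float], cutoff: float = 3.0
) -> PriorSpec:
    """Empirical Gaussian prior from a cohort's fitted rates.

    Rates strictly above ``cutoff`` (day^-1) are removed as outliers; the
    prior is the mean and sample standard deviation of the survivors.
    Fewer than two surviving rates is an error.
    """
    r = np.asarray(list(rates), dtype=float)
    keep = r[r <= cutoff]
    if len(keep) < 2:
        raise ValueError("need at least two rates at or below the cutoff")
    return PriorSpec(
        mean=float(keep.mean()), sd=float(keep.std(ddof=1)), outlier_cutoff=cutoff
    )


# --------------------------------------------------------------------------
# Bayesian MAP refit
# --------------------------------------------------------------------------

_RATE_PHASE = {"k_growth": "growth", "k_relapse": "relapse"}


def needs_refit(fit: FitResult, which: str, prior: PriorSpec) -> bool:
    """Refit trigger: unpenalized rate above the outlier cutoff, or a
    two-point phase (where rate outliers concentrate)."""
    if which not in _RATE_PHASE:
        raise ValueError("refit applies to k_growth or k_relapse only")
    rate = getattr(fit.params, which)
    if rate is None:
        return False
    sl = phase_slices(fit.segmentation, len(fit.series)).get(_RATE_PHASE[which])
    if sl is None:
        return False
    return rate > prior.outlier_cutoff or (sl[1] - sl[0]) == 2


def bayesian_refit(
    fit: FitResult,
    prior: PriorSpec,
    *,
    which: str = "k_growth",
    noise_sd: float = 0.15,
) -> FitResult:
    """Replace one rate by its Gaussian maximum a posteriori value.

    Minimizes sum((log10 residual / noise_sd)^2) over the phase's
    timepoints plus ((k - mean)/sd)^2, as a 1-D problem in the rate with
    the other phase parameters held at their fitted values.  ``noise_sd``
    is the assumed measurement noise in log10 decades.  Junction values
    downstream of a refit growth rate are re-propagated through the
    parameter set (the decay start and T1_relapse are derived quantities).
    """
    if which not in _RATE_PHASE:
        raise ValueError("refit applies to k_growth or k_relapse only")
    if prior.sd <= 0:
        raise ValueError("refit requires a prior with sd > 0")
    phase = _RATE_PHASE[which]
    sl = phase_slices(fit.segmentation, len(fit.series)).get(phase)
    rate0 = getattr(fit.params, which)
    if sl is None or rate0 is None:
        raise ValueError(f"fit has no {phase} phase to refit")
    i0, i1 = sl
    t = fit.series.days[i0:i1]
    floor = fit.provenance.get("floor", 1e3)
    y = np.log10(np.maximum(fit.series.values[i0:i1], floor))
    p = fit.params

    if which == "k_growth":
        def model(k):
            return growth_curve(t, p.T0, k, p.T_inf)
    else:
        def model(k):
            return relapse_curve(t, replace(p, k_relapse=k))

    def objective(k):
        r = (np.log10(model(k)) - y) / noise_sd
        return float(np.sum(r**2) + ((k - prior.mean) / prior.sd) ** 2)

    hi = max(rate0, prior.mean) + 2.0
    res = minimize_scalar(
        objective, bounds=(0.0, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    k_map = float(res.x)
    new_params = replace(p, **{which: k_map})
    modelled = piecewise_predict(fit.series.days, new_params, fit.label)
    y_all = np.log10(np.maximum(fit.series.values, floor))
    residuals = np.log10(np.maximum(modelled, 1e-300)) - y_all
    flags = dict(fit.refit_flags)
    flags[which] = True
    return replace(
        fit,
        params=new_params,
        residuals=residuals,
        refit_flags=flags,
        objective=float(np.nansum(residuals**2)),
        provenance={**fit.provenance, f"refit_{which}": {
            "prior_mean": prior.mean, "prior_sd": prior.sd,
            "noise_sd": noise_sd, "unpenalized": rate0,
        }},
    )


def apply_refits(
    fit: FitResult,
    priors: dict[str, PriorSpec],
    *,
    noise_sd: float = 0.15,
) -> FitResult:
    """Apply the trigger rule and MAP-refit whichever rates it flags."""
    out = fit
    for which, prior in priors.items():
        if getattr(out.params, which) is not None and needs_refit(out, which, prior):
            out = bayesian_refit(out, prior, which=which, noise_sd=noise_sd)
    return out


# --------------------------------------------------------------------------
# population-level rate analyses
# --------------------------------------------------------------------------

def killing_rate(k_growth_treated: float, k_control: float) -> float:
    """CAR-T killing rate: the tumor growth rate without treatment minus
    the growth rate under treatment (k - kGrowth; may be negative)."""
    if k_growth_treated < 0 or k_control < 0:
        raise ValueError("rates must be nonnegative")
    return k_control - k_growth_treated


def cohort_killing_rates(
    rates: pd.DataFrame,
    *,
    rate_col: str = "k_growth",
    control_col: str = "is_control",
    group_col: str | None = None,
) -> pd.DataFrame:
    """Killing rate for every treated mouse, against the mean fitted growth
    rate of the control (untreated/mock) mice of the same group.

    Raises if any group lacks control mice.
    """
    df = rates.copy()
    if group_col is None:
        group_col = "_all"
        df[group_col] = "all"
    out = []
    for g, sub in df.groupby(group_col):
        ctrl = sub.loc[sub[control_col].astype(bool), rate_col]
        if ctrl.empty:
            raise ValueError(f"no control mice in group {g!r}")
        k_control = float(ctrl.mean())
        treated = sub.loc[~sub[control_col].astype(bool)].copy()
        treated["killing_rate"] = [
            killing_rate(k, k_control) for k in treated[rate_col]
        ]
        treated["k_control"] = k_control
        out.append(treated)
    return pd.concat(out, ignore_index=True) if out else df.iloc[0:0]


def classify_growth_speed(k_growth: float, threshold: float = 0.85) -> str:
    """Dichotomize the initial growth rate: 'slow' iff k <= threshold
    (day^-1), else 'fast'."""
    if k_growth < 0:
        raise ValueError("k_growth must be nonnegative")
    return "slow" if k_growth <= threshold else "fast"


def compare_growth_relapse(
    fits: Iterable[FitResult],
) -> tuple[float, pd.DataFrame]:
    """Fraction of relapsing mice whose relapse growth rate is below their
    initial growth rate, with the paired rates."""
    rows = []
    for f in fits:
        kg, kr = f.params.k_growth, f.params.k_relapse
        if kg is None or kr is None:
            raise ValueError(
                f"fit for {f.series.mouse_id!r} lacks a growth or relapse rate"
            )
        rows.append({"mouse_id": f.series.mouse_id, "k_growth": kg,
                     "k_relapse": kr})
    if not rows:
        raise ValueError("no fits supplied")
    df = pd.DataFrame(rows)
    frac = float((df["k_relapse"] < df["k_growth"]).mean())
    return frac, df
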
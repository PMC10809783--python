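"""Per-cycle biophysical function metrics of surfactant films.

Three parameters characterize how well a surfactant film performs under
cyclic compression:

* the per-cycle extremum of the surface measure -- maximum surface pressure
  Pi_max (LBT) or minimum surface tension gamma_min (CSD);
* the compressibility modulus ``kappa = -A * dPi/dA`` (the reciprocal of the
  compressibility C), computed pointwise along a branch, or as a single
  "global" slope ``|dgamma/dA|`` between the iso-cycle extrema when the cycle
  is too sparsely sampled for derivatives;
* the hysteresis ``dA``: the area gap between the compression and expansion
  branches at half of the cycle's maximum surface measure, a proxy for
  material loss or refinement during the cycle.

Across many cycles, gamma_min typically relaxes toward a plateau; this module
fits mono- and biexponential decays parameterized directly by half-lives,
``y(t) = plateau + sum_i a_i * 2**(-t / thalf_i)``, with an
extra-sum-of-squares F test for model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.signal import savgol_filter

from .trace_io import CycleSet, SurfactometryTrace

__all__ = [
    "CycleMetrics",
    "ModulusCurve",
    "GlobalCompressibility",
    "DecayFit",
    "RelativeMetric",
    "WindowSummary",
    "MonotonicityError",
    "DegenerateCycleError",
    "CoverageError",
    "WindowError",
    "FitFailureError",
    "cycle_extrema",
    "modulus_curve",
    "global_compressibility",
    "hysteresis",
    "summarize_windows",
    "relative_to_control",
    "fit_decay",
    "half_life_to_rate",
    "rate_to_half_life",
]


class MonotonicityError(ValueError):
    """A branch is not strictly monotone in area after deduplication."""


class DegenerateCycleError(ValueError):
    """A cycle has no area separation between its surface extrema."""


class CoverageError(ValueError):
    """A branch does not cross the requested surface level."""


class WindowError(ValueError):
    """Requested summary window exceeds the number of usable cycles."""


class FitFailureError(RuntimeError):
    """Decay fit failed to converge; carries the best residual found."""

    def __init__(self, message: str, best_rss: float):
        super().__init__(message)
        self.best_rss = best_rss


@dataclass
class CycleMetrics:
    """Extremum, compressibility and hysteresis values for one iso-cycle."""

    cycle_index: int  # 1-based
    complete: bool
    pi_max: float | None = None
    gamma_min: float | None = None
    area_at_extremum: float | None = None
    hysteresis_area: float | None = None
    global_compressibility: float | None = None


def cycle_extrema(trace: SurfactometryTrace, cycles: CycleSet) -> list[CycleMetrics]:
    """Per-cycle Pi_max (pressure traces) or gamma_min (tension traces).

    Values are taken from the raw samples of each cycle (no interpolation),
    together with the area at which the extremum occurs.  Incomplete cycles
    are included but flagged so that downstream summaries can skip them.
    """
    out: list[CycleMetrics] = []
    for k, cyc in enumerate(cycles.cycles, start=1):
        lo, hi = cyc.start, cyc.stop
        seg = trace.surface_value[lo : hi + 1]
        if trace.measure_kind == "pressure":
            j = int(np.argmax(seg))
            m = CycleMetrics(k, cyc.complete, pi_max=float(seg[j]))
        else:
            j = int(np.argmin(seg))
            m = CycleMetrics(k, cyc.complete, gamma_min=float(seg[j]))
        m.area_at_extremum = float(trace.area[lo + j])
        out.append(m)
    if not out:
        # Zero-cycle traces are a warning condition, not an exception.
        return out
    return out


@dataclass
class ModulusCurve:
    """Pointwise compressibility modulus along one branch, raw and smoothed."""

    pressure_grid: np.ndarray
    kappa_raw: np.ndarray
    kappa_smoothed: np.ndarray
    branch: str = "compression"


def _dedupe_area(area: np.ndarray, surface: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse consecutive runs of identical area, averaging the surface measure."""
    new_run = np.empty(area.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = area[1:] != area[:-1]
    if new_run.all():
        return area.astype(float), surface.astype(float)
    run_id = np.cumsum(new_run) - 1
    counts = np.bincount(run_id)
    a = np.bincount(run_id, weights=area) / counts
    s = np.bincount(run_id, weights=surface) / counts
    return a, s


def modulus_curve(
    area,
    pressure,
    sg_window: int = 9,
    sg_order: int = 3,
    branch: str = "compression",
) -> ModulusCurve:
    """Compressibility modulus ``kappa = -A * dPi/dA`` along a branch.

    The derivative uses centered finite differences at interior points and
    one-sided differences at the ends (``numpy.gradient`` on the non-uniform
    area grid).  ``kappa_smoothed`` applies a Savitzky-Golay filter
    (default 9-point window, cubic) to the raw modulus, reported against the
    surface pressure at the same samples.
    """
    area = np.asarray(area, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    if area.size != pressure.size:
        raise ValueError("area and pressure must have equal length")
    area, pressure = _dedupe_area(area, pressure)
    d = np.diff(area)
    if not (np.all(d > 0) or np.all(d < 0)):
        bad = int(np.argmax(np.sign(d) != np.sign(d[0])))
        raise MonotonicityError(
            f"branch area is not strictly monotone: first violation between "
            f"samples {bad} and {bad + 1}"
        )
    if area.size < sg_window:
        raise ValueError(
            f"branch has {area.size} points, fewer than sg_window={sg_window}"
        )
    kappa_raw = -area * np.gradient(pressure, area)
    kappa_smoothed = savgol_filter(kappa_raw, sg_window, sg_order)
    return ModulusCurve(pressure, kappa_raw, kappa_smoothed, branch)


@dataclass(frozen=True)
class GlobalCompressibility:
    """Endpoint slope |dgamma/dA| of a sparsely sampled iso-cycle."""

    value: float  # positive magnitude, mN/m per area unit
    signed_slope: float


def global_compressibility(area, surface) -> GlobalCompressibility:
    """Slope between the minimum and maximum surface points of a branch.

    For drop surfactometer cycles with too few points for pointwise moduli,
    the compressibility is estimated as the endpoint slope
    ``(gamma_max - gamma_min) / (A_at_gamma_max - A_at_gamma_min)`` on the
    compression branch.  Reported as a positive magnitude; the signed slope
    is retained alongside.
    """
    area = np.asarray(area, dtype=float)
    surface = np.asarray(surface, dtype=float)
    i_max = int(np.argmax(surface))
    i_min = int(np.argmin(surface))
    dA = area[i_max] - area[i_min]
    if dA == 0.0:
        if surface[i_max] == surface[i_min]:
            return GlobalCompressibility(0.0, 0.0)
        raise DegenerateCycleError("zero area difference between surface extrema")
    slope = (surface[i_max] - surface[i_min]) / dA
    return GlobalCompressibility(abs(slope), float(slope))


def _area_at_level(area: np.ndarray, surface: np.ndarray, level: float, label: str) -> float:
    """Area at the first crossing of ``surface == level``, linearly interpolated."""
    s = surface - level
    if s[0] == 0.0:
        return float(area[0])
    crossings = np.nonzero(s[:-1] * s[1:] <= 0.0)[0]
    if crossings.size == 0:
        raise CoverageError(f"{label} branch does not cross level {level:g} mN/m")
    i = int(crossings[0])
    if s[i + 1] == s[i]:
        return float(area[i])
    frac = -s[i] / (s[i + 1] - s[i])
    return float(area[i] + frac * (area[i + 1] - area[i]))


def hysteresis(
    comp_area,
    comp_surface,
    exp_area,
    exp_surface,
    measure_kind: str = "pressure",
) -> float:
    """Area gap dA between compression and expansion at half-maximum.

    The level is half the whole-cycle maximum of the surface measure
    (pressure for LBT, tension for CSD).  Each branch's area at that level is
    found by linear interpolation at its first crossing; the result is
    ``A_compression - A_expansion`` (positive when the expansion branch lies
    inside the compression branch, the typical loss/refinement signature).
    """
    comp_area = np.asarray(comp_area, dtype=float)
    comp_surface = np.asarray(comp_surface, dtype=float)
    exp_area = np.asarray(exp_area, dtype=float)
    exp_surface = np.asarray(exp_surface, dtype=float)
    level = 0.5 * max(float(np.max(comp_surface)), float(np.max(exp_surface)))
    a_comp = _area_at_level(comp_area, comp_surface, level, "compression")
    a_exp = _area_at_level(exp_area, exp_surface, level, "expansion")
    return a_comp - a_exp


def cycle_hysteresis(trace: SurfactometryTrace, cycles: CycleSet) -> list[float | None]:
    """Hysteresis of every complete cycle of a trace (None when incomplete)."""
    out: list[float | None] = []
    for cyc in cycles.cycles:
        if not cyc.complete or cyc.expansion is None:
            out.append(None)
            continue
        c0, c1 = cyc.compression
        e0, e1 = cyc.expansion
        out.append(
            hysteresis(
                trace.area[c0 : c1 + 1],
                trace.surface_value[c0 : c1 + 1],
                trace.area[e0 : e1 + 1],
                trace.surface_value[e0 : e1 + 1],
                measure_kind=trace.measure_kind,
            )
        )
    return out


@dataclass(frozen=True)
class WindowSummary:
    """Mean +/- standard error of a metric over first/last cycle windows."""

    field: str
    first_mean: float
    first_sem: float
    last_mean: float
    last_sem: float
    first_n: int
    last_n: int
    n_used: int


def summarize_windows(
    metrics: list[CycleMetrics],
    first_n: int,
    last_n: int,
    field_name: str | None = None,
) -> WindowSummary:
    """Mean and standard error over the first and last N complete cycles.

    Incomplete (flagged) cycles are skipped before windowing.  The default
    field is ``gamma_min`` when present, else ``pi_max``.
    """
    usable = [m for m in metrics if m.complete]
    if field_name is None:
        field_name = "gamma_min" if any(m.gamma_min is not None for m in usable) else "pi_max"
    values = np.array(
        [getattr(m, field_name) for m in usable if getattr(m, field_name) is not None],
        dtype=float,
    )
    need = max(first_n, last_n)
    if values.size < need:
        raise WindowError(
            f"window of {need} cycles requested but only {values.size} usable "
            f"cycles carry {field_name}"
        )

    def _mean_sem(x: np.ndarray) -> tuple[float, float]:
        if x.size == 1:
            return float(x[0]), 0.0
        return float(np.mean(x)), float(np.std(x, ddof=1) / math.sqrt(x.size))

    fm, fs = _mean_sem(values[:first_n])
    lm, ls = _mean_sem(values[-last_n:])
    return WindowSummary(field_name, fm, fs, lm, ls, first_n, last_n, int(values.size))


@dataclass(frozen=True)
class RelativeMetric:
    """A metric expressed as a ratio to a control condition."""

    value: float
    reference_label: str


def relative_to_control(value: float, control_value: float, reference_label: str = "control") -> RelativeMetric:
    """Ratio of a metric to its control; the control relative to itself is 1."""
    if control_value == 0:
        raise ZeroDivisionError("control value is zero; relative metric undefined")
    return RelativeMetric(value / control_value, reference_label)


def half_life_to_rate(t_half: float) -> float:
    """Exponential rate constant (1/s) equivalent to a half-life (s)."""
    return math.log(2.0) / t_half


def rate_to_half_life(rate: float) -> float:
    """Half-life (s) equivalent to an exponential rate constant (1/s)."""
    return math.log(2.0) / rate


@dataclass
class DecayFit:
    """Mono- or biexponential decay of gamma_min across cycles.

    The model is ``y(t) = plateau + sum_i a_i * 2**(-t / thalf_i)`` with
    non-negative amplitudes, so the printed half-lives are the parameters
    themselves.  ``half_lives`` are sorted ascending with ``amplitudes``
    aligned.
    """

    model: str  # "mono" or "bi"
    plateau: float
    amplitudes: np.ndarray
    half_lives: np.ndarray
    rss: float
    n_points: int
    selection: dict = field(default_factory=dict)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.plateau, dtype=float)
        for a, h in zip(self.amplitudes, self.half_lives):
            y = y + a * np.exp2(-t / h)
        return y

    @property
    def n_params(self) -> int:
        return 1 + 2 * len(self.half_lives)


def _design(t: np.ndarray, half_lives: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(t)] + [np.exp2(-t / h) for h in half_lives]
    return np.column_stack(cols)


def _nnls_at(t: np.ndarray, y: np.ndarray, half_lives: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative amplitudes (and plateau >= 0) at fixed half-lives."""
    X = _design(t, half_lives)
    coef, _ = optimize.nnls(X, y)
    resid = y - X @ coef
    return coef, float(resid @ resid)

def _halflife_grid(t: np.ndarray, n: int) -> np.ndarray:
    dt = np.diff(t)
    dt_min = float(dt[dt > 0].min()) if np.any(dt > 0) else 1.0
    total = float(t[-1] - t[0]) or 1.0
    return np.geomspace(max(dt_min, 1e-6), 10.0 * total, n)


def _fit_k(t: np.ndarray, y: np.ndarray, k: int) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Best k-phase fit: coarse half-life grid + NNLS, then bounded refinement.

    Deterministic by construction -- the multi-start grid is fixed by the
    time base, no random numbers are involved.
    """
    if k == 1:
        grid = [(h,) for h in _halflife_grid(t, 40)]
    else:
        g = _halflife_grid(t, 16)
        grid = [(g[i], g[j]) for i in range(len(g)) for j in range(i + 1, len(g))]

    best_rss = np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    for hs in grid:
        hs_arr = np.array(hs)
        coef, rss = _nnls_at(t, y, hs_arr)
        if rss < best_rss:
            best_rss = rss
            best = (coef, hs_arr)
    if best is None:
        raise FitFailureError("no admissible grid start", math.inf)
    coef0, hs0 = best

    # Refine (plateau, amplitudes, half-lives) jointly under the constraints
    # a_i >= 0, thalf_i > 0; plateau left free.
    p0 = np.concatenate([[coef0[0]], coef0[1:], hs0])
    lb = np.concatenate([[-np.inf], np.zeros(k), np.full(k, 1e-9)])
    ub = np.full(1 + 2 * k, np.inf)
    p0 = np.clip(p0, lb + 1e-12, None)

    def residuals(p):
        plateau, amps, hs = p[0], p[1 : 1 + k], p[1 + k :]
        pred = plateau + sum(a * np.exp2(-t / h) for a, h in zip(amps, hs))
        return pred - y

    try:
        sol = optimize.least_squares(residuals, p0, bounds=(lb, ub), method="trf")
        refined = sol.x
        rss_ref = float(sol.fun @ sol.fun)
    except Exception:
        refined, rss_ref = p0, best_rss
    if not np.isfinite(rss_ref) or rss_ref > best_rss:
        refined, rss_ref = p0, best_rss

    plateau = float(refined[0])
    amps = np.asarray(refined[1 : 1 + k], dtype=float)
    hs = np.asarray(refined[1 + k :], dtype=float)
    order = np.argsort(hs)
    return plateau, amps[order], hs[order], rss_ref


def fit_decay(times, values, model: str = "auto", alpha: float = 0.05, criterion: str = "ftest") -> DecayFit:
    """Fit gamma_min(t) with a mono- or biexponential half-life decay.

    ``model="auto"`` fits both and keeps the biexponential only when the
    extra-sum-of-squares F test rejects the monoexponential at ``alpha``
    (``criterion="aicc"`` selects by corrected AIC instead).  The fit is
    deterministic: a fixed log-spaced half-life grid with non-negative linear
    least squares provides the starts, followed by bounded refinement.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values must have equal length")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    if model not in ("mono", "bi", "auto"):
        raise ValueError(f"unknown model {model!r}")
    k_needed = {"mono": 3, "bi": 5, "auto": 5}[model]
    if t.size < 3 * k_needed:
        raise ValueError(
            f"need at least {3 * k_needed} points for model={model!r}, got {t.size}"
        )

    if model == "mono":
        plateau, amps, hs, rss = _fit_k(t, y, 1)
        return DecayFit("mono", plateau, amps, hs, rss, t.size)

    mono = _fit_k(t, y, 1)
    bi = _fit_k(t, y, 2)
    rss_m, rss_b = mono[3], bi[3]
    if rss_b > rss_m:
        # The mono optimum is a boundary point of the bi model; never let
        # numerical refinement report a worse bi fit.
        bi = (mono[0], np.array([mono[1][0], 0.0]), np.array([mono[2][0], mono[2][0] * 10]), rss_m)
        rss_b = rss_m

    if model == "bi":
        return DecayFit("bi", bi[0], bi[1], bi[2], rss_b, t.size)

    n = t.size
    selection: dict = {"rss_mono": rss_m, "rss_bi": rss_b, "criterion": criterion}
    scale = float(np.mean(y**2)) or 1.0
    if criterion == "aicc":
        def aicc(rss, p):
            if n - p - 1 <= 0:
                return np.inf
            return n * math.log(max(rss, 1e-300) / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)
        pick_bi = aicc(rss_b, 5) < aicc(rss_m, 3)
        selection["aicc_mono"] = aicc(rss_m, 3)
        selection["aicc_bi"] = aicc(rss_b, 5)
    else:
        if rss_m <= 1e-20 * n * scale:
            # Mono already explains the data to machine precision.
            pick_bi = False
            selection["p_value"] = 1.0
        elif rss_b <= 1e-20 * n * scale:
            pick_bi = True
            selection["p_value"] = 0.0
        else:
            df2 = n - 5
            f_stat = ((rss_m - rss_b) / 2.0) / (rss_b / df2)
            p_val = float(stats.f.sf(f_stat, 2, df2)) if f_stat > 0 else 1.0
            pick_bi = p_val < alpha
            selection["f_stat"] = f_stat
            selection["p_value"] = p_val

    if pick_bi:
        fit = DecayFit("bi", bi[0], bi[1], bi[2], rss_b, n, selection)
    else:
        fit = DecayFit("mono", mono[0], mono[1], mono[2], rss_m, n, selection)
    return fit
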
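"""Reading, writing, validation and cycle segmentation of surfactometry traces.

A surfactometry trace is a timestamped record of interfacial area together
with a surface measure -- surface pressure Pi for a Langmuir-Blodgett trough
(LBT) or surface tension gamma for a constrained sessile drop (CSD)
surfactometer.  Both measures share units of mN/m and are related through the
clean-water reference gamma0 by ``Pi = gamma0 - gamma``.

The on-disk format is a plain CSV with a ``#``-prefixed ``key=value`` header
block followed by the columns ``time_s``, ``area``, ``surface_mN_per_m``.
LBT areas are cm^2 (optionally stored as fractions of the total trough area,
see ``total_area_cm2``), CSD areas are mm^2 of drop surface.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WaterReference",
    "SurfactometryTrace",
    "Cycle",
    "CycleSet",
    "TraceFormatError",
    "EmptyInputError",
    "OrderingError",
    "read_trace",
    "write_trace",
    "convert_measure",
    "segment_cycles",
]

#: Surface tension of a clean air-water interface at 20 degC, mN/m.
GAMMA0_WATER_20C = 72.8

_COLUMNS = ("time_s", "area", "surface_mN_per_m")

_DIALECT_DEFAULTS = {
    "lbt_csv": {"device": "LBT", "measure_kind": "pressure"},
    "csd_csv": {"device": "CSD", "measure_kind": "tension"},
    "generic_csv": {"device": "generic", "measure_kind": "pressure"},
}


class TraceFormatError(ValueError):
    """Raised when a trace file does not match the expected layout."""


class EmptyInputError(ValueError):
    """Raised when a trace file contains no data rows."""


class OrderingError(ValueError):
    """Raised when the time column is not monotone non-decreasing."""


@dataclass(frozen=True)
class WaterReference:
    """Clean-water surface tension used as the pressure/tension pivot."""

    gamma0: float = GAMMA0_WATER_20C
    temperature_c: float = 20.0

    def __post_init__(self) -> None:
        if not (self.gamma0 > 0):
            raise ValueError(f"gamma0 must be positive, got {self.gamma0}")


@dataclass
class SurfactometryTrace:
    """A validated (time, area, surface measure) series.

    Parameters
    ----------
    time : array, seconds, monotone non-decreasing
    area : array, cm^2 (LBT) or mm^2 (CSD), strictly positive
    surface_value : array, mN/m (pressure or tension per ``measure_kind``)
    measure_kind : ``"pressure"`` or ``"tension"``
    device : ``"LBT"``, ``"CSD"`` or ``"generic"``
    temperature_c : acquisition temperature, degC (optional)
    metadata : free-form key/value header entries
    """

    time: np.ndarray
    area: np.ndarray
    surface_value: np.ndarray
    measure_kind: str
    device: str = "generic"
    temperature_c: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        self.surface_value = np.asarray(self.surface_value, dtype=float)
        n = self.time.size
        if not (n == self.area.size == self.surface_value.size):
            raise ValueError("time, area and surface_value must have equal length")
        if n < 2:
            raise ValueError(f"a trace needs at least 2 samples, got {n}")
        if self.measure_kind not in ("pressure", "tension"):
            raise ValueError(f"unknown measure_kind {self.measure_kind!r}")
        if np.any(np.diff(self.time) < 0):
            raise OrderingError("time must be monotone non-decreasing")
        if not np.all(self.area > 0):
            raise ValueError("area must be strictly positive everywhere")
        if not np.all(np.isfinite(self.surface_value)):
            raise ValueError("surface_value must be finite")
        # Soft physical plausibility band; out-of-band data is flagged,
        # not rejected, because instrument exports occasionally under/overshoot.
        lo, hi = (-5.0, 100.0) if self.measure_kind == "pressure" else (0.0, 100.0)
        if np.any(self.surface_value < lo) or np.any(self.surface_value > hi):
            self.metadata.setdefault("validation_warnings", []).append(
                f"surface_value outside [{lo}, {hi}] mN/m band"
            )

    @property
    def n(self) -> int:
        return self.time.size


def _parse_header(lines: list[str]) -> dict:
    meta: dict = {}
    for raw in lines:
        body = raw.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, value = body.split("=", 1)
        meta[key.strip()] = value.strip()
    return meta


def read_trace(path, dialect: str = "generic_csv") -> SurfactometryTrace:
    """Read a surfactometry trace from a headered CSV file.

    ``dialect`` selects instrument defaults (``lbt_csv``: pressure/cm^2,
    ``csd_csv``: tension/mm^2, ``generic_csv``: header-driven).  Header keys
    override dialect defaults.  Rows containing non-finite values are dropped
    and counted in ``metadata["dropped_rows"]``.  A ``total_area_cm2`` header
    key converts fractional LBT areas to absolute cm^2.
    """
    if dialect not in _DIALECT_DEFAULTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    header_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    if not body.strip():
        raise EmptyInputError(f"{path}: no data rows")
    meta = _parse_header(header_lines)
    df = pd.read_csv(io.StringIO(body))
    df.columns = [c.strip() for c in df.columns]
    for col in _COLUMNS:
        if col not in df.columns:
            raise TraceFormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    finite = np.isfinite(df[list(_COLUMNS)].to_numpy(dtype=float)).all(axis=1)
    dropped = int((~finite).sum())
    df = df.loc[finite]
    if len(df) < 2:
        raise EmptyInputError(f"{path}: fewer than 2 finite data rows")

    defaults = _DIALECT_DEFAULTS[dialect]
    device = meta.pop("device", defaults["device"])
    measure_kind = meta.pop("measure_kind", defaults["measure_kind"])
    temperature = meta.pop("temperature_C", None)
    temperature = float(temperature) if temperature is not None else None

    area = df["area"].to_numpy(dtype=float)
    if "total_area_cm2" in meta:
        # LBT software may export relative area; rescale to absolute cm^2.
        total = float(meta["total_area_cm2"])
        area = area * total
        meta["area_rescaled_from_relative"] = "true"
        meta["total_area_cm2"] = str(total)
    if dropped:
        meta["dropped_rows"] = dropped

    return SurfactometryTrace(
        time=df["time_s"].to_numpy(dtype=float),
        area=area,
        surface_value=df["surface_mN_per_m"].to_numpy(dtype=float),
        measure_kind=measure_kind,
        device=device,
        temperature_c=temperature,
        metadata=meta,
    )


def write_trace(trace: SurfactometryTrace, path) -> str:
    """Write a trace to the headered-CSV format read by :func:`read_trace`.

    Round trip preserves arrays to better than 1e-9 relative and all
    metadata entries (values are stringified).
    """
    lines = [f"# device={trace.device}", f"# measure_kind={trace.measure_kind}"]
    if trace.temperature_c is not None:
        lines.append(f"# temperature_C={trace.temperature_c!r}")
    skip = {"area_rescaled_from_relative", "total_area_cm2"}
    for key, value in trace.metadata.items():
        if key in skip:
            continue
        lines.append(f"# {key}={value}")
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "area": trace.area,
            "surface_mN_per_m": trace.surface_value,
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return str(path)


def convert_measure(values, from_kind: str, reference: WaterReference | None = None) -> np.ndarray:
    """Convert surface tension to surface pressure or back: ``Pi = gamma0 - gamma``.

    The transform is its own inverse, so converting twice returns the input
    exactly (the same subtraction is applied in both directions).
    """
    if from_kind not in ("pressure", "tension"):
        raise ValueError(f"unknown measure kind {from_kind!r}")
    reference = reference or WaterReference()
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("surface values must be finite")
    return reference.gamma0 - values


@dataclass(frozen=True)
class Cycle:
    """Index ranges (inclusive) of one compression-expansion iso-cycle."""

    compression: tuple[int, int]
    expansion: tuple[int, int] | None
    complete: bool

    @property
    def start(self) -> int:
        return self.compression[0]

    @property
    def stop(self) -> int:
        return self.expansion[1] if self.expansion is not None else self.compression[1]


@dataclass
class CycleSet:
    """Ordered compression/expansion branches found in a trace."""

    cycles: list[Cycle]
    warnings: list[str] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def n_complete(self) -> int:
        return sum(c.complete for c in self.cycles)


def _moving_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def _turning_points(a: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Alternating extrema of ``a`` ignoring reversals smaller than ``threshold``.

    Returns (index, kind) pairs with kind +1 for a local maximum and -1 for a
    local minimum, in time order.  Classic zigzag filter: a new extreme is
    committed only once the series has moved ``threshold`` away from it.
    """
    turns: list[tuple[int, int]] = []
    i_max = i_min = 0
    v_max = v_min = a[0]
    direction = 0  # 0 unknown, +1 rising, -1 falling
    for i in range(1, a.size):
        v = a[i]
        if v > v_max:
            v_max, i_max = v, i
        if v < v_min:
            v_min, i_min = v, i
        if direction >= 0 and v_max - v >= threshold:
            turns.append((i_max, +1))
            direction = -1
            v_min, i_min = v, i
        elif direction <= 0 and v - v_min >= threshold:
            turns.append((i_min, -1))
            direction = +1
            v_max, i_max = v, i
    return turns


def segment_cycles(
    trace: SurfactometryTrace,
    min_amplitude_fraction: float = 0.02,
    smooth_window: int = 5,
) -> CycleSet:
    """Split a trace into compression/expansion iso-cycles.

    The area series is smoothed with a centered moving median (robust to
    single-point jitter) and cycle boundaries are placed at sign changes of
    its derivative; reversals whose amplitude is below
    ``min_amplitude_fraction`` of the global area range are ignored.

    A cycle is one compression branch (area non-increasing) followed by its
    expansion branch.  A trailing expansion that does not return to the
    cycle-start area (within the amplitude threshold) and is not followed by
    another compression is retained but flagged incomplete, as is a trailing
    compression with no expansion at all.
    """
    if trace.n < 4:
        raise ValueError("segmentation needs at least 4 samples")
    if not (0.0 < min_amplitude_fraction < 1.0):
        raise ValueError("min_amplitude_fraction must lie in (0, 1)")

    a = _moving_median(trace.area, smooth_window)
    rng = float(a.max() - a.min())
    if rng == 0.0:
        return CycleSet(cycles=[], warnings=["constant area: no cycles found"])
    threshold = min_amplitude_fraction * rng

    turns = _turning_points(a, threshold)
    # Median smoothing flattens sharp reversals; snap each detected turn to
    # the raw-area extremum in its neighborhood so noiseless vertices are hit
    # exactly.
    w = max(1, smooth_window // 2 + 1)
    snapped: list[tuple[int, int]] = []
    for idx, kind in turns:
        lo = max(0, idx - w)
        hi = min(trace.n, idx + w + 1)
        seg = trace.area[lo:hi]
        local = int(np.argmax(seg) if kind > 0 else np.argmin(seg))
        snapped.append((lo + local, kind))
    turns = [t for i, t in enumerate(snapped) if i == 0 or t[0] > snapped[i - 1][0]]
    warnings: list[str] = []

    # A trace may begin mid-expansion; cycles start at the first maximum.
    if turns and turns[0][1] == -1:
        warnings.append("leading expansion before first compression was skipped")
        turns = turns[1:]
    if not turns:
        # Monotone trace: a lone compression or expansion.
        if a[-1] < a[0]:
            warnings.append("trailing cycle incomplete (no expansion branch)")
            return CycleSet(
                cycles=[Cycle((0, trace.n - 1), None, complete=False)],
                warnings=warnings,
            )
        return CycleSet(cycles=[], warnings=["no compression found"])

    cycles: list[Cycle] = []
    n_last = trace.n - 1
    for k, (idx, kind) in enumerate(turns):
        if kind != +1:
            continue
        comp_end_idx = turns[k + 1][0] if k + 1 < len(turns) else n_last
        if comp_end_idx <= idx:
            continue
        if k + 1 >= len(turns):
            # Compression runs to the end of the record: no expansion.
            cycles.append(Cycle((idx, n_last), None, complete=False))
            warnings.append("trailing cycle incomplete (no expansion branch)")
            break
        valley = turns[k + 1][0]
        exp_end = turns[k + 2][0] if k + 2 < len(turns) else n_last
        if exp_end <= valley:
            cycles.append(Cycle((idx, valley), None, complete=False))
            warnings.append("trailing cycle incomplete (no expansion branch)")
            break
        if k + 2 < len(turns):
            complete = True
        else:
            # Final expansion: complete only if it climbs back to the
            # cycle-start area within the amplitude threshold.
            complete = abs(a[exp_end] - a[idx]) <= threshold
            if not complete:
                warnings.append("trailing expansion incomplete")
        cycles.append(Cycle((idx, valley), (valley, exp_end), complete=complete))

    return CycleSet(cycles=cycles, warnings=warnings)
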
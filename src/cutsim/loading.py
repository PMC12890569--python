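"""Static and dynamic loading programs and cycle bookkeeping.

Bench protocol: the static program ramps axial compression from ~5 to 50 N
over 5 s, then switches to displacement control at 2 mm/min until 7 mm
(the cut-out criterion).  The dynamic program ramps from ~5 to 100 N over
15 s, then applies a double-peak (M-shaped walking-gait) force curve at
1 Hz, first cycle spanning 100 to 1000 N, with the per-cycle maximum
growing by 0.1 N/cycle and the minimum held at 10% of the maximum.

The simulation substitutes a single monotone plate ramp at 2 m/s for both
programs (the dynamic case uses derated foam strengths instead of explicit
cycling); the cyclic schedule here exists for physical-data bookkeeping —
notably converting a peak force into the cycle index at which it is first
reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LoadSchedule",
    "static_schedule",
    "dynamic_schedule",
    "simulated_ramp_schedule",
    "cycles_to_force",
    "peak_force",
    "trough_force",
    "double_peak_waveform",
    "waveform_series",
]

#: first-cycle maximum force, N
FIRST_PEAK_N = 1000.0
#: per-cycle growth of the maximum force, N/cycle
PEAK_INCREMENT_N = 0.1
#: minimum force as a fraction of the maximum
TROUGH_RATIO = 0.1
#: simulated plate rate, mm/ms (= 2 m/s)
SIMULATED_PLATE_RATE = 2.0


@dataclass(frozen=True)
class LoadSchedule:
    """One loading program.

    ``mode`` is ``static`` (force ramp then displacement control),
    ``dynamic-cyclic`` (ramp then growing double-peak cycles) or
    ``simulated-ramp`` (constant plate velocity used by the solver).
    Forces in N, durations in s, displacement rate in the unit named by
    ``rate_unit``.
    """

    mode: str
    ramp_start_N: float = 5.0
    ramp_end_N: float = 50.0
    ramp_duration_s: float = 5.0
    displacement_rate: float = 2.0
    rate_unit: str = "mm/min"
    cycle_frequency_Hz: float = 0.0
    first_cycle_min_N: float = 0.0
    first_cycle_max_N: float = 0.0
    peak_increment_N_per_cycle: float = 0.0
    trough_ratio: float = 0.0
    cutout_displacement_mm: float = 7.0

    def __post_init__(self):
        if self.ramp_start_N < 0 or self.ramp_end_N < 0:
            raise ValueError("ramp forces must be non-negative")
        if self.peak_increment_N_per_cycle < 0:
            raise ValueError("peak increment must be non-negative")
        if self.mode == "dynamic-cyclic" and not 0.0 < self.trough_ratio < 1.0:
            raise ValueError("trough ratio must lie in (0, 1)")

    def ramp_force(self, t_s: float) -> float:
        """Force during the initial quasi-static ramp (clamped at the end)."""
        x = min(max(t_s / self.ramp_duration_s, 0.0), 1.0)
        return self.ramp_start_N + x * (self.ramp_end_N - self.ramp_start_N)


def static_schedule() -> LoadSchedule:
    """The bench static program: ~5->50 N in 5 s, then 2 mm/min to 7 mm."""
    return LoadSchedule(mode="static")


def simulated_ramp_schedule(rate_mm_per_ms: float = SIMULATED_PLATE_RATE) -> LoadSchedule:
    """Solver surrogate: constant plate velocity (default 2 m/s) to 7 mm."""
    return LoadSchedule(
        mode="simulated-ramp",
        ramp_start_N=0.0,
        ramp_end_N=0.0,
        ramp_duration_s=0.0,
        displacement_rate=rate_mm_per_ms,
        rate_unit="mm/ms",
    )


def dynamic_schedule() -> LoadSchedule:
    """The bench dynamic program: ~5->100 N in 15 s, then 1 Hz double-peak
    cycles from 100/1000 N growing 0.1 N per cycle at a 10% trough ratio."""
    return LoadSchedule(
        mode="dynamic-cyclic",
        ramp_start_N=5.0,
        ramp_end_N=100.0,
        ramp_duration_s=15.0,
        cycle_frequency_Hz=1.0,
        first_cycle_min_N=FIRST_PEAK_N * TROUGH_RATIO,
        first_cycle_max_N=FIRST_PEAK_N,
        peak_increment_N_per_cycle=PEAK_INCREMENT_N,
        trough_ratio=TROUGH_RATIO,
    )


def peak_force(cycle: int | np.ndarray) -> float | np.ndarray:
    """Maximum force of cycle ``i`` (1-based): 1000 + 0.1 (i - 1) N."""
    c = np.asarray(cycle)
    if np.any(c < 1):
        raise ValueError("cycle index is 1-based")
    out = FIRST_PEAK_N + PEAK_INCREMENT_N * (c - 1)
    return float(out) if np.isscalar(cycle) else out


def trough_force(cycle: int | np.ndarray) -> float | np.ndarray:
    """Minimum force of cycle ``i``: 10% of that cycle's maximum."""
    p = peak_force(cycle)
    return TROUGH_RATIO * p


def cycles_to_force(target_peak_N: float) -> int:
    """Smallest cycle index whose maximum force reaches ``target_peak_N``.

    ceil((target - 1000) / 0.1) + 1, evaluated with a half-increment guard
    against binary-fraction rounding.
    """
    if target_peak_N < FIRST_PEAK_N:
        raise ValueError("target below the first-cycle maximum")
    steps = (target_peak_N - FIRST_PEAK_N) / PEAK_INCREMENT_N
    return int(math.ceil(steps - 1e-9)) + 1


# ---------------------------------------------------------------------------
# double-peak (walking gait) waveform
# ---------------------------------------------------------------------------

#: phase locations of the two gait force peaks (heel strike, toe off) and
#: the mid-stance valley level as a fraction of the peak force; the shape
#: follows the double-peaked hip-contact-force profile of instrumented
#: walking data and is configurable
PEAK_PHASES = (0.30, 0.62)
VALLEY_FRACTION = 0.75


def double_peak_waveform(
    phase: float | np.ndarray,
    trough_N: float,
    peak_N: float,
    peak_phases: tuple[float, float] = PEAK_PHASES,
    valley_fraction: float = VALLEY_FRACTION,
) -> float | np.ndarray:
    """Force at ``phase`` (fraction of a cycle) of the M-shaped gait curve.

    Piecewise half-cosine segments through (0, trough), (p1, peak),
    (mid, valley), (p2, peak), (1, trough): continuous and C1, with exactly
    two local maxima at the peak value and the cycle minimum at the trough.
    """
    if trough_N >= peak_N:
        raise ValueError("trough must be below peak")
    p1, p2 = peak_phases
    if not 0.0 < p1 < p2 < 1.0:
        raise ValueError("peak phases must be ordered inside (0, 1)")
    valley_N = max(valley_fraction * peak_N, trough_N + 0.5 * (peak_N - trough_N))
    mid = 0.5 * (p1 + p2)

    nodes = np.array([0.0, p1, mid, p2, 1.0])
    values = np.array([trough_N, peak_N, valley_N, peak_N, trough_N])

    ph = np.mod(np.asarray(phase, dtype=float), 1.0)
    seg = np.clip(np.searchsorted(nodes, ph, side="right") - 1, 0, 3)
    x0 = nodes[seg]
    x1 = nodes[seg + 1]
    v0 = values[seg]
    v1 = values[seg + 1]
    s = (ph - x0) / (x1 - x0)
    smooth = 0.5 * (1.0 - np.cos(np.pi * s))
    out = v0 + (v1 - v0) * smooth
    return float(out) if np.isscalar(phase) else out


def waveform_series(
    cycle: int, samples_per_cycle: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """(time_ms, force_N) samples of one dynamic cycle at 1 Hz."""
    ph = np.arange(samples_per_cycle) / samples_per_cycle
    f = double_peak_waveform(ph, trough_force(cycle), peak_force(cycle))
    return ph * 1000.0, f
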
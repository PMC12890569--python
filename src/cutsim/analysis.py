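"""Force-displacement analytics, damage summaries and concordance statistics.

Post-processing mirrors the bench study's workflow: toe-in artifacts are
trimmed so force curves share a zero-depth origin, the force at cut-out
(7 mm vertical displacement) is read off each curve — linearly extrapolated
from the 3 mm slope when a record stops short — and physical/simulated
curve pairs are compared with Lin's concordance correlation coefficient
rho_c = rho * C_b, where rho (Pearson) measures precision and C_b measures
accuracy (deviation of the best-fit line from the 45-degree identity line).
Damage is summarized as yielding/failed particle counts, their material
volumes (cubic convention, count * r^3) and percent differences against a
reference device; spatial clustering is visualized by counting neighboring
yielding particles within a 6 mm radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree

from .foam import occupied_volume

__all__ = [
    "FDCurve",
    "ConcordanceResult",
    "DamageSummary",
    "GroupSummary",
    "normalize_toe_in",
    "force_at_cutout",
    "damage_summary",
    "heatmap_density",
    "lin_ccc",
    "match_curves",
    "group_stats",
    "anova_from_summary",
    "comparison_report",
]


@dataclass
class FDCurve:
    """An ordered force-displacement record of one loading run."""

    displacement_mm: np.ndarray
    force_N: np.ndarray
    provenance: str = "simulated"  # 'physical' | 'simulated'
    device: str = ""
    mode: str = ""  # 'static' | 'dynamic'

    def __post_init__(self):
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        if self.displacement_mm.shape != self.force_N.shape:
            raise ValueError("displacement and force must have equal length")
        if not np.all(np.isfinite(self.force_N)):
            raise ValueError("forces must be finite")

    @property
    def n(self) -> int:
        return len(self.force_N)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"displacement_mm": self.displacement_mm, "force_N": self.force_N}
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "FDCurve":
        df = pd.read_csv(path)
        for col in ("displacement_mm", "force_N"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        return cls(df["displacement_mm"].to_numpy(), df["force_N"].to_numpy(), **kwargs)


def normalize_toe_in(curve: FDCurve, force_threshold_N: float = 50.0) -> FDCurve:
    """Trim low-force toe-in and shift the displacement origin.

    The origin moves to the first sample whose force reaches the threshold
    (default 50 N, the static ramp endpoint); earlier samples are dropped.
    """
    if curve.n == 0:
        raise ValueError("empty curve")
    idx = np.nonzero(curve.force_N >= force_threshold_N)[0]
    if len(idx) == 0:
        raise ValueError(
            f"no sample reaches the {force_threshold_N} N toe-in threshold"
        )
    k = idx[0]
    return FDCurve(
        curve.displacement_mm[k:] - curve.displacement_mm[k],
        curve.force_N[k:],
        provenance=curve.provenance,
        device=curve.device,
        mode=curve.mode,
    )


def force_at_cutout(
    curve: FDCurve, cutout_mm: float = 7.0, extrapolate_from_mm: float = 3.0
) -> float:
    """Force at the cut-out displacement, extrapolating short records.

    If the record reaches the cut-out displacement the force is linearly
    interpolated there; otherwise a least-squares line through all samples
    at displacement >= ``extrapolate_from_mm`` is evaluated at the cut-out.
    """
    d = curve.displacement_mm
    f = curve.force_N
    if d.max() < extrapolate_from_mm:
        raise ValueError(
            f"curve ends at {d.max():.3f} mm, before the "
            f"{extrapolate_from_mm} mm extrapolation window"
        )
    if d.max() >= cutout_mm:
        return float(np.interp(cutout_mm, d, f))
    mask = d >= extrapolate_from_mm
    if mask.sum() < 2:
        mask = d >= d.max() - 1e-9  # degenerate: single point at the end
        raise ValueError("fewer than two samples beyond the extrapolation start")
    slope, intercept = np.polyfit(d[mask], f[mask], 1)
    return float(slope * cutout_mm + intercept)


# ---------------------------------------------------------------------------
# damage summaries
# ---------------------------------------------------------------------------


@dataclass
class DamageSummary:
    """Counts, volumes and reference-relative percentages of damaged foam."""

    yielding_count: int
    failed_count: int
    resolution_um: float
    device: str = ""
    mode: str = ""
    force_at_cutout_N: float | None = None
    percent_force_vs_reference: float | None = None
    percent_volume_vs_reference: float | None = None

    @property
    def yielding_volume_mL(self) -> float:
        return occupied_volume(self.yielding_count, self.resolution_um)

    @property
    def failed_volume_mL(self) -> float:
        return occupied_volume(self.failed_count, self.resolution_um)

    @property
    def combined_volume_mL(self) -> float:
        return self.yielding_volume_mL + self.failed_volume_mL

    def to_dict(self) -> dict:
        return {
            "device": self.device,
            "mode": self.mode,
            "yielding_count": self.yielding_count,
            "failed_count": self.failed_count,
            "yielding_volume_mL": round(self.yielding_volume_mL, 3),
            "failed_volume_mL": round(self.failed_volume_mL, 3),
            "combined_volume_mL": round(self.combined_volume_mL, 3),
            "force_at_cutout_N": self.force_at_cutout_N,
            "percent_force_vs_reference": self.percent_force_vs_reference,
            "percent_volume_vs_reference": self.percent_volume_vs_reference,
        }


def damage_summary(
    yielding_count: int,
    failed_count: int,
    resolution_um: float,
    reference: DamageSummary | None = None,
    force_at_cutout_N: float | None = None,
    **meta,
) -> DamageSummary:
    """Build a damage summary, optionally relative to a reference device.

    Percent-vs-reference values are 100 * (x / x_ref - 1), computed on the
    combined damaged volume and on the force at cut-out.
    """
    if yielding_count < 0 or failed_count < 0:
        raise ValueError("counts must be non-negative")
    out = DamageSummary(
        yielding_count=int(yielding_count),
        failed_count=int(failed_count),
        resolution_um=resolution_um,
        force_at_cutout_N=force_at_cutout_N,
        **meta,
    )
    if reference is not None:
        if reference.combined_volume_mL <= 0:
            raise ValueError("reference damaged volume is zero")
        out.percent_volume_vs_reference = 100.0 * (
            out.combined_volume_mL / reference.combined_volume_mL - 1.0
        )
        if force_at_cutout_N is not None and reference.force_at_cutout_N:
            out.percent_force_vs_reference = 100.0 * (
                force_at_cutout_N / reference.force_at_cutout_N - 1.0
            )
    return out


def heatmap_density(positions: np.ndarray, radius_mm: float = 6.0) -> np.ndarray:
    """Neighbor counts of yielding particles within a 6 mm radius.

    For each particle, the number of *other* particles within the radius
    (self excluded) — the scalar used for damage-density heatmaps.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(pts) == 0:
        return np.zeros(0, dtype=np.int64)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius_mm, return_length=True)
    return np.asarray(counts, dtype=np.int64) - 1


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceResult:
    """Lin's concordance of a matched pair of series."""

    rho_c: float
    pearson_rho: float
    bias_factor_Cb: float
    ci95_lower: float
    ci95_upper: float
    n: int

    def __iter__(self):
        yield from (self.rho_c, self.pearson_rho, self.bias_factor_Cb)


def lin_ccc(x: np.ndarray, y: np.ndarray) -> ConcordanceResult:
    """Lin's concordance correlation coefficient of paired series.

    rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2) with
    population (1/n) moments, the convention of the concordance literature;
    rho is the Pearson coefficient and C_b = rho_c / rho the bias
    (accuracy) factor.  The 95% CI applies a Fisher z-transform to rho_c
    with standard error 1/sqrt(n - 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-D series")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        raise ValueError("zero variance in a series")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    rho_c = 2.0 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2)
    rho = sxy / math.sqrt(vx * vy)
    cb = rho_c / rho if rho != 0.0 else np.nan

    z = np.arctanh(np.clip(rho_c, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / math.sqrt(n - 3)
    lo, hi = np.tanh(z - 1.96 * se), np.tanh(z + 1.96 * se)
    return ConcordanceResult(
        rho_c=float(rho_c),
        pearson_rho=float(rho),
        bias_factor_Cb=float(cb),
        ci95_lower=float(lo),
        ci95_upper=float(hi),
        n=n,
    )


def match_curves(
    physical: FDCurve, simulated: FDCurve, grid_step_mm: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate two curves onto a common displacement grid.

    Returns paired (physical force, simulated force) samples over the
    overlapping displacement range, matched by displacement value.
    """
    lo = max(physical.displacement_mm.min(), simulated.displacement_mm.min())
    hi = min(physical.displacement_mm.max(), simulated.displacement_mm.max())
    if hi <= lo:
        raise ValueError("curves have no overlapping displacement range")
    grid = np.arange(lo, hi + 1e-12, grid_step_mm)
    if len(grid) < 2:
        raise ValueError("grid step larger than the overlapping range")
    fp = np.interp(grid, physical.displacement_mm, physical.force_N)
    fs = np.interp(grid, simulated.displacement_mm, simulated.force_N)
    return fp, fs


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    name: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group needs n >= 2")


def group_stats(groups: list[GroupSummary]) -> dict:
    """Two-sample pooled t-test or one-way ANOVA from summary statistics.

    Two groups: equal-variance two-sample t statistic and two-tailed p.
    More than two: one-way ANOVA F and p reconstructed from (n, mean, SD).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        a, b = groups
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        if sp2 == 0:
            raise ValueError("zero pooled variance")
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        t = (a.mean - b.mean) / se
        p = 2.0 * sps.t.sf(abs(t), df)
        return {"test": "t", "t": t, "df": df, "p": p}
    return anova_from_summary(groups)


def anova_from_summary(groups: list[GroupSummary]) -> dict:
    """One-way ANOVA from per-group (n, mean, SD)."""
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    N = ns.sum()
    k = len(groups)
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    dfb, dfw = k - 1, N - k
    if ssw == 0:
        raise ValueError("zero within-group variance")
    F = (ssb / dfb) / (ssw / dfw)
    p = sps.f.sf(F, dfb, dfw)
    return {"test": "anova", "F": float(F), "df_between": dfb,
            "df_within": int(dfw), "p": float(p)}


# ---------------------------------------------------------------------------
# comparison report
# ---------------------------------------------------------------------------


def comparison_report(
    physical: pd.DataFrame, simulated: pd.DataFrame
) -> pd.DataFrame:
    """Per device/mode agreement of simulated vs physical cut-out forces.

    ``physical`` needs columns (device, mode, mean_N) and optionally sd_N;
    ``simulated`` needs (device, mode, force_N).  The report carries the
    percent error 100 |sim - physical mean| / physical mean per matched
    entry; unmatched entries are listed with NaN rather than dropped.
    """
    phys = physical.set_index(["device", "mode"])
    sim = simulated.set_index(["device", "mode"])
    keys = sorted(set(phys.index) | set(sim.index))
    rows = []
    for device, mode in keys:
        p = phys["mean_N"].get((device, mode), np.nan)
        s = sim["force_N"].get((device, mode), np.nan)
        err = 100.0 * abs(s - p) / p if np.isfinite(p) and np.isfinite(s) else np.nan
        rows.append(
            {
                "device": device,
                "mode": mode,
                "physical_mean_N": p,
                "simulated_N": s,
                "percent_error": err,
            }
        )
    return pd.DataFrame(rows)


def percent_vs_reference(values: dict[str, float], reference: str) -> dict[str, float]:
    """100 * (x / x_ref - 1) for each entry, reference excluded."""
    ref = values[reference]
    if ref == 0:
        raise ValueError("reference value is zero")
    return {
        k: 100.0 * (v / ref - 1.0) for k, v in values.items() if k != reference
    }
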
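"""Enzymatic assay quantification.

Implements the quantitative analysis applied to the multiwell
fluorescence data: Michaelis-Menten rates, quadratic progress-curve
fitting with derivative-based rate estimation, fold changes against the
negative control, acceleration factors, intra/inter-assay coefficients
of variation, concentration bracketing against reference standards,
reference-curve preconcentration-factor estimation and the
Kruskal-Wallis rank test.

The in-memory container is :class:`PlateData`, a thin wrapper around a
tidy :class:`pandas.DataFrame` with columns
``device, well, group, class, time_min, rfu``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PLATE_COLUMNS = ["device", "well", "group", "class", "time_min", "rfu"]


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsSpec:
    """Michaelis-Menten parameters.

    Either ``v_max`` or (``k_cat``, ``c_enzyme``) must be given; if all
    three are given they are cross-checked (v_max = k_cat * c_enzyme).
    """

    k_m: float
    c_substrate: float
    v_max: float | None = None
    k_cat: float | None = None
    c_enzyme: float | None = None

    def __post_init__(self) -> None:
        if self.k_m <= 0.0:
            raise ValueError("k_m must be positive")
        if self.c_substrate < 0.0:
            raise ValueError("substrate concentration must be >= 0")
        if self.v_max is None and (self.k_cat is None or self.c_enzyme is None):
            raise ValueError("provide v_max or both k_cat and c_enzyme")
        if (
            self.v_max is not None
            and self.k_cat is not None
            and self.c_enzyme is not None
            and not math.isclose(self.v_max, self.k_cat * self.c_enzyme, rel_tol=1e-9)
        ):
            raise ValueError("inconsistent v_max != k_cat * c_enzyme")

    @property
    def effective_v_max(self) -> float:
        if self.v_max is not None:
            return self.v_max
        return self.k_cat * self.c_enzyme  # type: ignore[operator]


def michaelis_menten_rate(spec: KineticsSpec) -> float:
    """Reaction velocity v = v_max * c_s / (k_m + c_s).

    At c_s = k_m this is v_max/2 (the defining property of the Michaelis
    constant); v is proportional to the enzyme concentration through
    v_max = k_cat * c_enzyme.
    """
    return spec.effective_v_max * spec.c_substrate / (spec.k_m + spec.c_substrate)


# ---------------------------------------------------------------------------
# Progress curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadraticFit:
    """Quadratic progress-curve fit y = a t^2 + b t + c.

    ``time_unit`` tags the unit of t ("min" or "h") so derived rates are
    unambiguous.  The instantaneous rate is the analytic derivative
    y' = 2 a t + b.
    """

    a: float
    b: float
    c: float
    time_unit: str = "min"
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.time_unit not in ("min", "h"):
            raise ValueError("time_unit must be 'min' or 'h'")

    @classmethod
    def from_derivative(cls, slope: float, intercept: float, time_unit: str = "min") -> "QuadraticFit":
        """Build a fit whose derivative is y' = slope*t + intercept
        (i.e. a = slope/2, b = intercept, c unknown -> 0)."""
        return cls(a=0.5 * slope, b=intercept, c=0.0, time_unit=time_unit)


def fit_progress_curve(times: Sequence[float], signals: Sequence[float], time_unit: str = "min") -> QuadraticFit:
    """Ordinary least-squares quadratic fit of a progress curve.

    Requires at least three distinct time points; with exactly three the
    fit interpolates.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(signals, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and signals must have the same length")
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct time points for a quadratic fit")
    coeffs = np.polynomial.polynomial.polyfit(t, y, 2)
    c, b, a = coeffs
    rss = float(np.sum((np.polynomial.polynomial.polyval(t, coeffs) - y) ** 2))
    return QuadraticFit(a=float(a), b=float(b), c=float(c), time_unit=time_unit, rss=rss)


def reaction_rate_at(fit: QuadraticFit, t: float) -> float:
    """Instantaneous rate y'(t) = 2 a t + b, in signal units per
    ``fit.time_unit``."""
    return 2.0 * fit.a * t + fit.b


def convert_rate(rate: float, from_unit: str, to_unit: str) -> float:
    """Convert a rate between per-hour and per-minute."""
    factors = {("h", "min"): 1.0 / 60.0, ("min", "h"): 60.0, ("min", "min"): 1.0, ("h", "h"): 1.0}
    try:
        return rate * factors[(from_unit, to_unit)]
    except KeyError:
        raise ValueError(f"unsupported rate conversion {from_unit!r} -> {to_unit!r}") from None


def fold_change(net_signal: float, net_nc_signal: float) -> float:
    """Fold increase of a sample's net signal over the negative control.

    Net signal means I(t) - I(0) for the same well, both evaluated at
    the same time point.
    """
    if net_nc_signal <= 0.0:
        raise ValueError("negative-control net signal must be positive")
    return net_signal / net_nc_signal


def acceleration_factor(rate_fast: float, rate_slow: float) -> float:
    """Ratio of two reaction rates expressed in identical units."""
    if rate_slow <= 0.0:
        raise ValueError("slow rate must be positive")
    return rate_fast / rate_slow


# ---------------------------------------------------------------------------
# Plate container
# ---------------------------------------------------------------------------


@dataclass
class PlateData:
    """Per-well fluorescence time courses with replicate/device labels.

    ``frame`` is tidy with columns ``device`` (plate/run id), ``well``,
    ``group`` (concentration in ng/mL; 0 for NC), ``class``
    ("NC" | "standard" | "supernatant"), ``time_min``, ``rfu``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PLATE_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"plate frame missing columns: {sorted(missing)}")
        if (self.frame["rfu"] < 0).any():
            raise ValueError("RFU values must be >= 0")
        grids = self.frame.groupby("device")["time_min"].unique()
        first = None
        for g in grids:
            key = tuple(np.sort(g))
            if first is None:
                first = key
            elif key != first:
                raise ValueError("all wells of a device must share one time grid")

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frame["time_min"].unique())

    def net_signals(self, at_time: float) -> pd.DataFrame:
        """Per-well net signal I(t) - I(0) at the requested time.

        Returns a frame with device, well, group, class and ``net``.
        """
        f = self.frame
        t0 = f["time_min"].min()
        sel_t = f[np.isclose(f["time_min"], at_time)]
        sel_0 = f[np.isclose(f["time_min"], t0)]
        if sel_t.empty:
            raise ValueError(f"no samples at time {at_time} min")
        keys = ["device", "well", "group", "class"]
        merged = sel_t.merge(sel_0, on=keys, suffixes=("", "_0"))
        merged["net"] = merged["rfu"] - merged["rfu_0"]
        return merged[keys + ["net"]]

    def to_csv(self, path_or_buf) -> None:
        self.frame.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "PlateData":
        return cls(pd.read_csv(path_or_buf))

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def assay_cv(plate: PlateData, at_time: float, include_nc: bool = True) -> tuple[float, float]:
    """Intra- and inter-assay coefficients of variation, in percent.

    Intra-assay: per (device, group) CV of replicate net signals
    (sample sd / mean), averaged over all device-groups.  Inter-assay:
    per group, CV across devices of the device-group mean net signal,
    averaged over groups.  These are the standard immunoassay QC
    definitions.
    """
    net = plate.net_signals(at_time)
    if not include_nc:
        net = net[net["group"] != 0]
    intra_cvs = []
    for (_, _), sub in net.groupby(["device", "group"]):
        vals = sub["net"].to_numpy(float)
        if len(vals) < 2:
            continue
        m = vals.mean()
        if m == 0.0:
            raise ValueError("zero-mean replicate group; CV undefined")
        intra_cvs.append(np.std(vals, ddof=1) / abs(m) * 100.0)
    if not intra_cvs:
        raise ValueError("need >= 2 replicates per device group for intra-assay CV")
    inter_cvs = []
    means = net.groupby(["group", "device"])["net"].mean()
    for g, sub in means.groupby(level="group"):
        vals = sub.to_numpy(float)
        if len(vals) < 2:
            continue
        m = vals.mean()
        if m == 0.0:
            raise ValueError("zero-mean device group; CV undefined")
        inter_cvs.append(np.std(vals, ddof=1) / abs(m) * 100.0)
    if not inter_cvs:
        raise ValueError("need >= 2 devices for inter-assay CV")
    return float(np.mean(intra_cvs)), float(np.mean(inter_cvs))


# ---------------------------------------------------------------------------
# Concentration inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BracketResult:
    """Concentration bracket (and optional log-linear point estimate)."""

    c_low: float | None
    c_high: float | None
    point_estimate: float | None
    open_ended: bool


def bracket_concentration(
    net_signal: float,
    references: Sequence[tuple[float, float]],
    interpolate: bool = True,
) -> BracketResult:
    """Bracket an unknown between reference standards.

    ``references`` are (concentration, net_signal) pairs sorted by
    ascending concentration with monotonically increasing signals.  A
    signal outside the reference span yields an open-ended bracket with
    ``open_ended=True`` rather than an extrapolated number.
    """
    refs = list(references)
    if len(refs) < 2:
        raise ValueError("need at least two reference standards")
    concs = np.array([r[0] for r in refs], float)
    sigs = np.array([r[1] for r in refs], float)
    if np.any(np.diff(concs) <= 0):
        raise ValueError("reference concentrations must be strictly increasing")
    if np.any(np.diff(sigs) <= 0):
        raise ValueError("reference signals must be strictly increasing")
    exact = np.isclose(sigs, net_signal)
    if exact.any():
        c = float(concs[exact][0])
        return BracketResult(c_low=c, c_high=c, point_estimate=c, open_ended=False)
    if net_signal < sigs[0]:
        return BracketResult(c_low=None, c_high=float(concs[0]), point_estimate=None, open_ended=True)
    if net_signal > sigs[-1]:
        return BracketResult(c_low=float(concs[-1]), c_high=None, point_estimate=None, open_ended=True)
    i = int(np.searchsorted(sigs, net_signal)) - 1
    c_lo, c_hi = float(concs[i]), float(concs[i + 1])
    est = None
    if interpolate:
        frac = (net_signal - sigs[i]) / (sigs[i + 1] - sigs[i])
        est = float(np.exp(np.log(c_lo) + frac * (np.log(c_hi) - np.log(c_lo))))
    return BracketResult(c_low=c_lo, c_high=c_hi, point_estimate=est, open_ended=False)


@dataclass(frozen=True)
class PCFEstimate:
    """Preconcentration factor inferred from a reference intensity curve."""

    pcf: float
    apparent_concentration: float
    extrapolated: bool


def pcf_from_reference(
    plug_intensity: float,
    reference_curve: Sequence[tuple[float, float]],
    initial_concentration: float,
) -> PCFEstimate:
    """Estimate the preconcentration factor by inverse interpolation.

    The plug intensity is mapped to an apparent concentration through a
    monotone (concentration, intensity) reference curve; PCF is apparent
    over initial concentration.  An intensity outside the reference span
    is linearly extrapolated from the nearest segment and *flagged*.
    """
    refs = list(reference_curve)
    if len(refs) < 2:
        raise ValueError("need at least two reference points")
    concs = np.array([r[0] for r in refs], float)
    ints = np.array([r[1] for r in refs], float)
    if np.any(np.diff(concs) <= 0) or np.any(np.diff(ints) <= 0):
        raise ValueError("reference curve must be strictly monotone")
    if initial_concentration <= 0:
        raise ValueError("initial concentration must be positive")
    extrapolated = not (ints[0] <= plug_intensity <= ints[-1])
    i = int(np.clip(np.searchsorted(ints, plug_intensity) - 1, 0, len(refs) - 2))
    frac = (plug_intensity - ints[i]) / (ints[i + 1] - ints[i])
    apparent = float(concs[i] + frac * (concs[i + 1] - concs[i]))
    return PCFEstimate(
        pcf=apparent / initial_concentration,
        apparent_concentration=apparent,
        extrapolated=extrapolated,
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def kruskal_wallis(
    groups: Iterable[Sequence[float]],
    method: str = "chi2",
    n_permutations: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Kruskal-Wallis rank test across >= 2 groups.

    Returns (H, p).  ``method="chi2"`` uses the chi-square approximation
    with k-1 degrees of freedom (tie-corrected); ``method="permutation"``
    estimates p by seeded Monte-Carlo relabelling, appropriate for very
    small groups.  Identical data in all groups gives H = 0, p = 1.
    """
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(len(g) == 0 for g in gs):
        raise ValueError("need at least two nonempty groups")
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*gs)
    if method == "chi2":
        return float(h), float(p)
    if method != "permutation":
        raise ValueError("method must be 'chi2' or 'permutation'")
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in gs]
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        try:
            h_perm, _ = stats.kruskal(*parts)
        except ValueError:  # all-identical permutation draw
            h_perm = 0.0
        if h_perm >= h - 1e-12:
            count += 1
    return float(h), (count + 1) / (n_permutations + 1)
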
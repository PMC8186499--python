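"""Fluorometric MUF hydrolase assay: kinetics to activities.

Extracellular cellulase and xylanase activities are assayed by incubating
digester slurry with 4-methylumbelliferyl (MUF)-linked substrate mimics
(MUF-cellobioside, MUF-xylopyranoside) at substrate-saturating (V_max)
conditions and reading the fluorescence of released MUF every few minutes
for ~2 h. Because the assay runs at V_max, product accumulates linearly
(zero-order kinetics) and the activity is the initial linear slope,
converted to mg MUF released per litre of undiluted slurry per hour via a
matrix-matched MUF standard curve, corrected against heat-inactivated
blanks, and averaged over the two substrate concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: mg of 4-methylumbelliferone per µmol (molar mass 176.17 g·mol⁻¹).
MUF_MG_PER_UMOL = 0.17617

ROLES = ("sample", "blank", "standard")
MATRICES = ("active", "heat_inactivated")


class AssayError(ValueError):
    """Raised on invalid assay inputs (message names the offending field)."""


@dataclass
class Well:
    """One plate well: a fluorescence time course plus its annotations.

    ``standard_conc`` (µmol·L⁻¹ MUF) is required for standard wells and
    ignored otherwise. ``dilution`` is the fraction of slurry in the
    reaction (e.g. 0.01 for a 1% slurry dilution).
    """

    well_id: str
    role: str
    substrate: str
    substrate_conc: float
    matrix: str
    dilution: float
    times: np.ndarray
    fluorescence: np.ndarray
    standard_conc: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.role not in ROLES:
            raise AssayError(f"role: {self.role!r} not in {ROLES}")
        if self.matrix not in MATRICES:
            raise AssayError(f"matrix: {self.matrix!r} not in {MATRICES}")
        if not np.all(np.isfinite(self.fluorescence)):
            raise AssayError(f"fluorescence: non-finite values in well {self.well_id}")
        if np.any(np.diff(self.times) <= 0):
            raise AssayError(f"times: not strictly increasing in well {self.well_id}")
        if self.role != "standard" and len(self.times) < 3:
            raise AssayError(f"times: kinetic well {self.well_id} has < 3 points")
        if self.role == "standard" and self.standard_conc is None:
            raise AssayError(f"standard_conc: missing for standard well {self.well_id}")


@dataclass
class PlateKineticSeries:
    """A plate read: wells plus free-form metadata (temperature, reactor...)."""

    wells: list[Well]
    metadata: dict = field(default_factory=dict)

    def by_role(self, role: str) -> list[Well]:
        return [w for w in self.wells if w.role == role]

    def standards(self, matrix: str) -> list[Well]:
        return [w for w in self.wells if w.role == "standard" and w.matrix == matrix]


@dataclass
class StandardCurve:
    """Linear MUF calibration for one slurry matrix.

    slope is in AU per µmol·L⁻¹ MUF; linear_range is the concentration
    span (µmol·L⁻¹) over which the fit met the r² threshold.
    """

    matrix: str
    slope: float
    intercept: float
    r_squared: float
    linear_range: tuple[float, float]


@dataclass
class RateEstimate:
    """Initial-rate fit for one well, in mg MUF·L⁻¹·h⁻¹ of undiluted slurry."""

    rate: float
    r_squared: float
    window_points: int
    qc_flags: set[str] = field(default_factory=set)


@dataclass
class ActivitySeries:
    """Per-reactor, per-enzyme hydrolysis rates over sampling days."""

    reactor: str
    enzyme: str
    days: np.ndarray
    rates: np.ndarray
    sds: np.ndarray
    qc_flags: list[frozenset] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days)
        self.rates = np.asarray(self.rates, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if len(np.unique(self.days)) != len(self.days):
            raise AssayError("days: duplicate sampling days in activity series")
        if not self.qc_flags:
            self.qc_flags = [frozenset()] * len(self.days)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reactor": self.reactor,
                "enzyme": self.enzyme,
                "day": self.days,
                "rate": self.rates,
                "sd": self.sds,
                "flags": [";".join(sorted(f)) for f in self.qc_flags],
            }
        )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r² — with r² defined as 1 for a constant response."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0.0:
        return 0.0, float(y[0]), 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_standard_curve(
    standards: Iterable[tuple[float, float]],
    matrix: str = "active",
    r2_threshold: float = 0.99,
) -> StandardCurve:
    """Fit the MUF standard curve by OLS over its linear range.

    ``standards`` are (concentration in µmol·L⁻¹, mean fluorescence in AU)
    pairs. The linear range is the widest prefix of concentrations (from
    the lowest upward) whose OLS fit reaches ``r2_threshold``; at least
    three distinct concentrations are required. A zero slope (fluorescence
    not responding to MUF) is rejected.
    """
    pts = sorted((float(c), float(f)) for c, f in standards)
    conc = np.array([p[0] for p in pts])
    fluor = np.array([p[1] for p in pts])
    if len(np.unique(conc)) < 3:
        raise AssayError("standards: need >= 3 distinct concentrations")
    if np.ptp(conc) == 0:
        raise AssayError("standards: zero concentration spread")

    best = None
    for n in range(len(conc), 2, -1):
        slope, intercept, r2 = _ols(conc[:n], fluor[:n])
        if best is None:
            best = (n, slope, intercept, r2)  # fall back to the shortest prefix
        if r2 >= r2_threshold:
            best = (n, slope, intercept, r2)
            break
        best = (n, slope, intercept, r2)
    n, slope, intercept, r2 = best
    if slope == 0.0:
        raise AssayError("standards: zero slope (fluorescence does not track MUF)")
    return StandardCurve(
        matrix=matrix,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        linear_range=(float(conc[0]), float(conc[n - 1])),
    )


def estimate_initial_rate(
    times: Sequence[float],
    fluorescence: Sequence[float],
    curve: StandardCurve,
    dilution: float,
    r2_threshold: float = 0.98,
) -> RateEstimate:
    """Initial linear hydrolysis rate from one kinetic trace.

    Selects the longest window starting at the first reading whose linear
    fit has r² >= ``r2_threshold`` and >= 4 points (the whole series when
    it has fewer than 6 points); converts the AU·min⁻¹ slope to
    µmol·L⁻¹·min⁻¹ through the standard-curve slope, to mg MUF·L⁻¹·h⁻¹
    (×60 × 0.17617), and divides by ``dilution`` to report the rate of the
    undiluted slurry. Product accumulation can only slow the reaction, so
    the initial prefix is the zero-order regime.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if len(t) < 3:
        raise AssayError("times: need >= 3 kinetic points")
    if curve.slope <= 0:
        raise AssayError("curve: slope must be positive")
    if not 0 < dilution <= 1:
        raise AssayError("dilution: must be in (0, 1]")

    flags: set[str] = set()
    if len(t) < 6:
        slope, _, r2 = _ols(t, y)
        n_win = len(t)
        if r2 < r2_threshold:
            flags.add("nonlinear")
    else:
        slope = r2 = None
        n_win = 0
        for n in range(len(t), 3, -1):
            s, _, r2_n = _ols(t[:n], y[:n])
            if r2_n >= r2_threshold:
                slope, r2, n_win = s, r2_n, n
                break
        if slope is None:
            slope, _, r2 = _ols(t, y)
            n_win = len(t)
            flags.add("nonlinear")

    rate = slope / curve.slope * 60.0 * MUF_MG_PER_UMOL / dilution
    return RateEstimate(rate=float(rate), r_squared=float(r2), window_points=n_win, qc_flags=flags)


def blank_correct(
    sample_rate: float, blank_rate: float, flag_fraction: float = 0.20
) -> tuple[float, set[str]]:
    """Subtract the heat-inactivated blank rate, floored at zero.

    Negative net activities are physically meaningless and are clipped to
    0. A ``high_blank`` flag is set when the blank exceeds
    ``flag_fraction`` of the sample rate (non-enzymatic MUF release or
    matrix effects dominating the signal).
    """
    net = max(sample_rate - blank_rate, 0.0)
    flags: set[str] = set()
    if blank_rate > flag_fraction * max(sample_rate, 0.0):
        flags.add("high_blank")
    return net, flags


def average_concentrations(
    rate_high: float, rate_low: float, tolerance: float = 0.25
) -> tuple[float, bool]:
    """Average the rates from the two substrate concentrations.

    The two concentrations probe whether hydrolysis is substrate-
    independent (V_max reached); the independence flag is raised when the
    relative discrepancy |high − low| / mean exceeds ``tolerance``.
    """
    mean = 0.5 * (rate_high + rate_low)
    if mean == 0.0:
        return 0.0, False
    flag = abs(rate_high - rate_low) / mean > tolerance
    return mean, flag


def plate_activity(
    plate: PlateKineticSeries,
    substrate: str,
    r2_threshold: float = 0.98,
    curve_r2_threshold: float = 0.99,
    blank_flag_fraction: float = 0.20,
    independence_tolerance: float = 0.25,
    average_replicates: bool = True,
) -> tuple[float, float, set[str]]:
    """Full per-plate computation: (rate, sd, qc_flags) for one substrate.

    Standard curves are fit per matrix so each well is calibrated against
    standards prepared in its own matrix (controls for quenching).
    Replicate wells at the same substrate concentration are averaged on
    the fluorescence traces before rate fitting by default; with
    ``average_replicates=False`` rates are fit per well and then averaged.
    The blank rate from matched heat-inactivated wells is subtracted per
    concentration and the two concentrations are averaged.
    """
    curves: dict[str, StandardCurve] = {}
    for matrix in MATRICES:
        std_wells = plate.standards(matrix)
        if std_wells:
            pts = [(w.standard_conc, float(np.mean(w.fluorescence))) for w in std_wells]
            curves[matrix] = fit_standard_curve(pts, matrix=matrix, r2_threshold=curve_r2_threshold)
    if "active" not in curves:
        raise AssayError("standards: no active-matrix standard wells on plate")

    def _group_rate(wells: list[Well], curve: StandardCurve) -> tuple[float, float, set[str]]:
        flags: set[str] = set()
        if average_replicates:
            times = wells[0].times
            fl = np.mean([w.fluorescence for w in wells], axis=0)
            est = estimate_initial_rate(times, fl, curve, wells[0].dilution, r2_threshold)
            per_well = [
                estimate_initial_rate(w.times, w.fluorescence, curve, w.dilution, r2_threshold).rate
                for w in wells
            ]
            flags |= est.qc_flags
            return est.rate, float(np.std(per_well, ddof=1)) if len(per_well) > 1 else 0.0, flags
        ests = [
            estimate_initial_rate(w.times, w.fluorescence, curve, w.dilution, r2_threshold)
            for w in wells
        ]
        for e in ests:
            flags |= e.qc_flags
        rates = [e.rate for e in ests]
        return float(np.mean(rates)), float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0, flags

    concs = sorted(
        {w.substrate_conc for w in plate.by_role("sample") if w.substrate == substrate},
        reverse=True,
    )
    if not concs:
        raise AssayError(f"substrate: no sample wells for {substrate!r}")

    conc_rates: list[float] = []
    sds: list[float] = []
    flags: set[str] = set()
    for conc in concs:
        samp = [
            w for w in plate.by_role("sample") if w.substrate == substrate and w.substrate_conc == conc
        ]
        blank = [
            w for w in plate.by_role("blank") if w.substrate == substrate and w.substrate_conc == conc
        ]
        s_rate, s_sd, f = _group_rate(samp, curves["active"])
        flags |= f
        b_rate = 0.0
        if blank:
            b_curve = curves.get("heat_inactivated", curves["active"])
            b_rate, _, _ = _group_rate(blank, b_curve)
        net, bflags = blank_correct(s_rate, b_rate, blank_flag_fraction)
        flags |= bflags
        conc_rates.append(net)
        sds.append(s_sd)

    if len(conc_rates) >= 2:
        rate, dep = average_concentrations(conc_rates[0], conc_rates[1], independence_tolerance)
        if dep:
            flags.add("substrate_dependent")
    else:
        rate = conc_rates[0]
        flags.add("single_concentration")
    sd = float(np.sqrt(np.mean(np.square(sds))))
    return rate, sd, flags


# ---------------------------------------------------------------------------
# Delimited-text I/O

PLATE_COLUMNS = [
    "well",
    "role",
    "substrate",
    "substrate_conc",
    "matrix",
    "dilution",
    "standard_conc",
    "time_min",
    "fluorescence",
]


def read_plate_table(path, sep: str | None = None) -> PlateKineticSeries:
    """Read a long-format plate table (CSV/TSV; one row per reading)."""
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns and c != "standard_conc"]
    if missing:
        raise AssayError(f"plate table: missing columns {missing}")
    wells = []
    for well_id, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_min")
        first = grp.iloc[0]
        std = first.get("standard_conc")
        wells.append(
            Well(
                well_id=str(well_id),
                role=str(first["role"]),
                substrate=str(first["substrate"]),
                substrate_conc=float(first["substrate_conc"]),
                matrix=str(first["matrix"]),
                dilution=float(first["dilution"]),
                times=grp["time_min"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                standard_conc=None if pd.isna(std) else float(std),
            )
        )
    return PlateKineticSeries(wells=wells)


def write_plate_table(plate: PlateKineticSeries, path, sep: str = "\t") -> None:
    rows = []
    for w in plate.wells:
        for t, f in zip(w.times, w.fluorescence):
            rows.append(
                {
                    "well": w.well_id,
                    "role": w.role,
                    "substrate": w.substrate,
                    "substrate_conc": w.substrate_conc,
                    "matrix": w.matrix,
                    "dilution": w.dilution,
                    "standard_conc": "" if w.standard_conc is None else w.standard_conc,
                    "time_min": t,
                    "fluorescence": repr(float(f)),
                }
            )
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, sep=sep, index=False)


def write_activity_series(series_list: Iterable[ActivitySeries], path, sep: str = "\t") -> None:
    pd.concat([s.to_frame() for s in series_list], ignore_index=True).to_csv(
        path, sep=sep, index=False
    )


def read_activity_series(path, sep: str = "\t") -> list[ActivitySeries]:
    df = pd.read_csv(path, sep=sep)
    out = []
    for (reactor, enzyme), grp in df.groupby(["reactor", "enzyme"], sort=True):
        grp = grp.sort_values("day")
        flags = [
            frozenset(str(f).split(";")) if isinstance(f, str) and f else frozenset()
            for f in grp["flags"].fillna("")
        ]
        out.append(
            ActivitySeries(
                reactor=str(reactor),
                enzyme=str(enzyme),
                days=grp["day"].to_numpy(),
                rates=grp["rate"].to_numpy(dtype=float),
                sds=grp["sd"].to_numpy(dtype=float),
                qc_flags=flags,
            )
        )
    return out
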
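"""Derived quantities from whole-cell steady-state I-V recordings.

Implements the analysis conventions of the bestrophin dual-gate study:

* steady-state currents as the mean of the final fraction of each voltage
  step;
* reversal potentials by linear interpolation between the step pair
  bracketing zero current;
* bi-ionic relative permeability from the Goldman-Hodgkin-Katz voltage
  relation ``dE_rev = 59 log10(150 P_Cl / (120 P_X))`` mV, so that
  ``P_X/P_Cl = (150/120) * 10^(-dE_rev/59)``;
* slope conductances at E_rev +/- 50 mV (influx branch with the external
  methanesulfonate current pre-multiplied by 1.2 to compensate the
  120-vs-150 mM concentration difference; the efflux/"trans" branch
  without compensation);
* Ca2+ fold-stimulation as the current(-density) ratio at +100 mV;
* two-tailed unpaired Student's t comparisons with mean +/- s.e.m.

Per-cell quantities are computed first and then averaged; cells are never
pooled before derivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    NoReversalError,
    ProtocolError,
    UndefinedFoldError,
    WindowError,
)


@dataclass(frozen=True)
class EphysConstants:
    """Constants of the permeability/conductance arithmetic.

    Defaults reproduce the study conventions: a 59 mV/decade Nernst slope,
    150 mM internal Cl-, 120 mM external methanesulfonate, a 1.2x
    concentration compensation on the methanesulfonate current, and slope
    windows centred 50 mV either side of the reversal potential.
    """

    nernst_slope: float = 59.0      # mV per decade
    cl_internal: float = 150.0      # mM
    x_external: float = 120.0       # mM
    conc_compensation: float = 1.2  # applied to external-X current
    offset_voltage: float = 50.0    # mV from E_rev for slope windows


@dataclass(frozen=True)
class IVCurve:
    """One condition's steady-state current vs. step voltage."""

    voltages: np.ndarray            # mV, strictly increasing
    currents: np.ndarray            # pA or pA/pF
    units: str = "pA"               # "pA" | "pA_per_pF"
    external_anion: str = "Cl"      # "Cl" | "CH3SO3"
    ca_level: float = 0.0           # uM free Ca2+
    cell_id: str = ""
    capacitance: float | None = None   # pF
    junction_offset: float = 0.0       # mV
    junction_applied: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        if v.ndim != 1 or v.shape != i.shape:
            raise ProtocolError(
                f"voltages {v.shape} and currents {i.shape} must be equal-length"
            )
        if len(v) and not np.all(np.diff(v) > 0):
            raise ProtocolError("step voltages must be strictly increasing")
        if not np.all(np.isfinite(i)) or not np.all(np.isfinite(v)):
            raise ProtocolError("voltages and currents must be finite")
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "currents", i)

    @property
    def effective_voltages(self) -> np.ndarray:
        """Voltages with the liquid-junction offset applied (if pending)."""
        if self.junction_applied:
            return self.voltages
        return self.voltages - self.junction_offset

    def scaled(self, factor: float) -> "IVCurve":
        return replace(self, currents=self.currents * factor)


@dataclass(frozen=True)
class PermeabilityResult:
    """Bi-ionic relative permeability P_X/P_Cl."""

    delta_erev: float               # mV
    p_ratio: float
    per_cell: tuple[float, ...] = ()
    mean: float | None = None
    sem: float | None = None


@dataclass(frozen=True)
class ConductanceResult:
    """Slope-conductance ratio G_X/G_Cl on one branch of the I-V curve."""

    g_ratio: float
    branch: str                     # "influx" (E_rev+50) | "trans" (E_rev-50)
    per_cell: tuple[float, ...] = ()
    mean: float | None = None
    sem: float | None = None


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t: float
    p: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# per-curve operations
# ---------------------------------------------------------------------------

def steady_state_currents(
    traces: Sequence[np.ndarray],
    voltages: Sequence[float],
    window_fraction: float = 0.1,
    **curve_kwargs,
) -> IVCurve:
    """Collapse per-step time series to steady-state currents.

    Each step's steady-state value is the mean of the final
    ``window_fraction`` of its samples (default: last 10 %).
    """
    if len(traces) != len(voltages):
        raise ProtocolError(
            f"{len(traces)} traces for {len(voltages)} step potentials"
        )
    steady = []
    for k, trace in enumerate(traces):
        t = np.asarray(trace, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ProtocolError(f"trace {k} is not a non-empty 1-D series")
        n_win = max(1, int(round(window_fraction * len(t))))
        if n_win > len(t):
            raise ProtocolError(f"trace {k} shorter than the averaging window")
        steady.append(float(t[-n_win:].mean()))
    order = np.argsort(voltages)
    v = np.asarray(voltages, dtype=float)[order]
    i = np.asarray(steady, dtype=float)[order]
    return IVCurve(voltages=v, currents=i, **curve_kwargs)


def to_current_density(iv: IVCurve) -> IVCurve:
    """Normalise currents by membrane capacitance (pA -> pA/pF)."""
    if iv.units == "pA_per_pF":
        return iv
    if iv.capacitance is None or iv.capacitance <= 0:
        raise ProtocolError(
            f"cell {iv.cell_id!r}: capacitance missing or non-positive; "
            "cannot convert to current density"
        )
    return replace(iv, currents=iv.currents / iv.capacitance, units="pA_per_pF")


def reversal_potential(iv: IVCurve) -> float:
    """Zero-current voltage (mV) by linear interpolation.

    The crossing is interpolated between the bracketing step pair; with
    multiple sign changes the crossing nearest 0 mV is used.
    """
    v = iv.effective_voltages
    i = iv.currents
    candidates: list[float] = []
    for k in range(len(v) - 1):
        i0, i1 = i[k], i[k + 1]
        if i0 == 0.0:
            candidates.append(float(v[k]))
        elif i0 * i1 < 0:
            candidates.append(float(v[k] - i0 * (v[k + 1] - v[k]) / (i1 - i0)))
    if len(i) and i[-1] == 0.0:
        candidates.append(float(v[-1]))
    if not candidates:
        raise NoReversalError(
            f"cell {iv.cell_id!r} ({iv.external_anion}, {iv.ca_level} uM Ca): "
            "current does not change sign over the voltage range"
        )
    return min(candidates, key=abs)


def relative_permeability(
    erev_x: float,
    erev_cl: float,
    constants: EphysConstants | None = None,
) -> PermeabilityResult:
    """P_X/P_Cl from the bi-ionic reversal-potential shift.

    ``dE_rev = erev_x - erev_cl``; inverting the GHK voltage relation gives
    ``P_X/P_Cl = (cl_internal / x_external) * 10^(-dE_rev / nernst_slope)``.
    A right-shifted (positive) dE_rev therefore means the external anion is
    less permeant than Cl-.
    """
    c = constants or EphysConstants()
    delta = erev_x - erev_cl
    p_ratio = (c.cl_internal / c.x_external) * 10.0 ** (-delta / c.nernst_slope)
    return PermeabilityResult(delta_erev=delta, p_ratio=p_ratio)


def delta_erev_from_p_ratio(
    p_ratio: float, constants: EphysConstants | None = None
) -> float:
    """Inverse of :func:`relative_permeability`: the GHK shift for a P ratio."""
    c = constants or EphysConstants()
    if p_ratio <= 0:
        raise ValueError("p_ratio must be positive")
    return c.nernst_slope * math.log10(
        c.cl_internal / (c.x_external * p_ratio)
    )


def slope_conductance(
    iv: IVCurve,
    at_voltage: float,
    half_window: float | None = None,
) -> float:
    """Local slope dI/dV (nS for pA-mV data) around ``at_voltage``.

    A least-squares line is fitted to all points within ``at_voltage +/-
    half_window``.  By default the window just spans the step points
    bracketing ``at_voltage`` (a two-point secant off-grid; the two
    neighbours plus the point itself on-grid).
    """
    v = iv.effective_voltages
    i = iv.currents
    if half_window is None:
        below = v[v < at_voltage]
        above = v[v > at_voltage]
        spans = []
        if len(below):
            spans.append(at_voltage - below.max())
        if len(above):
            spans.append(above.min() - at_voltage)
        if not spans:
            raise WindowError(
                f"no step points around {at_voltage:g} mV "
                f"(range {v.min():g}..{v.max():g} mV)"
            )
        half_window = max(spans)
    mask = (v >= at_voltage - half_window - 1e-9) & (
        v <= at_voltage + half_window + 1e-9
    )
    if mask.sum() < 2:
        raise WindowError(
            f"only {int(mask.sum())} point(s) within {at_voltage:g} +/- "
            f"{half_window:g} mV; need >= 2"
        )
    slope, _ = np.polyfit(v[mask], i[mask], 1)
    return float(slope)


def conductance_ratio_influx(
    iv_x: IVCurve,
    iv_cl: IVCurve,
    constants: EphysConstants | None = None,
) -> ConductanceResult:
    """G_X(E_rev,X + 50 mV) / G_Cl(E_rev,Cl + 50 mV), anion-influx branch.

    The external-X current is pre-multiplied by the concentration
    compensation factor (1.2 by default) before the slope is taken.
    """
    c = constants or EphysConstants()
    e_x = reversal_potential(iv_x)
    e_cl = reversal_potential(iv_cl)
    g_x = slope_conductance(iv_x.scaled(c.conc_compensation), e_x + c.offset_voltage)
    g_cl = slope_conductance(iv_cl, e_cl + c.offset_voltage)
    return ConductanceResult(g_ratio=g_x / g_cl, branch="influx")


def trans_effect(
    iv_ex_x: IVCurve,
    iv_ex_cl: IVCurve,
    constants: EphysConstants | None = None,
) -> ConductanceResult:
    """Trans-effect statistic: Cl- efflux conductance ratio at E_rev - 50 mV.

    Slope conductance under external X divided by the same under external
    Cl-, each at its own reversal potential minus 50 mV.  No concentration
    compensation is applied (the moving ion is internal Cl- in both cases).
    """
    c = constants or EphysConstants()
    e_x = reversal_potential(iv_ex_x)
    e_cl = reversal_potential(iv_ex_cl)
    g_x = slope_conductance(iv_ex_x, e_x - c.offset_voltage)
    g_cl = slope_conductance(iv_ex_cl, e_cl - c.offset_voltage)
    return ConductanceResult(g_ratio=g_x / g_cl, branch="trans")


def ca_stimulation(
    iv_ca: IVCurve,
    iv_noca: IVCurve,
    at_voltage: float = 100.0,
) -> float:
    """Ca2+ fold-stimulation: current(-density) ratio at +100 mV."""
    def value_at(iv: IVCurve) -> float:
        v = iv.effective_voltages
        idx = np.where(np.isclose(v, at_voltage, atol=1e-6))[0]
        if len(idx) == 0:
            raise ProtocolError(
                f"cell {iv.cell_id!r}: no step at {at_voltage:g} mV"
            )
        return float(iv.currents[idx[0]])

    num = value_at(iv_ca)
    den = value_at(iv_noca)
    if den == 0.0:
        raise UndefinedFoldError(
            f"cell {iv_noca.cell_id!r}: zero current at {at_voltage:g} mV "
            "without Ca2+; fold stimulation undefined"
        )
    return num / den


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> GroupComparison:
    """Two-tailed unpaired Student's t test with mean +/- s.e.m. per group."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"each group needs n >= 2 (got {len(a)} and {len(b)})"
        )
    sem_a = float(a.std(ddof=1) / math.sqrt(len(a)))
    sem_b = float(b.std(ddof=1) / math.sqrt(len(b)))
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        # degenerate: zero variance in both groups
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = math.inf if a.mean() > b.mean() else -math.inf, 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    return GroupComparison(
        mean_a=float(a.mean()), sem_a=sem_a,
        mean_b=float(b.mean()), sem_b=sem_b,
        t=t, p=p, n_a=len(a), n_b=len(b),
    )


# ---------------------------------------------------------------------------
# study-shaped batch analysis
# ---------------------------------------------------------------------------

SCHEMA_COLUMNS = (
    "cell_id", "genotype", "external_anion", "ca_uM",
    "voltage_mV", "current_pA", "capacitance_pF",
)


@dataclass
class EphysReport:
    """Per-genotype summary of the derived quantities."""

    genotype: str
    n_cells: int
    p_ratio: PermeabilityResult | None = None
    g_ratio_influx: ConductanceResult | None = None
    trans: ConductanceResult | None = None
    ca_fold_cl: tuple[float | None, float | None] = (None, None)   # mean, sem
    ca_fold_x: tuple[float | None, float | None] = (None, None)
    ca_vs_noca_cl: GroupComparison | None = None
    per_cell: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def cond(r):
            if r is None:
                return None
            return {"mean": r.mean, "sem": r.sem, "per_cell": list(r.per_cell),
                    "branch": getattr(r, "branch", None)}

        d = {
            "genotype": self.genotype,
            "n_cells": self.n_cells,
            "p_ratio": None,
            "g_ratio_influx": cond(self.g_ratio_influx),
            "trans_effect": cond(self.trans),
            "ca_fold_cl": {"mean": self.ca_fold_cl[0], "sem": self.ca_fold_cl[1]},
            "ca_fold_ch3so3": {"mean": self.ca_fold_x[0], "sem": self.ca_fold_x[1]},
        }
        if self.p_ratio is not None:
            d["p_ratio"] = {
                "mean": self.p_ratio.mean,
                "sem": self.p_ratio.sem,
                "delta_erev_mV": self.p_ratio.delta_erev,
                "per_cell": list(self.p_ratio.per_cell),
            }
        if self.ca_vs_noca_cl is not None:
            g = self.ca_vs_noca_cl
            d["ca_vs_noca_cl_at_100mV"] = {
                "mean_ca": g.mean_a, "sem_ca": g.sem_a,
                "mean_noca": g.mean_b, "sem_noca": g.sem_b,
                "t": g.t, "p": g.p,
            }
        return d


def _mean_sem(values: Sequence[float]) -> tuple[float | None, float | None]:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return None, None
    arr = np.asarray(vals, dtype=float)
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else None
    return float(arr.mean()), sem


def curves_from_table(df: pd.DataFrame) -> dict[tuple[str, str, str, float], IVCurve]:
    """Build per-(genotype, cell, anion, Ca) IVCurves from a schema table.

    Expected columns: cell_id, genotype, external_anion, ca_uM, voltage_mV,
    current_pA, capacitance_pF and optionally junction_mV.
    """
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ProtocolError(f"I-V table is missing column(s) {missing}")
    curves: dict[tuple[str, str, str, float], IVCurve] = {}
    keys = ["genotype", "cell_id", "external_anion", "ca_uM"]
    for (genotype, cell, anion, ca), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("voltage_mV")
        cap = grp["capacitance_pF"].iloc[0]
        junction = float(grp["junction_mV"].iloc[0]) if "junction_mV" in grp else 0.0
        curves[(genotype, cell, anion, float(ca))] = IVCurve(
            voltages=grp["voltage_mV"].to_numpy(dtype=float),
            currents=grp["current_pA"].to_numpy(dtype=float),
            units="pA",
            external_anion=anion,
            ca_level=float(ca),
            cell_id=str(cell),
            capacitance=float(cap) if np.isfinite(cap) else None,
            junction_offset=junction,
            junction_applied=junction == 0.0,
        )
    return curves


def analyze_recordings(
    df: pd.DataFrame,
    constants: EphysConstants | None = None,
    ca_active: float = 1.2,
) -> dict[str, EphysReport]:
    """Full per-genotype analysis of a study-shaped I-V table.

    For every genotype and cell the available condition pairs yield the
    bi-ionic P ratio, the influx conductance ratio, the trans-effect
    statistic and the Ca2+ fold-stimulations; per-cell values are then
    summarised as mean +/- s.e.m.  Conditions a cell lacks are simply
    omitted from that cell's contribution.
    """
    c = constants or EphysConstants()
    curves = curves_from_table(df)
    genotypes = sorted({k[0] for k in curves})
    reports: dict[str, EphysReport] = {}
    for gt in genotypes:
        cells = sorted({k[1] for k in curves if k[0] == gt})
        per_cell: dict[str, dict[str, float]] = {}
        p_vals, g_vals, t_vals = [], [], []
        fold_cl, fold_x = [], []
        dens_ca, dens_noca = [], []
        for cell in cells:
            def get(anion: str, ca: float) -> IVCurve | None:
                return curves.get((gt, cell, anion, ca))

            row: dict[str, float] = {}
            cl_ca, x_ca = get("Cl", ca_active), get("CH3SO3", ca_active)
            cl_0, x_0 = get("Cl", 0.0), get("CH3SO3", 0.0)
            try:
                if cl_ca is not None and x_ca is not None:
                    res = relative_permeability(
                        reversal_potential(x_ca), reversal_potential(cl_ca), c
                    )
                    row["p_ratio"] = res.p_ratio
                    row["delta_erev_mV"] = res.delta_erev
                    p_vals.append(res.p_ratio)
                    g = conductance_ratio_influx(x_ca, cl_ca, c)
                    row["g_ratio_influx"] = g.g_ratio
                    g_vals.append(g.g_ratio)
                    tr = trans_effect(x_ca, cl_ca, c)
                    row["trans_effect"] = tr.g_ratio
                    t_vals.append(tr.g_ratio)
            except (NoReversalError, WindowError):
                pass
            try:
                if cl_ca is not None and cl_0 is not None:
                    f = ca_stimulation(cl_ca, cl_0)
                    row["ca_fold_cl"] = f
                    fold_cl.append(f)
                    dens_ca.append(
                        float(to_current_density(cl_ca).currents[-1])
                    )
                    dens_noca.append(
                        float(to_current_density(cl_0).currents[-1])
                    )
            except (UndefinedFoldError, ProtocolError):
                pass
            try:
                if x_ca is not None and x_0 is not None:
                    f = ca_stimulation(x_ca, x_0)
                    row["ca_fold_ch3so3"] = f
                    fold_x.append(f)
            except (UndefinedFoldError, ProtocolError):
                pass
            per_cell[cell] = row

        report = EphysReport(genotype=gt, n_cells=len(cells), per_cell=per_cell)
        if p_vals:
            m, s = _mean_sem(p_vals)
            deltas = [per_cell[c_]["delta_erev_mV"]
                      for c_ in per_cell if "delta_erev_mV" in per_cell[c_]]
            report.p_ratio = PermeabilityResult(
                delta_erev=float(np.mean(deltas)),
                p_ratio=m,
                per_cell=tuple(p_vals), mean=m, sem=s,
            )
        if g_vals:
            m, s = _mean_sem(g_vals)
            report.g_ratio_influx = ConductanceResult(
                g_ratio=m, branch="influx",
                per_cell=tuple(g_vals), mean=m, sem=s,
            )
        if t_vals:
            m, s = _mean_sem(t_vals)
            report.trans = ConductanceResult(
                g_ratio=m, branch="trans",
                per_cell=tuple(t_vals), mean=m, sem=s,
            )
        report.ca_fold_cl = _mean_sem(fold_cl)
        report.ca_fold_x = _mean_sem(fold_x)
        if len(dens_ca) >= 2 and len(dens_noca) >= 2:
            report.ca_vs_noca_cl = group_compare(dens_ca, dens_noca)
        reports[gt] = report
    return reports
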
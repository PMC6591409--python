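"""Synthetic fixtures with known ground truth.

Two generators make every pipeline stage testable without downloads:

* :func:`make_pentamer_fixture` builds C5-symmetric pseudo-pentamer
  coordinates (five chains A-E) whose constriction rings have a stated
  circumradius, controlled Gaussian radial jitter and an optional
  single-point displacement - the geometry of a pentameric channel reduced
  to exactly what the ring-radius and asymmetry measurements consume.

* :func:`simulate_ghk_iv` produces whole-cell step recordings following
  Goldman-Hodgkin-Katz (GHK) electrodiffusion under the study's solutions
  (150 mM internal Cl-, ~151 mM external Cl- or 120 mM external
  methanesulfonate), with additive noise, optional ohmic leak, a Ca2+
  activation factor and an optional trans-gating gain; the analytic
  reversal potential of the noiseless curve closes the recovery loop.

The trans gain multiplies the inward-current limb of the net current under
external methanesulfonate.  Gating modifies conductance, not the ionic
equilibrium, so the gain is sign-gated on the net current and leaves the
reversal potential invariant; a per-ion-flux gain would shift E_rev and
conflate selectivity with gating.

All generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ephys import IVCurve, steady_state_currents
from .pore_geometry import GeometryConstants, PENTAGON_FACTOR_EXACT
from .structure_io import Atom, StructureModel

#: Default step protocol: -100..+100 mV in 20 mV steps, holding 0 mV.
DEFAULT_PROTOCOL = tuple(float(v) for v in range(-100, 101, 20))

_CHAINS = ("A", "B", "C", "D", "E")
_PHE_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
_PROBE_ATOM = {"ILE": "CD1", "VAL": "CG1", "LEU": "CD1"}
_OUTER_METHYL = {"VAL": "CG2", "LEU": "CD2"}


# ---------------------------------------------------------------------------
# structural fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingSpec:
    """One constriction ring of a pseudo-pentamer fixture."""

    residue_number: int
    residue_name: str              # ILE, VAL, LEU or PHE
    circumradius: float            # A, axis -> probe atom (or inferred H)
    z: float = 0.0                 # A, position along the pore axis
    jitter_sd: float = 0.0         # A, per-point radial Gaussian jitter
    displaced_point: int | None = None
    displacement: float = 0.0      # A, radial shift of the displaced point


@dataclass(frozen=True)
class PentamerSpec:
    """Specification of a five-chain synthetic channel fixture."""

    rings: tuple[RingSpec, ...]
    seed: int = 0
    identifier: str = "SYNTH-PENTAMER"


def expected_fixture_radius(
    circumradius: float,
    probe_vdw_radius: float,
    constants: GeometryConstants | None = None,
) -> float:
    """Closed-form ring radius of a perfect C5 fixture.

    For a regular pentagon of circumradius R the five edges are
    2 R sin(36 deg), so the measured radius is
    ``(2 sin 36 / pentagon_factor) * R - probe_vdw``.
    """
    c = constants or GeometryConstants()
    return PENTAGON_FACTOR_EXACT * circumradius / c.pentagon_factor - probe_vdw_radius


def make_pentamer_fixture(spec: PentamerSpec) -> StructureModel:
    """Build a five-chain C5 pseudo-pentamer with the requested rings.

    Each ring's probe atoms sit at angles 2*pi*k/5 (k = 0..4, chains A-E)
    at the stated circumradius and z.  Ile/Val/Leu rings carry the methyl
    probe carbon directly (plus, for Val/Leu, the second methyl placed
    farther from the axis, so the pore-lining choice is exercised); Phe
    rings are emitted as full six-carbon planar rings oriented so that the
    inferred inward hydrogen lands exactly at the stated circumradius.
    Every residue also carries a CA atom (circumradius + 5 A) so the
    superposition machinery has a backbone-like selection to match.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []

    # draw all jitter up-front so chain iteration order cannot change it
    jitter: dict[int, np.ndarray] = {}
    for ring in spec.rings:
        jitter[ring.residue_number] = (
            rng.normal(0.0, ring.jitter_sd, size=5)
            if ring.jitter_sd > 0
            else np.zeros(5)
        )

    for k, chain_id in enumerate(_CHAINS):
        theta = 2.0 * math.pi * k / 5.0
        u = np.array([math.cos(theta), math.sin(theta), 0.0])  # radial unit
        for ring in sorted(spec.rings, key=lambda r: r.residue_number):
            r_eff = ring.circumradius + jitter[ring.residue_number][k]
            if ring.displaced_point == k:
                r_eff += ring.displacement
            z = np.array([0.0, 0.0, ring.z])

            def add(name: str, pos: np.ndarray, element: str = "C") -> None:
                atoms.append(
                    Atom(
                        chain_id=chain_id,
                        residue_number=ring.residue_number,
                        residue_name=ring.residue_name,
                        atom_name=name,
                        alt_loc="",
                        element=element,
                        position=pos,
                        occupancy=1.0,
                    )
                )

            add("CA", (r_eff + 5.0) * u + z)
            name = ring.residue_name.upper()
            if name in ("ILE", "VAL", "LEU"):
                add(_PROBE_ATOM[name], r_eff * u + z)
                if name in _OUTER_METHYL:
                    add(_OUTER_METHYL[name], (r_eff + 1.5) * u + z)
            elif name == "PHE":
                # hexagon in the (radial, z) plane; innermost C at r_eff+1.08,
                # its exocyclic bisector points at the axis, so the inferred
                # inward H sits at radius r_eff exactly.
                ch = 1.08
                cc = 1.39  # aromatic ring circumradius
                center = (r_eff + ch + cc) * u + z
                zhat = np.array([0.0, 0.0, 1.0])
                for m, aname in enumerate(_PHE_RING_ATOMS):
                    phi = math.pi + m * math.pi / 3.0  # start pointing inward
                    pos = center + cc * (
                        math.cos(phi) * u + math.sin(phi) * zhat
                    )
                    add(aname, pos)
            else:
                raise ValueError(
                    f"fixture rings support ILE/VAL/LEU/PHE, got {name}"
                )
    return StructureModel(identifier=spec.identifier, atoms=atoms)


# ---------------------------------------------------------------------------
# GHK recordings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GHKParams:
    """Ground truth of the GHK whole-cell simulator.

    ``conductance_scale`` sets the Cl- permeability in instrument units
    (pA per mM of driving term); with the default 1.0 the external-Cl
    curve tops out near 600 pA at +100 mV, so the default 6 pA noise is
    about 1 % of the maximal current.  ``ca_scale`` multiplies the channel
    current in the presence of activating Ca2+ relative to the Ca2+-free
    (spontaneous) level, so the fold-stimulation at +100 mV recovers it.
    """

    p_ratio: float = 0.25              # P_X / P_Cl
    cl_internal: float = 150.0         # mM
    cl_external: float = 151.0         # mM (sum of external Cl- sources)
    x_external: float = 120.0          # mM methanesulfonate
    nernst_slope: float = 59.0         # mV per decade
    conductance_scale: float = 1.0     # pA / mM
    trans_gain: float = 1.0            # inward-limb gain under external X
    leak: float = 0.0                  # nS ohmic leak
    noise_sd: float = 6.0              # pA, sd of each steady-state point
    ca_scale: float = 9.0              # Ca2+ fold-stimulation
    seed: int = 0

    @property
    def thermal_voltage(self) -> float:
        """mV per e-fold, nernst_slope / ln 10."""
        return self.nernst_slope / math.log(10.0)


def ghk_current(
    voltages: np.ndarray,
    c_in: float,
    c_out: float,
    permeability: float,
    thermal_voltage: float,
) -> np.ndarray:
    """GHK electrodiffusion current of one monovalent anion, outward positive.

    ``I = P * u * (c_in - c_out e^u) / (1 - e^u)`` with ``u = V / V_T``.
    Anion influx (external ion entering) is outward current; internal-anion
    efflux is inward (negative) current.
    """
    v = np.asarray(voltages, dtype=float)
    u = v / thermal_voltage
    small = np.abs(u) < 1e-9
    u_safe = np.where(small, 1.0, u)
    out = permeability * u_safe * (c_in - c_out * np.exp(u_safe)) / (
        -np.expm1(u_safe)
    )
    limit = -permeability * (c_in - c_out)  # u -> 0
    return np.where(small, limit, out)


def analytic_reversal(params: GHKParams, external_anion: str) -> float:
    """Zero-current voltage (mV) of the noiseless GHK curve."""
    if external_anion == "Cl":
        c_out = params.cl_external
    elif external_anion == "CH3SO3":
        c_out = params.p_ratio * params.x_external
    else:
        raise ValueError(f"unknown external anion {external_anion!r}")
    return params.thermal_voltage * math.log(params.cl_internal / c_out)


def noiseless_currents(
    params: GHKParams,
    voltages: Sequence[float],
    external_anion: str,
    ca_level: float,
) -> np.ndarray:
    """Net steady-state current (pA) at each step potential, no noise."""
    v = np.asarray(voltages, dtype=float)
    vt = params.thermal_voltage
    s = params.conductance_scale
    if external_anion == "Cl":
        i = ghk_current(v, params.cl_internal, params.cl_external, s, vt)
    elif external_anion == "CH3SO3":
        i = ghk_current(v, params.cl_internal, 0.0, s, vt) + ghk_current(
            v, 0.0, params.x_external, s * params.p_ratio, vt
        )
        # trans gating gain on the inward-current (internal-anion efflux)
        # limb; sign-gated so the reversal potential is untouched
        i = np.where(i < 0, params.trans_gain * i, i)
    else:
        raise ValueError(f"unknown external anion {external_anion!r}")
    if ca_level <= 0:
        i = i / params.ca_scale
    return i + params.leak * v


@dataclass(frozen=True)
class SimulatedRecording:
    """Step traces plus the steady-state I-V curve derived from them."""

    iv: IVCurve
    noiseless: IVCurve
    traces: tuple[np.ndarray, ...]
    analytic_erev: float
    params: GHKParams


def simulate_ghk_iv(
    params: GHKParams,
    protocol: Sequence[float] = DEFAULT_PROTOCOL,
    external_anion: str = "CH3SO3",
    ca_level: float = 1.2,
    cell_id: str = "sim",
    capacitance: float | None = None,
    n_samples: int = 400,
    window_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
) -> SimulatedRecording:
    """Simulate one condition's step recording and analyse it to an IVCurve.

    Each step trace relaxes exponentially (time constant 5 % of the step)
    onto its GHK steady-state value; per-sample Gaussian noise is scaled so
    that the mean of the final ``window_fraction`` window has standard
    deviation ``params.noise_sd``.  The returned curve is produced by
    :func:`bestgate.ephys.steady_state_currents` on those traces, so the
    simulated and analysed noise models agree by construction.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    v = np.asarray(sorted(protocol), dtype=float)
    steady = noiseless_currents(params, v, external_anion, ca_level)
    n_win = max(1, int(round(window_fraction * n_samples)))
    sample_sd = params.noise_sd * math.sqrt(n_win)
    t = np.arange(n_samples) / n_samples
    tau = 0.05
    traces = []
    for i_ss in steady:
        relax = 0.3 * i_ss * np.exp(-t / tau)
        wiggle = rng.normal(0.0, sample_sd, size=n_samples) if sample_sd > 0 else 0.0
        traces.append(i_ss + relax + wiggle)
    meta = dict(
        external_anion=external_anion,
        ca_level=ca_level,
        cell_id=cell_id,
        capacitance=capacitance,
    )
    iv = steady_state_currents(traces, v, window_fraction=window_fraction, **meta)
    noiseless = IVCurve(voltages=v, currents=steady, **meta)
    return SimulatedRecording(
        iv=iv,
        noiseless=noiseless,
        traces=tuple(traces),
        analytic_erev=analytic_reversal(params, external_anion),
        params=params,
    )


#: Phenomenological per-genotype ground truth used by the study-shaped
#: generator.  P ratios and Ca2+ folds follow the measured phenotypes
#: (wild type selects strongly against methanesulfonate and is ~9-fold
#: Ca2+-stimulated; aperture mutants equalise permeabilities; neck mutants
#: lose the trans effect); trans gains are qualitative (present/absent).
GENOTYPE_PRESETS: Mapping[str, GHKParams] = {
    "WT": GHKParams(p_ratio=0.25, ca_scale=9.0, trans_gain=2.0),
    "I205A": GHKParams(p_ratio=1.15, ca_scale=5.0, trans_gain=2.0),
    "3A": GHKParams(p_ratio=0.42, ca_scale=2.0, trans_gain=1.0),
    "4A": GHKParams(p_ratio=1.17, ca_scale=1.0, trans_gain=1.0),
}


def make_recording_set(
    genotypes: Sequence[str] = ("WT", "I205A", "3A", "4A"),
    params: Mapping[str, GHKParams] | None = None,
    n_cells: int = 6,
    seed: int = 0,
    protocol: Sequence[float] = DEFAULT_PROTOCOL,
    ca_levels: Sequence[float] = (0.0, 1.2),
    anions: Sequence[str] = ("Cl", "CH3SO3"),
    capacitance_mean: float = 15.0,
    capacitance_sd: float = 3.0,
    cell_scale_sd: float = 0.15,
) -> pd.DataFrame:
    """Full study-shaped dataset: genotype x external anion x Ca2+ x cells.

    Returns a long-format table in the analysis schema (cell_id, genotype,
    external_anion, ca_uM, voltage_mV, current_pA, capacitance_pF).
    Per-cell capacitance is N(15, 3) pF truncated above 5 pF, and channel
    density varies log-normally between cells (sd ``cell_scale_sd`` in log
    space); within a cell all four conditions share the same scale, as a
    real solution-exchange experiment would.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    presets = params or GENOTYPE_PRESETS
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in genotypes:
        base = presets[genotype]
        for cell_idx in range(n_cells):
            cell_id = f"{genotype}-c{cell_idx + 1:02d}"
            cap = 0.0
            while cap <= 5.0:
                cap = rng.normal(capacitance_mean, capacitance_sd)
            scale = (cap / capacitance_mean) * math.exp(
                rng.normal(0.0, cell_scale_sd)
            )
            cell_params = replace(
                base, conductance_scale=base.conductance_scale * scale
            )
            for anion in anions:
                for ca in ca_levels:
                    rec = simulate_ghk_iv(
                        cell_params,
                        protocol=protocol,
                        external_anion=anion,
                        ca_level=ca,
                        cell_id=cell_id,
                        capacitance=cap,
                        rng=rng,
                    )
                    for volt, curr in zip(rec.iv.voltages, rec.iv.currents):
                        rows.append(
                            (cell_id, genotype, anion, ca, volt, curr, cap)
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "genotype", "external_anion", "ca_uM",
            "voltage_mV", "current_pA", "capacitance_pF",
        ],
    )
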
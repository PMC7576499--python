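"""Forward simulation of stopped-flow shock experiments and procedural
generation of toy channel structures and alignments.

Every downstream stage of the package (kinetics estimation, pore profiling,
conservation analysis) can be exercised end-to-end against data produced here
with known ground truth.

Shock traces
------------
Two forward models are provided:

``exponential``
    The exact inverse of the estimator chain.  A water shock relaxes as
    ``v(t) = v_inf + (1 - v_inf) exp(-k t)`` with ``k`` back-computed from the
    ``P_f`` formula; a glycerol shock freezes the exponential once shrinkage
    is complete (residual amplitude 2%) and re-swells linearly with slope
    ``m = P_gly (A/V0)``.  Noiseless traces are recovered to machine
    precision by the estimators.

``ode``
    A mechanistic two-state model: relative volume ``v`` and internal
    glycerol amount ``n`` (mol per cm^3 of initial cell volume) obey

        dv/dt = -P_f (A/V0) V_w (C_out - C_in),   C_in = (a_imp + n) / v
        dn/dt =  P_gly (A/V0) (C_gly,out - n / v)

    with all internal solutes osmotically active by default.  For a sorbitol
    shock the external medium is entirely impermeant; for a glycerol shock
    the final external osmolarity is carried entirely by glycerol, which is
    the composition under which the operational slope formula approximates
    ``P_gly``.

Both permeabilities scale with temperature by Arrhenius factors
``exp(-E_a/R (1/T - 1/T_ref))``.  Fluorescence is a linear self-quenching
readout, ``F = baseline + span * v`` plus i.i.d. Gaussian noise of standard
deviation ``noise_sd * span``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .constants import OSMOLAR_TO_MOL_PER_CM3, arrhenius_factor
from .errors import InsufficientDesignError, InvalidParameterError, InvalidSpecError
from .kinetics import (
    CellGeometry,
    ShockConditions,
    ShockTrace,
    reswelling_slope_constant,
    shrinkage_rate_constant,
)

__all__ = [
    "SimulationParams",
    "SyntheticStructureSpec",
    "AlignmentSpec",
    "simulate_shock",
    "simulate_arrhenius_series",
    "make_channel_structure",
    "make_alignment",
    "default_simulation_params",
    "SIMILARITY_GROUPS",
]

#: Residual fraction of the shrinkage amplitude at which the exponential-mode
#: glycerol trace switches from exponential decay to linear re-swelling.
SHRINK_COMPLETE_RESIDUAL = 0.02

#: Default acquisition stopping rules (see docs/methods.md): a water shock is
#: recorded until 90% of the amplitude has decayed, a glycerol shock until the
#: cell has re-swollen by 12% of its initial volume past shrink completion.
WATER_DECAY_DEPTH = 10.0  # record for ln(10)/k seconds
GLYCEROL_RECOVERY_DEPTH = 0.12  # relative-volume units of recovery


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of a simulated strain and experiment."""

    pf_true: float  # cm s^-1
    pgly_true: float  # cm s^-1, 0 allowed
    ea_water: float  # kcal mol^-1
    ea_glycerol: float  # kcal mol^-1
    duration: float  # s
    dt: float  # s
    t_ref: float = 23.0  # deg C at which pf_true / pgly_true hold
    geometry: CellGeometry = field(default_factory=CellGeometry)
    conditions: ShockConditions = field(default_factory=ShockConditions)
    noise_sd: float = 0.0  # fraction of the signal span
    mode: str = "exponential"  # "exponential" | "ode"
    seed: int = 0
    signal_baseline: float = 0.0
    signal_span: float = 1.0
    strain: str | None = None

    def __post_init__(self):
        if self.pf_true < 0 or self.pgly_true < 0:
            raise InvalidParameterError("permeabilities must be non-negative")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be positive")
        if not (0 < self.dt < self.duration):
            raise InvalidParameterError("dt must satisfy 0 < dt < duration")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        if self.mode not in ("exponential", "ode"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")

    @property
    def shock_kind(self) -> str:
        return "water" if self.conditions.shock_solute == "sorbitol" else "glycerol"


def default_simulation_params(
    pf_true: float,
    pgly_true: float,
    ea_water: float,
    ea_glycerol: float,
    shock_solute: str = "sorbitol",
    n_samples: int = 1500,
    **kwargs,
) -> SimulationParams:
    """Build params with acquisition length set by the stopping rules.

    Water shocks are recorded for ``ln(10)/k`` seconds (signal within 10% of
    its plateau); glycerol shocks for the shrink-complete time ``ln(50)/k``
    plus ``0.12/m`` seconds of re-swelling.  ``dt`` is the duration divided by
    ``n_samples``.
    """
    geometry = kwargs.pop("geometry", CellGeometry())
    conditions = kwargs.pop(
        "conditions", ShockConditions(shock_solute=shock_solute)
    )
    if conditions.shock_solute != shock_solute:
        conditions = replace(conditions, shock_solute=shock_solute)
    k = shrinkage_rate_constant(pf_true, geometry, conditions)
    if k <= 0:
        raise InvalidParameterError("pf_true must be positive to size the trace")
    if shock_solute == "sorbitol":
        duration = math.log(WATER_DECAY_DEPTH) / k
    else:
        m = reswelling_slope_constant(pgly_true, geometry)
        recovery = GLYCEROL_RECOVERY_DEPTH / m if m > 0 else 3.0 / k
        duration = -math.log(SHRINK_COMPLETE_RESIDUAL) / k + recovery
    return SimulationParams(
        pf_true=pf_true,
        pgly_true=pgly_true,
        ea_water=ea_water,
        ea_glycerol=ea_glycerol,
        duration=duration,
        dt=duration / n_samples,
        geometry=geometry,
        conditions=conditions,
        **kwargs,
    )


def _scaled_permeabilities(
    params: SimulationParams, temperature: float
) -> tuple[float, float]:
    pf = params.pf_true * arrhenius_factor(
        params.ea_water, temperature, params.t_ref
    )
    pgly = params.pgly_true * arrhenius_factor(
        params.ea_glycerol, temperature, params.t_ref
    )
    return pf, pgly


def _exponential_volume(
    params: SimulationParams, t: np.ndarray, pf: float, pgly: float
) -> np.ndarray:
    cond = params.conditions
    geo = params.geometry
    af = geo.active_fraction
    v_inf = 1.0 - af + af * cond.osm_in_initial / cond.osm_out_final
    k = shrinkage_rate_constant(pf, geo, cond)
    v = v_inf + (1.0 - v_inf) * np.exp(-k * t)
    if params.shock_kind == "glycerol" and pgly > 0:
        m = reswelling_slope_constant(pgly, geo)
        t_on = -math.log(SHRINK_COMPLETE_RESIDUAL) / k
        v_on = v_inf + (1.0 - v_inf) * math.exp(-k * t_on)
        after = t >= t_on
        v = np.where(after, v_on + m * (t - t_on), v)
    return v


def _ode_volume(
    params: SimulationParams, t: np.ndarray, pf: float, pgly: float
) -> np.ndarray:
    cond = params.conditions
    geo = params.geometry
    af = geo.active_fraction
    vb = 1.0 - af  # osmotically inactive volume
    a_over_v0 = 1.0 / geo.v0_over_a
    a_imp_int = cond.osm_in_mol_cm3 * af  # conserved internal impermeants
    c_out_total = cond.osm_out_mol_cm3
    if params.shock_kind == "glycerol":
        c_gly_out = c_out_total  # final medium osmolarity carried by glycerol
    else:
        c_gly_out = 0.0

    def rhs(_t, y):
        v, n = y
        v_act = max(v - vb, 1e-9)
        c_in = (a_imp_int + n) / v_act
        dv = -pf * a_over_v0 * geo.v_w * (c_out_total - c_in)
        dn = pgly * a_over_v0 * (c_gly_out - n / v_act)
        return (dv, dn)

    sol = solve_ivp(
        rhs,
        (0.0, float(t[-1])),
        (1.0, 0.0),
        t_eval=t,
        rtol=1e-9,
        atol=1e-12,
        method="LSODA",
    )
    if not sol.success:
        raise InvalidParameterError(f"volume ODE integration failed: {sol.message}")
    return sol.y[0]


def simulate_shock(params: SimulationParams, temperature: float) -> ShockTrace:
    """Simulate one stopped-flow trace at the given bath temperature."""
    if not (0.0 <= temperature <= 45.0):
        raise InvalidParameterError("temperature must lie within 0-45 degC")
    pf, pgly = _scaled_permeabilities(params, temperature)
    if pf <= 0:
        raise InvalidParameterError("pf_true must be positive to simulate a shock")

    n_steps = int(round(params.duration / params.dt))
    t = np.arange(n_steps + 1) * params.dt
    if params.mode == "exponential":
        v = _exponential_volume(params, t, pf, pgly)
    else:
        v = _ode_volume(params, t, pf, pgly)

    signal = params.signal_baseline + params.signal_span * v
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        signal = signal + rng.normal(
            0.0, params.noise_sd * abs(params.signal_span), size=signal.shape
        )
    return ShockTrace(
        time=t,
        signal=signal,
        temperature=temperature,
        shock_kind=params.shock_kind,
        conditions=params.conditions,
        signal_baseline=params.signal_baseline,
        signal_span=params.signal_span,
        strain=params.strain,
        meta={
            "mode": params.mode,
            "seed": params.seed,
            "temperature_C": temperature,
            "pf_at_T": pf,
            "pgly_at_T": pgly,
        },
    )


def simulate_arrhenius_series(
    params: SimulationParams,
    temperatures: list[float],
    replicates: int,
    scale_time: bool = True,
) -> list[ShockTrace]:
    """Replicated shocks over a temperature grid.

    Replicate ``r`` at temperature index ``i`` uses seed
    ``params.seed + 1000*i + r``.  With ``scale_time`` (default) the
    acquisition window and sampling step are dilated by the inverse Arrhenius
    factor of the shock-relevant permeability, emulating the experimental
    practice of recording each trace until it plateaus; the trace shape (and
    hence any estimator bias) is then temperature-invariant.
    """
    distinct = sorted(set(float(x) for x in temperatures))
    if len(distinct) < 3:
        raise InsufficientDesignError("need at least 3 distinct temperatures")
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")

    ea_relevant = (
        params.ea_water if params.shock_kind == "water" else params.ea_glycerol
    )
    traces = []
    for i, temp in enumerate(temperatures):
        p_i = params
        if scale_time:
            factor = arrhenius_factor(ea_relevant, temp, params.t_ref)
            p_i = replace(
                params, duration=params.duration / factor, dt=params.dt / factor
            )
        for r in range(replicates):
            p_ir = replace(p_i, seed=params.seed + 1000 * i + r)
            traces.append(simulate_shock(p_ir, temp))
    return traces


# --------------------------------------------------------------------------
# toy channel structures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticStructureSpec:
    """Procedural hourglass/cylinder channel.

    Pseudo-atoms are placed on rings of radius ``wall_radius(z) + atom_vdw``
    around the z axis, so the largest inscribed sphere at each ring plane has
    exactly the designed wall radius.  The wall profile is a base cylinder
    with an optional triangular constriction notch.
    """

    axis_length: float = 40.0  # Angstrom
    base_radius: float = 4.0
    constriction_radius: float | None = None
    constriction_z: float | None = None
    constriction_half_width: float = 8.0
    atom_spacing: float = 1.0
    atom_vdw: float = 1.7
    atoms_per_ring: int = 12
    residue_labels: tuple[str, ...] = ("ALA", "VAL", "SER", "THR")
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.atom_spacing <= 0:
            raise InvalidSpecError("atom_spacing must be positive")
        if self.axis_length <= 0 or self.base_radius <= 0 or self.atom_vdw <= 0:
            raise InvalidSpecError("lengths and radii must be positive")
        if self.constriction_radius is not None:
            if self.constriction_radius > self.base_radius:
                raise InvalidSpecError(
                    "constriction radius must not exceed base radius"
                )
            if self.constriction_z is None or not (
                0.0 <= self.constriction_z <= self.axis_length
            ):
                raise InvalidSpecError(
                    "constriction z must lie within [0, axis_length]"
                )
            if self.constriction_half_width <= 0:
                raise InvalidSpecError("constriction half-width must be positive")

    def wall_radius(self, z: float) -> float:
        """Designed inscribed-sphere radius at axial position z."""
        r = self.base_radius
        if self.constriction_radius is not None:
            depth = self.base_radius - self.constriction_radius
            notch = max(0.0, 1.0 - abs(z - self.constriction_z) / self.constriction_half_width)
            r -= depth * notch
        return r


def make_channel_structure(spec: SyntheticStructureSpec):
    """Instantiate the pseudo-atom channel described by ``spec``.

    Returns a :class:`nipflow.pore_structure.Structure`.  Residue numbers
    increase along z (one residue per ring); residue names cycle through
    ``spec.residue_labels``.
    """
    from .pore_structure import Structure

    rng = np.random.default_rng(spec.seed)
    n_rings = int(round(spec.axis_length / spec.atom_spacing)) + 1
    angles = 2.0 * np.pi * np.arange(spec.atoms_per_ring) / spec.atoms_per_ring

    serials, elements, res_names, res_ids, chains = [], [], [], [], []
    coords = []
    serial = 1
    for ring in range(n_rings):
        z = ring * spec.atom_spacing
        ring_r = spec.wall_radius(z) + spec.atom_vdw
        name = spec.residue_labels[ring % len(spec.residue_labels)]
        for a in angles:
            x = ring_r * math.cos(a)
            y = ring_r * math.sin(a)
            if spec.jitter_sd > 0:
                x += rng.normal(0.0, spec.jitter_sd)
                y += rng.normal(0.0, spec.jitter_sd)
            coords.append((x, y, z))
            serials.append(serial)
            elements.append("C")
            res_names.append(name)
            res_ids.append(ring + 1)
            chains.append("A")
            serial += 1

    return Structure(
        serial=np.array(serials, dtype=int),
        element=np.array(elements, dtype="U2"),
        res_name=np.array(res_names, dtype="U3"),
        res_id=np.array(res_ids, dtype=int),
        chain=np.array(chains, dtype="U1"),
        coords=np.array(coords, dtype=float),
        vdw=np.full(len(serials), spec.atom_vdw, dtype=float),
    )


# --------------------------------------------------------------------------
# toy alignments
# --------------------------------------------------------------------------

#: Physicochemical similarity groups used by the generator and available as
#: an alternative classification rule.
SIMILARITY_GROUPS: tuple[frozenset, ...] = tuple(
    frozenset(g) for g in ("ILVMA", "FWY", "ST", "DE", "KRH", "NQ", "GP", "C")
)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def _positive_cliques() -> dict[str, tuple[str, ...]]:
    """For each residue, a greedy set of residues all pairwise BLOSUM62>0."""
    mat = _blosum62()
    cliques: dict[str, tuple[str, ...]] = {}
    for ref in _AMINO_ACIDS:
        members = [ref]
        for cand in _AMINO_ACIDS:
            if cand == ref:
                continue
            if all(mat[cand][m] > 0 for m in members) and mat[cand][cand] > 0:
                members.append(cand)
        cliques[ref] = tuple(members)
    return cliques


def _negative_partners() -> dict[str, tuple[str, ...]]:
    mat = _blosum62()
    return {
        ref: tuple(c for c in _AMINO_ACIDS if c != ref and mat[ref][c] <= 0)
        for ref in _AMINO_ACIDS
    }


@dataclass(frozen=True)
class AlignmentSpec:
    """Toy aligned homolog family with known per-column conservation class."""

    n_seqs: int = 4
    n_cols: int = 60
    channel_cols: tuple[int, ...] = ()  # 1-based; empty = all columns
    p_identical: float = 0.5
    p_similar: float = 0.3
    p_dissimilar: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_seqs < 2 or self.n_cols < 1:
            raise InvalidSpecError("need >= 2 sequences and >= 1 column")
        probs = (self.p_identical, self.p_similar, self.p_dissimilar)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise InvalidSpecError("class probabilities must be >= 0 and sum to 1")
        if any(not (1 <= c <= self.n_cols) for c in self.channel_cols):
            raise InvalidSpecError("channel columns must lie within [1, n_cols]")

    @property
    def effective_channel_cols(self) -> tuple[int, ...]:
        return self.channel_cols or tuple(range(1, self.n_cols + 1))


def make_alignment(spec: AlignmentSpec):
    """Generate an alignment with known per-column conservation classes.

    Returns ``(alignment, ground_truth)`` where ``ground_truth`` maps each
    1-based column to its realized class label.  Columns are constructed so
    that the default BLOSUM62-positive classification rule provably realizes
    the intended class: "similar" columns draw all residues from a pairwise
    BLOSUM62-positive clique around the reference residue (with at least one
    substitution), "dissimilar" columns place at least one residue with a
    non-positive score against the rest.
    """
    from .conservation import ChannelAlignment

    rng = np.random.default_rng(spec.seed)
    cliques = _positive_cliques()
    negatives = _negative_partners()
    similar_capable = [r for r in _AMINO_ACIDS if len(cliques[r]) > 1]

    names = [f"seq{i + 1}" for i in range(spec.n_seqs)]
    columns: list[str] = []
    ground_truth: dict[int, str] = {}
    labels = ("identical", "similar", "dissimilar")
    probs = (spec.p_identical, spec.p_similar, spec.p_dissimilar)

    for col in range(1, spec.n_cols + 1):
        label = labels[rng.choice(3, p=probs)]
        if label == "similar":
            ref = similar_capable[rng.integers(len(similar_capable))]
        else:
            ref = _AMINO_ACIDS[rng.integers(len(_AMINO_ACIDS))]
        residues = [ref]
        if label == "identical":
            residues += [ref] * (spec.n_seqs - 1)
        elif label == "similar":
            clique = cliques[ref]
            residues += [clique[rng.integers(len(clique))] for _ in names[1:]]
            if all(r == ref for r in residues[1:]):  # force >= 1 substitution
                partners = [c for c in clique if c != ref]
                residues[1 + int(rng.integers(spec.n_seqs - 1))] = partners[
                    rng.integers(len(partners))
                ]
        else:
            residues += [ref] * (spec.n_seqs - 1)
            offender = 1 + int(rng.integers(spec.n_seqs - 1))
            neg = negatives[ref]
            residues[offender] = neg[rng.integers(len(neg))]
        columns.append("".join(residues))
        ground_truth[col] = label

    sequences = {
        name: "".join(columns[c][i] for c in range(spec.n_cols))
        for i, name in enumerate(names)
    }
    alignment = ChannelAlignment(
        sequences=sequences,
        channel_columns=spec.effective_channel_cols,
        reference=names[0],
    )
    truth = {c: ground_truth[c] for c in spec.effective_channel_cols}
    return alignment, truth
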
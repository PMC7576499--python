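"""Stopped-flow permeability estimation.

The measurement chain mirrors the standard stopped-flow analysis of osmotic
shocks applied to fluorophore-loaded yeast cells:

* a hyperosmotic sorbitol shock drives water efflux; the fluorescence decay is
  fit to a single exponential with rate constant ``k`` and the osmotic water
  permeability follows from ``P_f = k (V0/A) / (V_w (osm_out)_inf)``;
* a hyperosmotic glycerol shock drives shrinkage followed by re-swelling as
  glycerol enters; the re-swelling limb is fit by ordinary least squares and
  the glycerol permeability follows from ``P_gly = m (V0/A)`` where ``m`` is
  the linear slope in relative-volume units;
* activation energies come from the slope of Arrhenius plots, ``ln P`` against
  ``1/T``, via ``E_a = -slope * R``.

All permeabilities are in cm s^-1, rates in s^-1, energies in kcal mol^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .constants import (
    DEFAULT_V0_OVER_A,
    OSMOLAR_TO_MOL_PER_CM3,
    R_KCAL,
    VW_WATER,
    celsius_to_kelvin,
)
from .errors import (
    FitDegenerateError,
    FitFailureError,
    InsufficientDesignError,
    InvalidComparisonError,
    InvalidConditionsError,
    InvalidParameterError,
    NoReswellingError,
    WindowError,
)

__all__ = [
    "ShockTrace",
    "CellGeometry",
    "ShockConditions",
    "RateFit",
    "SlopeFit",
    "PermeabilityEstimate",
    "ArrheniusResult",
    "StrainComparison",
    "fit_shrinkage_rate",
    "water_permeability",
    "fit_reswelling_slope",
    "glycerol_permeability",
    "activation_energy",
    "percent_reduction",
    "compare_strains",
    "run_kinetics_pipeline",
    "shrinkage_rate_constant",
    "reswelling_slope_constant",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CellGeometry:
    """Single representative cell geometry.

    ``v0_over_a`` is the initial volume-to-area ratio V0/A in cm,
    ``v_w`` the molar volume of water in cm^3 mol^-1, and
    ``active_fraction`` the osmotically active fraction of the cell volume.
    """

    v0_over_a: float = DEFAULT_V0_OVER_A
    v_w: float = VW_WATER
    active_fraction: float = 1.0

    def __post_init__(self):
        if self.v0_over_a <= 0 or self.v_w <= 0:
            raise InvalidParameterError("geometry parameters must be positive")
        if not (0.0 < self.active_fraction <= 1.0):
            raise InvalidParameterError("active_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ShockConditions:
    """Osmolarities (osmol L^-1) before and after the shock."""

    osm_in_initial: float = 1.4
    osm_out_final: float = 2.1
    shock_solute: str = "sorbitol"

    def __post_init__(self):
        if self.osm_in_initial <= 0 or self.osm_out_final <= 0:
            raise InvalidConditionsError("osmolarities must be positive")
        if self.osm_out_final <= self.osm_in_initial:
            raise InvalidConditionsError(
                "hyperosmotic shock requires osm_out_final > osm_in_initial"
            )
        if self.shock_solute not in ("sorbitol", "glycerol"):
            raise InvalidConditionsError(
                f"unknown shock solute {self.shock_solute!r}"
            )

    @property
    def osm_out_mol_cm3(self) -> float:
        return self.osm_out_final * OSMOLAR_TO_MOL_PER_CM3

    @property
    def osm_in_mol_cm3(self) -> float:
        return self.osm_in_initial * OSMOLAR_TO_MOL_PER_CM3

    @property
    def equilibrium_relative_volume(self) -> float:
        """Relative volume at impermeant-solute equilibrium (active fraction 1)."""
        return self.osm_in_initial / self.osm_out_final


@dataclass
class ShockTrace:
    """One stopped-flow time series.

    ``signal`` is the normalized fluorescence; the generator's linear
    transduction ``F = baseline + span * v`` is recorded so estimators can map
    signal slopes back to relative-volume units.
    """

    time: np.ndarray
    signal: np.ndarray
    temperature: float
    shock_kind: str  # "water" | "glycerol"
    conditions: ShockConditions
    signal_baseline: float = 0.0
    signal_span: float = 1.0
    strain: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 10:
            raise InvalidParameterError("trace needs at least 10 samples")
        if self.time.size != self.signal.size:
            raise InvalidParameterError("time and signal lengths differ")
        if self.time[0] != 0.0:
            raise InvalidParameterError("time must start at 0")
        if not np.all(np.diff(self.time) > 0):
            raise InvalidParameterError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.signal))):
            raise InvalidParameterError("trace contains non-finite values")
        if self.shock_kind not in ("water", "glycerol"):
            raise InvalidParameterError(f"unknown shock kind {self.shock_kind!r}")
        if self.signal_span == 0:
            raise InvalidParameterError("signal_span must be nonzero")

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    def relative_volume(self) -> np.ndarray:
        """Invert the linear transduction back to relative volume."""
        return (self.signal - self.signal_baseline) / self.signal_span


@dataclass(frozen=True)
class RateFit:
    """Single-exponential fit ``signal = baseline + amplitude * exp(-k t)``."""

    k: float
    amplitude: float
    baseline: float
    rmse: float


@dataclass(frozen=True)
class SlopeFit:
    """Linear fit of the re-swelling limb; ``m`` is in relative-volume s^-1."""

    m: float
    window: tuple[int, int]
    r2: float


@dataclass(frozen=True)
class PermeabilityEstimate:
    kind: str  # "Pf" | "Pgly"
    value: float  # cm s^-1
    sd: float = 0.0
    n: int = 1
    temperature: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("Pf", "Pgly"):
            raise InvalidParameterError(f"unknown estimate kind {self.kind!r}")
        if self.n < 1:
            raise InvalidParameterError("n must be >= 1")
        if self.value < 0 and "reverse_flux" not in self.flags:
            raise InvalidParameterError("negative permeability without reverse_flux flag")


@dataclass(frozen=True)
class ArrheniusResult:
    ea: float  # kcal mol^-1
    ln_prefactor: float
    r2: float
    points: tuple[tuple[float, float], ...]  # (temperature K, permeability cm/s)

    def permeability_at(self, t_celsius: float) -> float:
        """Back-substitute the fitted line at a given temperature."""
        return math.exp(
            self.ln_prefactor - self.ea / R_KCAL / celsius_to_kelvin(t_celsius)
        )


@dataclass(frozen=True)
class StrainComparison:
    statistic: float
    p_value: float
    significance_label: str  # "ns" | "**" | "***"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidParameterError("p_value outside [0, 1]")


# --------------------------------------------------------------------------
# forward relations shared with the generator
# --------------------------------------------------------------------------


def shrinkage_rate_constant(
    pf: float, geometry: CellGeometry, conditions: ShockConditions
) -> float:
    """Rate constant implied by ``P_f = k (V0/A) / (V_w (osm_out)_inf)``."""
    return pf * geometry.v_w * conditions.osm_out_mol_cm3 / geometry.v0_over_a


def reswelling_slope_constant(pgly: float, geometry: CellGeometry) -> float:
    """Relative-volume slope implied by ``P_gly = m (V0/A)``."""
    return pgly / geometry.v0_over_a


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------


def _noise_floor(signal: np.ndarray) -> float:
    """Robust per-sample noise scale from first differences."""
    d = np.diff(signal)
    if d.size == 0:
        return 0.0
    return float(np.std(d) / math.sqrt(2.0))


def _smoothed(signal: np.ndarray, frac: float) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d

    w = max(3, int(round(frac * signal.size)))
    return uniform_filter1d(signal, size=w, mode="nearest")


def fit_shrinkage_rate(trace: ShockTrace, smooth_frac: float = 0.05) -> RateFit:
    """Fit the shrinkage phase to ``baseline + amplitude * exp(-k t)``.

    For glycerol shocks only the samples up to the (smoothed) volume minimum
    are used, since re-swelling violates the single-exponential form.  The
    initial rate guess comes from a log-linearized fit of the first third of
    the decay; the baseline guess is the last sample of the fitted segment.
    """
    t = trace.time
    s = trace.signal
    if trace.shock_kind == "glycerol":
        sm = _smoothed(trace.relative_volume(), smooth_frac)
        imin = int(np.argmin(sm))
        if imin >= 10:
            t, s = t[: imin + 1], s[: imin + 1]

    amp0 = float(s[0] - s[-1])
    sigma = _noise_floor(s)
    if abs(amp0) <= max(5.0 * sigma, 1e-12):
        raise FitDegenerateError(
            f"no resolvable decay: amplitude {amp0:.3g} vs noise floor {sigma:.3g}"
        )

    base0 = float(s[-1])
    # log-linearize the first third, guarding against non-positive residuals
    n3 = max(5, s.size // 3)
    resid = (s[:n3] - base0) * np.sign(amp0)
    mask = resid > max(sigma, 1e-15)
    if mask.sum() >= 3:
        slope, _ = np.polyfit(t[:n3][mask], np.log(resid[mask]), 1)
        k0 = max(-float(slope), 1e-6)
    else:
        k0 = 3.0 / max(float(t[-1]), 1e-12)

    def model(tt, baseline, amplitude, k):
        return baseline + amplitude * np.exp(-k * tt)

    try:
        popt, _ = optimize.curve_fit(
            model, t, s, p0=[base0, amp0, k0], maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitFailureError(f"exponential fit did not converge: {exc}") from exc

    baseline, amplitude, k = (float(x) for x in popt)
    rmse = float(np.sqrt(np.mean((model(t, *popt) - s) ** 2)))
    if k <= 0:
        raise FitDegenerateError(f"fitted rate non-positive (k={k:.3g})")
    return RateFit(k=k, amplitude=amplitude, baseline=baseline, rmse=rmse)


def water_permeability(
    fit: RateFit,
    geometry: CellGeometry,
    conditions: ShockConditions,
    temperature: float | None = None,
) -> PermeabilityEstimate:
    """``P_f = k (V0/A) / (V_w (osm_out)_inf)`` with osmolarity in mol cm^-3."""
    if conditions.osm_out_final <= 0:
        raise InvalidConditionsError("osm_out_final must be positive")
    pf = fit.k * geometry.v0_over_a / (geometry.v_w * conditions.osm_out_mol_cm3)
    return PermeabilityEstimate(kind="Pf", value=pf, temperature=temperature)


def fit_reswelling_slope(
    trace: ShockTrace,
    smooth_frac: float = 0.05,
    guard_frac: float = 0.02,
    window_frac: float = 0.40,
) -> SlopeFit:
    """Fit the linear re-swelling limb of a glycerol-shock trace.

    The global minimum of a moving-average copy of the relative-volume series
    locates the turning point; the raw series is then regressed over a
    fixed-fraction window starting one guard gap past the minimum.  Working in
    relative-volume units (the exact inverse of the generator's linear
    transduction) makes the slope independent of the signal scale and sign.

    A trace whose post-minimum rise is smaller than both the smoothed noise
    floor and 5% of the shrinkage amplitude is rejected as having no
    re-swelling phase (e.g. a water-only channel under a glycerol shock).
    """
    v = trace.relative_volume()
    n = v.size
    w = max(3, int(round(smooth_frac * n)))
    sm = _smoothed(v, smooth_frac)
    imin = int(np.argmin(sm))
    if imin < 2 or imin > n - max(5, w):
        raise NoReswellingError("no interior minimum: trace is monotone")
    tail = sm[min(n - 1, imin + max(1, (n - imin) // 4)):]
    rise = float(np.max(tail) - sm[imin]) if tail.size else 0.0
    sigma = _noise_floor(v)
    amp = float(np.max(sm) - np.min(sm))
    if rise <= max(4.0 * sigma / math.sqrt(w), 0.05 * amp, 1e-15):
        raise NoReswellingError("signal does not rise after its minimum")

    i0 = imin + max(1, int(round(guard_frac * n)))
    i1 = min(n, i0 + int(round(window_frac * n)))
    if i1 - i0 < 5:
        raise WindowError(f"regression window [{i0}, {i1}) shorter than 5 samples")

    tt, vv = trace.time[i0:i1], v[i0:i1]
    slope, intercept = np.polyfit(tt, vv, 1)
    pred = slope * tt + intercept
    sst = float(np.sum((vv - vv.mean()) ** 2))
    r2 = 1.0 - float(np.sum((vv - pred) ** 2)) / sst if sst > 0 else 1.0
    return SlopeFit(m=float(slope), window=(int(i0), int(i1)), r2=r2)


def glycerol_permeability(
    fit: SlopeFit, geometry: CellGeometry, temperature: float | None = None
) -> PermeabilityEstimate:
    """``P_gly = m (V0/A)``; a negative slope is flagged, not raised."""
    if not math.isfinite(fit.m):
        raise InvalidParameterError("slope must be finite")
    value = fit.m * geometry.v0_over_a
    flags = ("reverse_flux",) if value < 0 else ()
    return PermeabilityEstimate(
        kind="Pgly", value=value, temperature=temperature, flags=flags
    )


def activation_energy(
    points: list[tuple[float, PermeabilityEstimate]]
) -> ArrheniusResult:
    """OLS of ``ln P`` against ``1/T`` (kelvin); ``E_a = -slope * R``."""
    if len(points) < 3:
        raise InsufficientDesignError("activation energy needs >= 3 temperatures")
    temps_c = [t for t, _ in points]
    if len(set(temps_c)) < 3:
        raise InsufficientDesignError("temperatures must include >= 3 distinct values")
    values = [est.value for _, est in points]
    if any(v <= 0 for v in values):
        raise InvalidParameterError("all permeabilities must be positive")
    inv_t = np.array([1.0 / celsius_to_kelvin(t) for t in temps_c])
    ln_p = np.log(values)
    res = stats.linregress(inv_t, ln_p)
    ea = -float(res.slope) * R_KCAL
    pts = tuple(
        (celsius_to_kelvin(t), float(est.value)) for t, est in points
    )
    return ArrheniusResult(
        ea=ea,
        ln_prefactor=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        points=pts,
    )


def percent_reduction(
    native: PermeabilityEstimate, mutant: PermeabilityEstimate
) -> float:
    """Percent loss of permeability in the mutant relative to the native."""
    if native.kind != mutant.kind:
        raise InvalidComparisonError(
            f"cannot compare {native.kind} with {mutant.kind}"
        )
    if native.value <= 0:
        raise InvalidParameterError("native permeability must be positive")
    return 100.0 * (native.value - mutant.value) / native.value


def compare_strains(
    replicates_a: list[float], replicates_b: list[float]
) -> StrainComparison:
    """Two-sided Welch t-test with the conventional significance labels."""
    a = np.asarray(replicates_a, dtype=float)
    b = np.asarray(replicates_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDesignError("each group needs >= 3 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return StrainComparison(statistic=0.0, p_value=1.0, significance_label="ns")
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    if math.isnan(p):  # zero variance in both groups, unequal means
        p = 0.0
    label = "***" if p < 0.001 else "**" if p < 0.01 else "ns"
    stat = float(res.statistic)
    if math.isnan(stat):
        stat = math.inf if a.mean() != b.mean() else 0.0
    return StrainComparison(statistic=stat, p_value=p, significance_label=label)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------


def _estimate_one(trace: ShockTrace, geometry: CellGeometry) -> PermeabilityEstimate:
    if trace.shock_kind == "water":
        fit = fit_shrinkage_rate(trace)
        return water_permeability(fit, geometry, trace.conditions, trace.temperature)
    fit = fit_reswelling_slope(trace)
    return glycerol_permeability(fit, geometry, trace.temperature)


def run_kinetics_pipeline(
    traces: list[ShockTrace],
    geometry: CellGeometry | None = None,
    reference_temperature: float = 23.0,
) -> dict:
    """Aggregate traces into per-strain permeability / Arrhenius report.

    Traces are grouped by ``(strain, shock_kind)``; replicates at each
    temperature are averaged (mean +/- SD), the reference-temperature group
    yields the headline permeability, and temperature series with at least
    three distinct temperatures yield activation energies.  Glycerol traces
    without a re-swelling limb are counted, not fatal.  The report is a plain
    JSON-serializable dict, deterministic for fixed inputs.
    """
    geometry = geometry or CellGeometry()
    groups: dict[tuple[str, str], dict[float, list[float]]] = {}
    no_reswell: dict[tuple[str, str], int] = {}
    warnings: list[str] = []

    for trace in traces:
        key = (trace.strain or "unlabeled", trace.shock_kind)
        try:
            est = _estimate_one(trace, geometry)
        except NoReswellingError:
            no_reswell[key] = no_reswell.get(key, 0) + 1
            continue
        groups.setdefault(key, {}).setdefault(float(trace.temperature), []).append(
            est.value
        )

    report: dict = {"strains": {}, "warnings": warnings}
    kind_name = {"water": "Pf", "glycerol": "Pgly"}
    for (strain, shock_kind) in sorted(set(groups) | set(no_reswell)):
        block = report["strains"].setdefault(strain, {})
        key = (strain, shock_kind)
        by_temp = groups.get(key, {})
        entry: dict = {
            "kind": kind_name[shock_kind],
            "by_temperature": {},
            "no_reswelling_traces": no_reswell.get(key, 0),
        }
        for temp in sorted(by_temp):
            vals = np.array(by_temp[temp])
            entry["by_temperature"][f"{temp:g}"] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        if float(reference_temperature) in by_temp:
            vals = np.array(by_temp[float(reference_temperature)])
            entry["permeability"] = {
                "value": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
                "temperature": reference_temperature,
            }
        positive = {t: np.mean(v) for t, v in by_temp.items() if np.mean(v) > 0}
        if len(positive) >= 3:
            pts = [
                (t, PermeabilityEstimate(kind=kind_name[shock_kind],
                                         value=float(v), temperature=t))
                for t, v in sorted(positive.items())
            ]
            arr = activation_energy(pts)
            entry["activation_energy"] = {
                "ea": arr.ea,
                "ln_prefactor": arr.ln_prefactor,
                "r2": arr.r2,
            }
        else:
            warnings.append(
                f"{strain}/{shock_kind}: temperature coverage too sparse for E_a"
            )
        block[shock_kind] = entry

    # pairwise strain comparison at the reference temperature
    report["comparisons"] = {}
    for shock_kind in ("water", "glycerol"):
        strains = [
            s
            for (s, k2) in sorted(groups)
            if k2 == shock_kind
            and float(reference_temperature) in groups[(s, k2)]
            and len(groups[(s, k2)][float(reference_temperature)]) >= 3
        ]
        for i, sa in enumerate(strains):
            for sb in strains[i + 1:]:
                cmp_ = compare_strains(
                    groups[(sa, shock_kind)][float(reference_temperature)],
                    groups[(sb, shock_kind)][float(reference_temperature)],
                )
                report["comparisons"][f"{sa}|{sb}|{shock_kind}"] = {
                    "statistic": cmp_.statistic,
                    "p_value": cmp_.p_value,
                    "label": cmp_.significance_label,
                }
    return report


def scaled_trace(trace: ShockTrace, c: float) -> ShockTrace:
    """Return a copy with all signal values (and transduction) scaled by c>0."""
    if c <= 0:
        raise InvalidParameterError("scale factor must be positive")
    return replace(
        trace,
        signal=trace.signal * c,
        signal_baseline=trace.signal_baseline * c,
        signal_span=trace.signal_span * c,
    )
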
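"""Single-cell Fick-Nernst-Planck model of lysosomal drug accumulation.

A drug diffuses from the external medium into the cytosol and from there
into two organelles, the lysosome (acidic, slightly positive inside) and the
mitochondrion (alkaline, strongly negative inside). In every compartment the
compound speciates instantaneously according to its pKa values
(Henderson-Hasselbalch); the neutral microspecies crosses membranes readily,
ionic microspecies cross poorly (a fixed log-offset on the permeability) and
are additionally dragged or repelled by the membrane potential
(Goldman/Nernst-Planck flux). A fraction of each compartment's content is
sorbed to lipids and unavailable for diffusion. Weak bases are therefore
trapped in the acidic lysosome ("ion trapping"): the neutral form enters,
is protonated at pH ~5, and the charged form cannot leave.

Because speciation fractions are fixed per compartment, the governing
equations are linear in the total concentrations, so the steady state can be
computed exactly by solving a linear system (:meth:`CellModel.steady_state`);
the time course is integrated with an adaptive, stiff-capable solver.

Four speciation variants are supported: ``monoacid``, ``monobase``,
``bibase`` and ``zwitter``. Compounds without a pKa in the relevant range
use the monoacid variant with pKa 15 (i.e. effectively always neutral).

All physical constants and preset parameters are named attributes of
:class:`CellModelParams` and can be overridden or loaded from YAML. The
defaults describe a generic mammalian cell in slightly alkaline medium;
an alternative preset with external pH 7.5 (bicarbonate-buffered DMEM)
is provided.

Units: concentrations in µM, times in minutes, potentials in mV,
temperature in K. Permeabilities are folded with the membrane
area-to-volume ratios into first-order rate coefficients (1/min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, NumericError
from .descriptors import (
    IonizationCategory,
    RELEVANT_ACID_PKA,
    RELEVANT_BASE_PKA,
    classify_ionization,
)

FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.31446  # J/(mol K)

#: species label -> formal charge; the zwitterion is net-neutral but crosses
#: membranes with the (low) ionic permeability
SPECIES = (("neutral", 0), ("cation1", 1), ("cation2", 2), ("anion1", -1), ("zwitterion", 0))

VARIANTS = ("monoacid", "monobase", "bibase", "zwitter")


@dataclass
class SpeciationProfile:
    """Ionization variant of a compound plus the pKa values it requires."""

    variant: str
    pka_base1: float | None = None
    pka_base2: float | None = None
    pka_acid: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown speciation variant {self.variant!r}")
        need = {
            "monoacid": ("pka_acid",),
            "monobase": ("pka_base1",),
            "bibase": ("pka_base1", "pka_base2"),
            "zwitter": ("pka_base1", "pka_acid"),
        }[self.variant]
        missing = [n for n in need if getattr(self, n) is None]
        if missing:
            raise ConfigurationError(
                f"variant {self.variant!r} requires {', '.join(missing)}"
            )
        if (
            self.variant == "bibase"
            and self.pka_base1 is not None
            and self.pka_base2 is not None
            and self.pka_base1 < self.pka_base2
        ):
            raise ConfigurationError("bibase requires pka_base1 >= pka_base2")

    @classmethod
    def from_pkas(
        cls,
        pka_base1: float | None,
        pka_base2: float | None,
        pka_acid: float | None,
    ) -> "SpeciationProfile":
        """Select the model variant from (pre-imputation) pKa values.

        Mirrors the ionization-category rules; compounds without a pKa in
        the relevant range fall back to the monoacid variant with pKa 15,
        which behaves as an always-neutral compound.
        """
        cat = classify_ionization(pka_base1, pka_base2, pka_acid)
        if cat is IonizationCategory.MONOBASE:
            base = pka_base1 if (pka_base1 or -99) >= RELEVANT_BASE_PKA else pka_base2
            return cls("monobase", pka_base1=base)
        if cat is IonizationCategory.BIBASE:
            return cls("bibase", pka_base1=pka_base1, pka_base2=pka_base2)
        if cat is IonizationCategory.ZWITTER:
            return cls("zwitter", pka_base1=pka_base1, pka_acid=pka_acid)
        if cat is IonizationCategory.ACID:
            return cls("monoacid", pka_acid=pka_acid)
        return cls("monoacid", pka_acid=15.0)


def fraction_speciation(profile: SpeciationProfile, ph: float) -> dict[str, float]:
    """Henderson-Hasselbalch microspecies fractions at the given pH.

    Returns fractions for all five species labels (zero where the variant
    does not form the species); they sum to 1. For the zwitter variant the
    basic and acidic sites dissociate independently.
    """
    if not 0.0 <= ph <= 14.0:
        raise ConfigurationError(f"pH must be in [0, 14], got {ph}")
    f = {name: 0.0 for name, _ in SPECIES}
    if profile.variant == "monobase":
        r = 10.0 ** (profile.pka_base1 - ph)
        f["neutral"] = 1.0 / (1.0 + r)
        f["cation1"] = r / (1.0 + r)
    elif profile.variant == "bibase":
        r1 = 10.0 ** (profile.pka_base1 - ph)
        r2 = 10.0 ** (profile.pka_base1 + profile.pka_base2 - 2.0 * ph)
        d = 1.0 + r1 + r2
        f["neutral"] = 1.0 / d
        f["cation1"] = r1 / d
        f["cation2"] = r2 / d
    elif profile.variant == "monoacid":
        ra = 10.0 ** (ph - profile.pka_acid)
        f["neutral"] = 1.0 / (1.0 + ra)
        f["anion1"] = ra / (1.0 + ra)
    else:  # zwitter
        rb = 10.0 ** (profile.pka_base1 - ph)
        ra = 10.0 ** (ph - profile.pka_acid)
        fb = rb / (1.0 + rb)  # protonated base
        fa = ra / (1.0 + ra)  # deprotonated acid
        f["neutral"] = (1.0 - fb) * (1.0 - fa)
        f["cation1"] = fb * (1.0 - fa)
        f["anion1"] = (1.0 - fb) * fa
        f["zwitterion"] = fb * fa
    return f


@dataclass
class CompartmentParams:
    """One compartment: pH, relative volume, membrane potential of its
    bounding membrane (inside relative to the adjacent outer compartment,
    mV), membrane area-to-volume ratio (relative units folded into the
    permeability scale) and lipid volume fraction available for sorption."""

    ph: float
    volume: float
    potential_mv: float = 0.0
    area_per_volume: float = 1.0
    lipid_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ConfigurationError("compartment volume must be > 0")
        if not 0.0 <= self.ph <= 14.0:
            raise ConfigurationError(f"pH must be in [0, 14], got {self.ph}")


@dataclass
class CellModelParams:
    """Full parameter set of the four-compartment cell model.

    ``perm_scale`` converts ``10**(perm_logp_coeff * min(logp, perm_logp_cap))``
    into a neutral-species rate coefficient; the cap models the
    unstirred-layer limit of membrane permeation at very high lipophilicity.
    Ionic permeability is the neutral permeability times
    ``10**ionic_log_offset``. Lipid sorption uses
    ``K = lipid_fraction * 10**(sorption_logp_coeff * logp)`` for the neutral
    species and a fixed fraction of that for ions; sorption has no cap,
    which is what makes highly lipophilic compounds accumulate slowly (large
    depot, bounded flux).
    """

    external: CompartmentParams = field(
        default_factory=lambda: CompartmentParams(ph=7.4, volume=1000.0)
    )
    cytosol: CompartmentParams = field(
        default_factory=lambda: CompartmentParams(
            ph=7.2, volume=1.0, potential_mv=-70.0, area_per_volume=6.0, lipid_fraction=0.05
        )
    )
    lysosome: CompartmentParams = field(
        default_factory=lambda: CompartmentParams(
            ph=5.0, volume=0.01, potential_mv=10.0, area_per_volume=100.0, lipid_fraction=0.05
        )
    )
    mitochondrion: CompartmentParams = field(
        default_factory=lambda: CompartmentParams(
            ph=8.0, volume=0.05, potential_mv=-160.0, area_per_volume=50.0, lipid_fraction=0.05
        )
    )
    temperature_k: float = 310.15
    perm_scale: float = 0.1
    perm_logp_coeff: float = 1.0
    perm_logp_cap: float = 4.0
    ionic_log_offset: float = -3.5
    sorption_logp_coeff: float = 1.0
    ion_sorption_factor: float = 0.1
    external_conc_um: float = 10.0
    closed_system: bool = False

    @classmethod
    def default(cls) -> "CellModelParams":
        return cls()

    @classmethod
    def dmem(cls) -> "CellModelParams":
        """Preset for bicarbonate-buffered DMEM medium (external pH 7.5)."""
        p = cls()
        p.external = replace(p.external, ph=7.5)
        return p

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CellModelParams":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        comps = {
            name: CompartmentParams(**raw.pop(name))
            for name in ("external", "cytosol", "lysosome", "mitochondrion")
            if name in raw
        }
        return cls(**comps, **raw)


@dataclass
class AccumulationResult:
    """Simulated time course plus the analytic steady state.

    ``concentrations`` maps compartment name to the *total* (free + sorbed,
    all species) concentration trace in µM. ``steady_state`` holds the
    analytic fixed-external steady-state totals; ``lysosome_ratio`` is the
    steady-state lysosome/external total concentration ratio.
    """

    time_min: np.ndarray
    concentrations: dict[str, np.ndarray]
    steady_state: dict[str, float]
    lysosome_ratio: float


_INTERNAL = ("cytosol", "lysosome", "mitochondrion")
#: membranes as (outer, inner); the potential is stored on the inner side
_MEMBRANES = (("external", "cytosol"), ("cytosol", "lysosome"), ("cytosol", "mitochondrion"))


class CellModel:
    """Linear compartment model for one compound.

    Precomputes speciation fractions, free-water fractions and per-membrane
    rate coefficients; exposes the analytic steady state and the ODE right-
    hand side used by :func:`simulate_accumulation`.
    """

    def __init__(self, profile: SpeciationProfile, params: CellModelParams, logp: float):
        self.profile = profile
        self.params = params
        self.logp = float(logp)
        self._build()

    # -- construction -----------------------------------------------------
    def _compartment(self, name: str) -> CompartmentParams:
        return getattr(self.params, name)

    def _perm_neutral(self) -> float:
        p = self.params
        eff = p.perm_logp_coeff * min(self.logp, p.perm_logp_cap)
        return p.perm_scale * 10.0**eff

    def _water_fraction(self, name: str, fractions: Mapping[str, float]) -> float:
        p = self.params
        comp = self._compartment(name)
        k_neutral = 10.0 ** (p.sorption_logp_coeff * self.logp)
        sorbed = 0.0
        for species, z in SPECIES:
            k = k_neutral if (z == 0 and species == "neutral") else k_neutral * p.ion_sorption_factor
            sorbed += fractions[species] * k
        return 1.0 / (1.0 + comp.lipid_fraction * sorbed)

    def _build(self) -> None:
        p = self.params
        names = ("external",) + _INTERNAL
        self.names = names
        frac = {n: fraction_speciation(self.profile, self._compartment(n).ph) for n in names}
        wf = {n: self._water_fraction(n, frac[n]) for n in names}
        self.fractions = frac
        self.water_fraction = wf

        pn = self._perm_neutral()
        pion = pn * 10.0**p.ionic_log_offset
        rt = GAS_CONSTANT * p.temperature_k

        n_int = len(_INTERNAL)
        idx = {n: i for i, n in enumerate(_INTERNAL)}
        a = np.zeros((n_int, n_int))
        b = np.zeros(n_int)
        a_full = np.zeros((n_int + 1, n_int + 1))  # closed system, external = index 0

        for outer, inner in _MEMBRANES:
            comp_in = self._compartment(inner)
            av = comp_in.area_per_volume
            e_volt = comp_in.potential_mv / 1000.0
            alpha = beta = 0.0  # flux = alpha*c_out_free - beta*c_in_free, per species
            coeff_out = 0.0  # d(inner)/dt contribution per unit total outer conc
            coeff_in = 0.0
            for species, z in SPECIES:
                perm = pn if species == "neutral" else pion
                if z == 0 or e_volt == 0.0:
                    alpha = beta = perm
                else:
                    nz = z * FARADAY * e_volt / rt
                    ex = math.exp(nz)
                    alpha = perm * nz / (ex - 1.0)
                    beta = alpha * ex
                coeff_out += alpha * wf[outer] * frac[outer][species]
                coeff_in += beta * wf[inner] * frac[inner][species]
            i = idx[inner]
            vol_in = comp_in.volume
            vol_out = self._compartment(outer).volume
            # open (fixed-external) system
            a[i, i] -= av * coeff_in
            if outer == "external":
                b[i] += av * coeff_out * p.external_conc_um
            else:
                a[i, idx[outer]] += av * coeff_out
                a[idx[outer], i] += av * (vol_in / vol_out) * coeff_in
                a[idx[outer], idx[outer]] -= av * (vol_in / vol_out) * coeff_out
            # closed system (external is a finite reservoir, state 0)
            io, ii = (0 if outer == "external" else idx[outer] + 1), idx[inner] + 1
            a_full[ii, ii] -= av * coeff_in
            a_full[ii, io] += av * coeff_out
            a_full[io, ii] += av * (vol_in / vol_out) * coeff_in
            a_full[io, io] -= av * (vol_in / vol_out) * coeff_out

        self._a, self._b, self._a_full = a, b, a_full

    # -- queries ----------------------------------------------------------
    def steady_state(self) -> dict[str, float]:
        """Analytic steady-state total concentrations (fixed external)."""
        css = np.linalg.solve(self._a, -self._b)
        if (css < -1e-9 * self.params.external_conc_um).any():
            raise NumericError(f"negative steady-state concentration: {css}")
        out = {"external": self.params.external_conc_um}
        out.update({n: float(css[i]) for i, n in enumerate(_INTERNAL)})
        return out

    def lysosome_ratio(self) -> float:
        """Steady-state lysosome/external total concentration ratio."""
        ss = self.steady_state()
        return ss["lysosome"] / ss["external"]

    def rhs(self, t, y):
        if self.params.closed_system:
            return self._a_full @ y
        return self._a @ y + self._b

    def jacobian(self, t, y):
        return self._a_full if self.params.closed_system else self._a


def simulate_accumulation(
    profile: SpeciationProfile,
    params: CellModelParams,
    logp: float,
    duration_min: float,
    n_points: int = 200,
    rtol: float = 1e-8,
) -> AccumulationResult:
    """Integrate the accumulation time course over ``duration_min`` minutes.

    Internal concentrations start at zero; the external medium holds
    ``params.external_conc_um`` (fixed, or as a finite reservoir when
    ``params.closed_system``). Uses LSODA (adaptive, stiff-capable) with the
    exact constant Jacobian.
    """
    if duration_min <= 0:
        raise ConfigurationError("duration must be > 0")
    model = CellModel(profile, params, logp)
    if params.closed_system:
        y0 = np.array([params.external_conc_um] + [0.0] * len(_INTERNAL))
    else:
        y0 = np.zeros(len(_INTERNAL))
    t_eval = np.linspace(0.0, duration_min, n_points)
    atol = rtol * max(params.external_conc_um, 1.0) * 1e-4
    sol = solve_ivp(
        model.rhs,
        (0.0, duration_min),
        y0,
        method="LSODA",
        jac=model.jacobian,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericError(f"integrator failure: {sol.message}")
    if (sol.y < -1e-6 * max(params.external_conc_um, 1.0)).any():
        raise NumericError("negative concentration beyond tolerance")
    if params.closed_system:
        conc = {"external": sol.y[0]}
        conc.update({n: sol.y[i + 1] for i, n in enumerate(_INTERNAL)})
    else:
        conc = {"external": np.full_like(sol.t, params.external_conc_um)}
        conc.update({n: sol.y[i] for i, n in enumerate(_INTERNAL)})
    ss = model.steady_state()
    return AccumulationResult(
        time_min=sol.t,
        concentrations=conc,
        steady_state=ss,
        lysosome_ratio=ss["lysosome"] / params.external_conc_um,
    )


def required_incubation(
    profile: SpeciationProfile,
    params: CellModelParams,
    logp: float,
    fraction: float = 0.95,
    cap_min: float = 1e5,
) -> float:
    """Minutes until the lysosomal concentration reaches ``fraction`` of its
    steady state; ``math.inf`` when the cap is exceeded.

    The default fraction 0.95 operationalises a "minimal but still
    sufficient" incubation; compare the result against the standard 30-min
    screening window to flag slow accumulators.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("fraction must be in (0, 1)")
    if params.closed_system:
        raise ConfigurationError("required_incubation assumes a fixed external medium")
    model = CellModel(profile, params, logp)
    target = fraction * model.steady_state()["lysosome"]
    i_lys = _INTERNAL.index("lysosome")

    def hit(t, y):
        return y[i_lys] - target

    hit.terminal = True
    hit.direction = 1
    sol = solve_ivp(
        model.rhs,
        (0.0, cap_min),
        np.zeros(len(_INTERNAL)),
        method="LSODA",
        jac=model.jacobian,
        events=hit,
        rtol=1e-8,
        atol=1e-12 * max(params.external_conc_um, 1.0),
    )
    if not sol.success:
        raise NumericError(f"integrator failure: {sol.message}")
    if sol.t_events[0].size:
        return float(sol.t_events[0][0])
    return math.inf


def clys_descriptor(
    profile: SpeciationProfile, params: CellModelParams, logp: float
) -> float:
    """Steady-state lysosomal total concentration (µM) -- the CLys descriptor."""
    return CellModel(profile, params, logp).steady_state()["lysosome"]
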
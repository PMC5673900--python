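"""Barite saturation state and remineralization titration.

A deliberately minimal speciation model for dilute fresh water: free-ion
concentrations equal totals (no ion pairing), single-ion activity
coefficients come from the Davies equation with a temperature-dependent
A parameter, and the barite solubility product carries a mild linear
temperature dependence calibrated against the ambient Lake Superior
solution (see the preset file). The saturation index is

    Omega_barite = {Ba2+} {SO4 2-} / Ksp(T) = gamma2^2 [Ba][SO4] / Ksp(T)

The titration experiment asks how much organic matter must be
remineralized inside a particle microenvironment, releasing Ba and
sulfate at fixed stoichiometric ratios to phosphorus (Ba:P in mM:M, S:P
in M:M), before the microenvironment reaches barite saturation. Ions are
added to 1 L of ambient solution, charge-balanced by inert monovalent
counter-ions so that ionic strength (and hence the activity
coefficients) evolves during the titration; the saturation point is
found by bracketing and bisection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .profiles_io import ValidationError

log = logging.getLogger("pelagicbarite")


@dataclass
class Ion:
    name: str
    charge: int
    mol_per_L: float


@dataclass
class ThermoPreset:
    """Barite Ksp(T) and Davies-equation constants.

    ``log10_ksp_25C`` plus a linear slope gives a continuous, monotone
    Ksp over 0-30 C; the slope is calibrated so the shipped ambient
    preset evaluates to Omega = 0.02 (see data/lake_superior.yaml for
    the calibration note).
    """

    log10_ksp_25C: float = -9.97
    dlog10_ksp_dT: float = 1.4235e-3
    davies_A_coeffs: tuple[float, float, float] = (0.4913, 6.0e-4, 3.2e-6)
    davies_linear_term: float = 0.3

    def log10_ksp(self, temperature_C: float) -> float:
        return self.log10_ksp_25C + self.dlog10_ksp_dT * (temperature_C - 25.0)

    def ksp(self, temperature_C: float) -> float:
        return 10.0 ** self.log10_ksp(temperature_C)

    def davies_A(self, temperature_C: float) -> float:
        a0, a1, a2 = self.davies_A_coeffs
        return a0 + a1 * temperature_C + a2 * temperature_C**2


@dataclass
class MajorIonSolution:
    """Ambient water chemistry: ion totals (mol/L), temperature, fixed pH."""

    ions: list[Ion]
    temperature_C: float
    pH: float
    name: str = "solution"

    def __post_init__(self) -> None:
        for ion in self.ions:
            if ion.mol_per_L < 0:
                raise ValidationError(f"negative concentration for {ion.name}")

    def concentration(self, name: str) -> float:
        for ion in self.ions:
            if ion.name == name:
                return ion.mol_per_L
        return 0.0

    def with_concentration(self, name: str, mol_per_L: float) -> "MajorIonSolution":
        ions = [replace(i) for i in self.ions]
        for ion in ions:
            if ion.name == name:
                ion.mol_per_L = mol_per_L
                break
        else:
            raise KeyError(name)
        return MajorIonSolution(ions, self.temperature_C, self.pH, self.name)

    def charge_imbalance(self) -> float:
        """|Σ c z| as a fraction of Σ c |z|."""
        net = sum(i.mol_per_L * i.charge for i in self.ions)
        total = sum(i.mol_per_L * abs(i.charge) for i in self.ions)
        return abs(net) / total if total else 0.0


def load_preset(source=None) -> tuple[MajorIonSolution, ThermoPreset]:
    """Load a solution + thermo preset from YAML.

    ``source`` is a path; omit it for the packaged ambient Lake Superior
    preset. Raises if the preset's charge imbalance exceeds 5%.
    """
    if source is None:
        text = (resources.files("pelagicbarite") / "data" / "lake_superior.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    solution = MajorIonSolution(
        ions=[Ion(d["name"], int(d["charge"]), float(d["mol_per_L"])) for d in raw["ions"]],
        temperature_C=float(raw["temperature_C"]),
        pH=float(raw["pH"]),
        name=raw.get("name", "preset"),
    )
    if solution.charge_imbalance() > 0.05:
        raise ValidationError(
            f"preset {solution.name}: charge imbalance "
            f"{100 * solution.charge_imbalance():.1f}% exceeds 5%"
        )
    t = raw["thermo"]
    thermo = ThermoPreset(
        log10_ksp_25C=float(t["log10_ksp_25C"]),
        dlog10_ksp_dT=float(t["dlog10_ksp_dT"]),
        davies_A_coeffs=tuple(float(c) for c in t["davies_A_coeffs"]),
        davies_linear_term=float(t.get("davies_linear_term", 0.3)),
    )
    return solution, thermo


def ionic_strength(solution: MajorIonSolution) -> float:
    """I = 1/2 Σ c_i z_i^2, in mol/L."""
    return 0.5 * sum(i.mol_per_L * i.charge**2 for i in solution.ions)


def activity_coefficient(
    charge: int, ionic_strength_M: float, temperature_C: float,
    thermo: ThermoPreset | None = None,
) -> float:
    """Davies-equation single-ion activity coefficient.

    log10 gamma = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I). Valid for dilute
    solutions; a warning is logged above I = 0.5 mol/L.
    """
    if ionic_strength_M < 0:
        raise ValidationError("ionic strength must be >= 0")
    if ionic_strength_M > 0.5:
        log.warning("Davies equation outside validity range: I = %.3g mol/L", ionic_strength_M)
    thermo = thermo or ThermoPreset()
    a = thermo.davies_A(temperature_C)
    s = math.sqrt(ionic_strength_M)
    return 10.0 ** (
        -a * charge**2 * (s / (1.0 + s) - thermo.davies_linear_term * ionic_strength_M)
    )


def omega_barite(solution: MajorIonSolution, thermo: ThermoPreset | None = None) -> float:
    """Barite saturation index of a solution (free ions = totals)."""
    thermo = thermo or ThermoPreset()
    I = ionic_strength(solution)
    g2 = activity_coefficient(2, I, solution.temperature_C, thermo)
    ba = solution.concentration("Ba+2")
    so4 = solution.concentration("SO4-2")
    return g2 * g2 * ba * so4 / thermo.ksp(solution.temperature_C)


MODES = ("both", "sulfate_only", "ba_only")


@dataclass
class TitrationScenario:
    """Which remineralization-released ions accumulate, and at what
    stoichiometry (Ba:P in mM:M, S:P in M:M)."""

    mode: str = "both"
    ba_p_mM_M: float = 0.44
    s_p: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.ba_p_mM_M <= 0 or self.s_p <= 0:
            raise ValidationError("stoichiometric ratios must be > 0")

    @property
    def adds_ba(self) -> bool:
        return self.mode in ("both", "ba_only")

    @property
    def adds_sulfate(self) -> bool:
        return self.mode in ("both", "sulfate_only")

    @property
    def ba_p(self) -> float:
        return self.ba_p_mM_M * 1e-3  # mol/mol


@dataclass
class TitrationResult:
    x_p: float  # mol P remineralized per L at saturation
    frac_sulfate_from_remin: float
    frac_ba_from_remin: float
    final_ba: float
    final_sulfate: float
    omega_final: float
    trajectory: pd.DataFrame = field(repr=False)  # columns x_p, omega, ionic_strength
    scenario: TitrationScenario = field(default_factory=TitrationScenario)


def _titrated_omega(
    x: float,
    solution: MajorIonSolution,
    scenario: TitrationScenario,
    thermo: ThermoPreset,
    i0: float,
    gamma_frozen: float | None,
) -> tuple[float, float]:
    """(Omega, I) after remineralizing x mol P/L into the solution."""
    d_ba = scenario.ba_p * x if scenario.adds_ba else 0.0
    d_s = scenario.s_p * x if scenario.adds_sulfate else 0.0
    # each mol of divalent ion arrives with 2 mol of inert monovalent
    # counter-ion: dI = (4 + 2)/2 * dc = 3 dc per divalent addition
    I = i0 + 3.0 * (d_ba + d_s)
    if gamma_frozen is None:
        g2 = activity_coefficient(2, I, solution.temperature_C, thermo)
    else:
        g2 = gamma_frozen
    ba = solution.concentration("Ba+2") + d_ba
    so4 = solution.concentration("SO4-2") + d_s
    return g2 * g2 * ba * so4 / thermo.ksp(solution.temperature_C), I


def titrate_remineralization(
    solution: MajorIonSolution,
    scenario: TitrationScenario | None = None,
    thermo: ThermoPreset | None = None,
    target_omega: float = 1.0,
    freeze_gamma: bool = False,
    rtol: float = 1e-9,
    max_iter: int = 200,
    n_trajectory: int = 50,
) -> TitrationResult:
    """Remineralize organic matter into the solution until barite saturation.

    Finds the smallest x_P >= 0 (mol P per liter) at which Omega reaches
    ``target_omega``, recomputing ionic strength and activity
    coefficients at every trial (or holding gamma at its ambient value
    when ``freeze_gamma`` is set — the closed-form oracle mode). The
    remineralization-derived fraction of each ion is added/(ambient+added).
    """
    scenario = scenario or TitrationScenario()
    thermo = thermo or ThermoPreset()
    i0 = ionic_strength(solution)
    gamma_frozen = (
        activity_coefficient(2, i0, solution.temperature_C, thermo) if freeze_gamma else None
    )

    def omega_of(x: float) -> float:
        return _titrated_omega(x, solution, scenario, thermo, i0, gamma_frozen)[0]

    omega0 = omega_of(0.0)
    if omega0 >= target_omega:
        traj = pd.DataFrame({"x_p": [0.0], "omega": [omega0], "ionic_strength": [i0]})
        return TitrationResult(
            x_p=0.0,
            frac_sulfate_from_remin=0.0,
            frac_ba_from_remin=0.0,
            final_ba=solution.concentration("Ba+2"),
            final_sulfate=solution.concentration("SO4-2"),
            omega_final=omega0,
            trajectory=traj,
            scenario=scenario,
        )
    if scenario.mode == "ba_only" and solution.concentration("SO4-2") == 0.0:
        raise ValidationError("ba_only titration cannot reach saturation with zero sulfate")
    if scenario.mode == "sulfate_only" and solution.concentration("Ba+2") == 0.0:
        raise ValidationError("sulfate_only titration cannot reach saturation with zero Ba")

    # expand the bracket geometrically, then solve
    hi = 1e-6
    for _ in range(max_iter):
        if omega_of(hi) >= target_omega:
            break
        hi *= 2.0
    else:
        raise ValidationError(
            f"target Omega = {target_omega} not reached within bracket expansion "
            f"({max_iter} doublings) in mode {scenario.mode!r}"
        )
    x_sat = brentq(
        lambda x: omega_of(x) - target_omega, 0.0, hi, rtol=rtol, maxiter=max_iter
    )

    d_ba = scenario.ba_p * x_sat if scenario.adds_ba else 0.0
    d_s = scenario.s_p * x_sat if scenario.adds_sulfate else 0.0
    ba0 = solution.concentration("Ba+2")
    s0 = solution.concentration("SO4-2")
    xs = np.linspace(0.0, x_sat, n_trajectory)
    omegas, strengths = zip(
        *(_titrated_omega(x, solution, scenario, thermo, i0, gamma_frozen) for x in xs)
    )
    return TitrationResult(
        x_p=float(x_sat),
        frac_sulfate_from_remin=d_s / (s0 + d_s) if d_s else 0.0,
        frac_ba_from_remin=d_ba / (ba0 + d_ba) if d_ba else 0.0,
        final_ba=ba0 + d_ba,
        final_sulfate=s0 + d_s,
        omega_final=float(omegas[-1]),
        trajectory=pd.DataFrame(
            {"x_p": xs, "omega": omegas, "ionic_strength": strengths}
        ),
        scenario=scenario,
    )


def scenario_multiplier(
    solution: MajorIonSolution,
    s_p: float,
    thermo: ThermoPreset | None = None,
    single_mode: str = "sulfate_only",
    ba_p_mM_M: float = 0.44,
    freeze_gamma: bool = False,
) -> float:
    """How much more remineralization a single-ion scenario needs.

    Ratio of x_P at saturation between ``single_mode`` and the both-ion
    scenario at identical stoichiometry.
    """
    both = titrate_remineralization(
        solution, TitrationScenario("both", ba_p_mM_M, s_p), thermo, freeze_gamma=freeze_gamma
    )
    single = titrate_remineralization(
        solution, TitrationScenario(single_mode, ba_p_mM_M, s_p), thermo,
        freeze_gamma=freeze_gamma,
    )
    if both.x_p == 0:
        raise ValidationError("ambient solution already saturated; multiplier undefined")
    return single.x_p / both.x_p
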
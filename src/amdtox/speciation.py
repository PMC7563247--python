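"""Equilibrium aqueous speciation for sulfate/chloride-rich acidic waters.

Given total dissolved concentrations of metal(loid) components and ligands,
a fixed pH, and a set of complex formation reactions with association
constants, the solver partitions each component between its free form and
its complexes so that

* every complex satisfies mass action on activities,
  ``a_complex = K * prod(a_component^nu)``, and
* every component satisfies mass balance,
  ``total = free + sum(nu * [complex])``.

Single-ion activity coefficients come from the Davies equation (A = 0.509,
valid to ionic strength ~0.5 M; the <2% temperature dependence of A over the
lake's 12.5-18.3 degC range is neglected). Ionic strength and the activity
coefficients are recomputed from the current species distribution on every
iteration, so the solution is self-consistent. The proton is a fixed-activity
pseudo-component (``a_H = 10**-pH``): measured pH is an input, not a solved
quantity, and no charge balance is imposed.

The solve itself is a damped multiplicative fixed-point iteration on the free
component concentrations — robust for the small component sets used here,
where each update rescales a free concentration by the ratio of declared to
implied total, damped in log space.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .errors import ConvergenceError, SchemaError

__all__ = [
    "ComponentSet",
    "ComplexDef",
    "SpeciationResult",
    "ionic_strength",
    "davies_gamma",
    "solve_speciation",
    "free_cation_table",
    "load_thermo_yaml",
    "default_thermo",
    "component_set_from_ug_per_L",
]

DAVIES_A = 0.509

#: g/mol used to convert ug/L totals into mol/L.
MOLAR_MASS = {
    "Al": 26.982,
    "Fe(II)": 55.845,
    "Fe(III)": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
    "Mn": 54.938,
    "Co": 58.933,
    "Ni": 58.693,
    "As(III)": 74.922,
    "As(V)": 74.922,
    "SO4": 96.06,
    "Cl": 35.45,
}


@dataclass
class ComponentSet:
    """Total dissolved component concentrations (mol/L) at fixed pH."""

    totals: dict[str, float]
    pH: float
    temperature: float = 25.0
    charges: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.pH < 14.0:
            raise ValueError("pH must lie in (0, 14)")
        for name, total in self.totals.items():
            if total < 0:
                raise ValueError(f"negative total for component {name!r}")


@dataclass
class ComplexDef:
    """One complexation reaction, association convention, activities."""

    name: str
    stoichiometry: dict[str, int]
    log10_K: float
    charge: int

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise SchemaError(f"complex {self.name!r} has empty stoichiometry")


@dataclass
class SpeciationResult:
    free_conc: dict[str, float]
    species_conc: dict[str, float]
    fractions: dict[str, dict[str, float]]  # metal -> {species label -> % of total}
    gamma: dict[str, float]
    ionic_strength: float
    free_activity: dict[str, float]
    charges: dict[str, int]


def ionic_strength(conc: Mapping[str, float], charge: Mapping[str, int]) -> float:
    """I = 1/2 sum c_i z_i^2, with molarity standing in for molality."""
    total = 0.0
    for name, c in conc.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name!r}")
        if name not in charge:
            raise SchemaError(f"no charge declared for species {name!r}")
        total += c * charge[name] ** 2
    return 0.5 * total


def davies_gamma(z: int, ionic_strength: float) -> float:
    """Davies single-ion activity coefficient; 1.0 for neutral species."""
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if z == 0 or ionic_strength == 0:
        return 1.0
    sqrt_i = math.sqrt(ionic_strength)
    log10_gamma = -DAVIES_A * z * z * (sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength)
    return 10.0 ** log10_gamma


def solve_speciation(
    components: ComponentSet,
    complexes: Sequence[ComplexDef],
    *,
    use_activities: bool = True,
    damping: float = 0.5,
    max_iter: int = 1000,
    tol: float = 1e-12,
) -> SpeciationResult:
    """Solve the equilibrium distribution of all components.

    Mass balance is satisfied to relative ``tol`` for every component with a
    positive total (the spec-level guarantee is 1e-8; the default iteration
    tolerance is tighter so downstream fractions are accurate to ~1e-10).
    Raises :class:`ConvergenceError` with the worst residual if ``max_iter``
    is exhausted.
    """
    names = list(components.totals)
    charges = dict(components.charges)
    for cx in complexes:
        for comp in cx.stoichiometry:
            if comp != "H" and comp not in components.totals:
                raise SchemaError(
                    f"complex {cx.name!r} references undeclared component {comp!r}"
                )
            if comp != "H" and cx.stoichiometry[comp] < 0:
                raise SchemaError(
                    f"complex {cx.name!r}: negative stoichiometry is only "
                    "supported for the proton"
                )

    h_activity = 10.0 ** (-components.pH)
    totals = components.totals
    # start from the declared totals (upper bound on each free concentration)
    free = {n: (totals[n] if totals[n] > 0 else 0.0) for n in names}
    gammas_comp = {n: 1.0 for n in names}
    gammas_cx = {cx.name: 1.0 for cx in complexes}
    ionic = 0.0
    worst = math.inf

    for _ in range(max_iter):
        # mass action on activities with the current gammas
        species: dict[str, float] = {}
        for cx in complexes:
            log_c = cx.log10_K - math.log10(gammas_cx[cx.name])
            ok = True
            for comp, nu in cx.stoichiometry.items():
                if comp == "H":
                    a = h_activity
                else:
                    c = free[comp]
                    if c <= 0.0:
                        ok = False
                        break
                    a = gammas_comp[comp] * c
                log_c += nu * math.log10(a)
            species[cx.name] = 10.0 ** log_c if ok else 0.0

        implied = dict(free)
        for cx in complexes:
            for comp, nu in cx.stoichiometry.items():
                if comp != "H":
                    implied[comp] += nu * species[cx.name]

        worst = 0.0
        for n in names:
            if totals[n] > 0:
                worst = max(worst, abs(implied[n] - totals[n]) / totals[n])
        if worst <= tol:
            break

        for n in names:
            if totals[n] > 0 and implied[n] > 0:
                free[n] *= (totals[n] / implied[n]) ** damping

        if use_activities:
            all_conc = {**{n: free[n] for n in names}, **species}
            all_charge = {**charges, **{cx.name: cx.charge for cx in complexes}}
            ionic = ionic_strength(all_conc, all_charge)
            gammas_comp = {n: davies_gamma(charges.get(n, 0), ionic) for n in names}
            gammas_cx = {cx.name: davies_gamma(cx.charge, ionic) for cx in complexes}
    else:
        raise ConvergenceError(
            f"speciation did not converge in {max_iter} iterations "
            f"(worst mass-balance residual {worst:.3e})",
            worst_residual=worst,
        )

    fractions: dict[str, dict[str, float]] = {}
    for n in names:
        if totals[n] <= 0:
            continue
        contrib = {n: free[n] / totals[n] * 100.0}
        for cx in complexes:
            nu = cx.stoichiometry.get(n, 0)
            if nu > 0:
                contrib[cx.name] = nu * species[cx.name] / totals[n] * 100.0
        fractions[n] = contrib

    free_activity = {n: gammas_comp[n] * free[n] for n in names}
    return SpeciationResult(
        free_conc=dict(free),
        species_conc=species,
        fractions=fractions,
        gamma={**gammas_comp, **gammas_cx},
        ionic_strength=ionic,
        free_activity=free_activity,
        charges=charges,
    )


def free_cation_table(
    result: SpeciationResult,
) -> dict[str, tuple[float, str, float]]:
    """Per metal: (free %, predominant species label, free-form activity).

    The predominant species is the one with the largest share of the metal's
    total; exact ties go to the alphabetically first label.
    """
    out = {}
    for metal, shares in result.fractions.items():
        predominant = min(shares, key=lambda s: (-shares[s], s))
        out[metal] = (shares[metal], predominant, result.free_activity[metal])
    return out


def load_thermo_yaml(source) -> tuple[dict[str, int], list[ComplexDef]]:
    """Read a thermodynamic config (component charges + complex definitions)."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    charges = {name: int(spec["charge"]) for name, spec in doc["components"].items()}
    complexes = [
        ComplexDef(
            name=c["name"],
            stoichiometry={k: int(v) for k, v in c["stoichiometry"].items()},
            log10_K=float(c["log10_K"]),
            charge=int(c["charge"]),
        )
        for c in doc["complexes"]
    ]
    return charges, complexes


def default_thermo() -> tuple[dict[str, int], list[ComplexDef]]:
    """The packaged default constant set (documented as non-site-specific)."""
    ref = resources.files("amdtox.data") / "thermo_default.yaml"
    with ref.open() as fh:
        return load_thermo_yaml(fh)


def subset_complexes(
    complexes: Sequence[ComplexDef], components: ComponentSet | Mapping[str, float]
) -> list[ComplexDef]:
    """Complexes whose non-proton components are all declared.

    Layer compositions typically declare only the redox species present
    (e.g. Fe(II) but not Fe(III)); the default complex set covers both, so
    it is subset before solving.
    """
    declared = set(components.totals if isinstance(components, ComponentSet) else components)
    return [
        cx for cx in complexes
        if all(c == "H" or c in declared for c in cx.stoichiometry)
    ]


def speciate_layer(
    chem,
    layer: str,
    thermo: tuple[dict[str, int], list[ComplexDef]] | None = None,
    **options,
) -> SpeciationResult:
    """Solve speciation for one layer of a WaterChemistry table (ug/L input)."""
    charges, complexes = thermo if thermo is not None else default_thermo()
    totals = {
        row.element: float(row.conc_ug_per_L)
        for row in chem.data[chem.data["layer"] == layer].itertuples()
        if row.element in MOLAR_MASS
    }
    if chem.conditions is None:
        raise SchemaError("water chemistry lacks layer conditions (pH)")
    cond = chem.conditions.set_index("layer")
    comps = component_set_from_ug_per_L(
        totals,
        pH=float(cond.loc[layer, "pH"]),
        temperature=float(cond.loc[layer].get("temperature_C", 25.0)),
        charges=charges,
    )
    return solve_speciation(comps, subset_complexes(complexes, comps), **options)


def component_set_from_ug_per_L(
    totals_ug_per_L: Mapping[str, float],
    pH: float,
    temperature: float = 25.0,
    charges: Mapping[str, int] | None = None,
) -> ComponentSet:
    """Build a mol/L :class:`ComponentSet` from ug/L totals via molar masses."""
    if charges is None:
        charges = default_thermo()[0]
    totals = {}
    for name, ug in totals_ug_per_L.items():
        if name not in MOLAR_MASS:
            raise SchemaError(f"no molar mass known for component {name!r}")
        totals[name] = float(ug) * 1e-6 / MOLAR_MASS[name]
    return ComponentSet(
        totals=totals,
        pH=pH,
        temperature=temperature,
        charges={n: charges.get(n, 0) for n in totals},
    )
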
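"""Photon mass-attenuation data and Hounsfield-unit helpers.

The material library stores dual-energy attenuation in Hounsfield units
(HU) because the decomposition inputs are virtual monoenergetic images
(VMIs), which are HU images.  Barycentric volume fractions are invariant
under the per-energy affine map between linear attenuation and HU, so an
HU-based library is equivalent to a linear-attenuation formulation.

The elemental mass-attenuation grid below (total cross section with
coherent scattering, cm^2/g) follows standard NIST-style tabulations on a
60/80/100/150 keV grid and is interpolated log-log to the working
energies (70 and 150 keV by default).  Regenerate / audit the derived
material table with ``scripts/make_attenuation_table.py``.
"""

from __future__ import annotations

import math

__all__ = [
    "ENERGY_GRID_KEV",
    "ELEMENT_MU_RHO",
    "COMPOSITIONS",
    "DENSITIES",
    "element_mu_rho",
    "compound_mu_rho",
    "mu_water",
    "hounsfield",
    "material_hu",
    "solution_hu",
]

#: Tabulation energies (keV) of the elemental grid.
ENERGY_GRID_KEV = (60.0, 80.0, 100.0, 150.0)

#: Mass attenuation coefficients mu/rho (cm^2/g), total with coherent
#: scattering, on ENERGY_GRID_KEV.  Oxygen is anchored so that liquid
#: water reproduces its reference values (0.2059, 0.1837, 0.1707,
#: 0.1505 cm^2/g) exactly; the HU scale is therefore exact by
#: construction.  Mid-Z entries (N, P, Ca) are accurate to a few percent,
#: which only shifts the collagen / hydroxyapatite vertices slightly.
ELEMENT_MU_RHO = {
    "H": (0.3260, 0.3091, 0.2944, 0.2651),
    "C": (0.1753, 0.1610, 0.1514, 0.1347),
    "N": (0.1828, 0.1642, 0.1531, 0.1353),
    "O": (0.1907, 0.1679, 0.1551, 0.1361),
    "P": (0.2958, 0.2120, 0.1825, 0.1452),
    "Ca": (0.5400, 0.3190, 0.2400, 0.1710),
    "I": (7.5790, 3.5100, 1.9420, 0.7338),
}

#: Elemental mass fractions of the compounds used by the default library.
COMPOSITIONS = {
    # liquid water H2O
    "water": {"H": 0.111894, "O": 0.888106},
    # triolein C57H104O6 -- the lipid basis
    "triolein": {"H": 0.118423, "C": 0.773219, "O": 0.108358},
    # dry collagen, (C102 H149 N31 O38)n
    "collagen": {"H": 0.062130, "C": 0.506773, "N": 0.179581, "O": 0.251516},
    # calcium hydroxyapatite Ca10(PO4)6(OH)2
    "hydroxyapatite": {"H": 0.002007, "O": 0.414068, "P": 0.184994, "Ca": 0.398931},
    # elemental iodine (dissolved contrast agent)
    "iodine": {"I": 1.0},
}

#: Nominal densities (g/cm^3).
DENSITIES = {
    "water": 1.000,
    "triolein": 0.915,
    "collagen": 1.350,
    "hydroxyapatite": 3.160,
}


def _loglog_interp(energy_kev: float, grid, values) -> float:
    """Log-log interpolation of a positive tabulated function."""
    if not grid[0] <= energy_kev <= grid[-1]:
        raise ValueError(
            f"energy {energy_kev} keV outside tabulated range "
            f"[{grid[0]}, {grid[-1]}] keV"
        )
    for i in range(len(grid) - 1):
        if grid[i] <= energy_kev <= grid[i + 1]:
            t = (math.log(energy_kev) - math.log(grid[i])) / (
                math.log(grid[i + 1]) - math.log(grid[i])
            )
            return math.exp(
                (1.0 - t) * math.log(values[i]) + t * math.log(values[i + 1])
            )
    raise AssertionError("unreachable")


def element_mu_rho(symbol: str, energy_kev: float) -> float:
    """mu/rho of an element (cm^2/g) at ``energy_kev``."""
    try:
        values = ELEMENT_MU_RHO[symbol]
    except KeyError as exc:
        raise KeyError(f"element {symbol!r} not in embedded table") from exc
    return _loglog_interp(energy_kev, ENERGY_GRID_KEV, values)


def compound_mu_rho(mass_fractions: dict, energy_kev: float) -> float:
    """Mixture-rule mu/rho (cm^2/g) from elemental mass fractions."""
    total = sum(mass_fractions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"mass fractions sum to {total}, expected 1")
    return sum(
        frac * element_mu_rho(sym, energy_kev) for sym, frac in mass_fractions.items()
    )


def mu_water(energy_kev: float) -> float:
    """Linear attenuation of water (cm^-1; density 1 g/cm^3)."""
    return compound_mu_rho(COMPOSITIONS["water"], energy_kev) * DENSITIES["water"]


def hounsfield(mu: float, energy_kev: float) -> float:
    """Convert linear attenuation (cm^-1) to HU at ``energy_kev``."""
    muw = mu_water(energy_kev)
    return 1000.0 * (mu - muw) / muw


def material_hu(name: str, energy_kev: float, density: float | None = None) -> float:
    """HU of a bulk compound from the embedded composition table."""
    rho = DENSITIES[name] if density is None else density
    mu = compound_mu_rho(COMPOSITIONS[name], energy_kev) * rho
    return hounsfield(mu, energy_kev)


def solution_hu(solute: str, concentration_mg_ml: float, energy_kev: float) -> float:
    """HU of water with ``concentration_mg_ml`` of dissolved solute.

    Dilute-solution model: the solute adds attenuation on top of water
    without displacing it, which is the standard contrast-rod idealization
    for iodine at <= 20 mg/mL and keeps the fraction-concentration map
    exactly linear with zero intercept.
    """
    if concentration_mg_ml < 0:
        raise ValueError("concentration must be >= 0")
    rho_solute = concentration_mg_ml * 1e-3  # mg/mL -> g/cm^3
    delta_mu = compound_mu_rho(COMPOSITIONS[solute], energy_kev) * rho_solute
    return 1000.0 * delta_mu / mu_water(energy_kev)
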
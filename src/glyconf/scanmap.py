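"""Conformational maps by rigid dihedral driving on a phi/psi grid.

A pluggable energy function E(phi, psi) (deterministic, 360-degree
periodic in both torsions, kcal/mol) is evaluated on a uniform grid —
the classic dihedral-driving construction of a rough potential-energy
surface.  No relaxation of other coordinates is performed; the result is
a single-point rigid scan.  Energies are reported relative to the map's
global minimum (absolute energies are meaningless across functions).

Local minima are detected on the discrete grid under 8-neighbour
comparison with periodic wrapping; Boltzmann populations at a given
temperature follow from the relative minimum energies.

Two toy potentials ship for testing and demonstration: a single-well
cosine potential and a two-well potential combining an exo-anomeric-like
cosine term on phi with a double-well cosine on psi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import UnknownPresetError, ValidationError

__all__ = [
    "ConformationalMap",
    "EnergyFunction",
    "scan",
    "find_minima",
    "boltzmann_population",
    "single_well_potential",
    "two_well_potential",
    "ENERGY_FUNCTIONS",
    "get_energy_function",
    "GAS_CONSTANT_KCAL",
]

#: gas constant in kcal/(mol K)
GAS_CONSTANT_KCAL = 0.0019872

EnergyFunction = Callable[[float, float], float]


@dataclass
class ConformationalMap:
    """Relative energies (kcal/mol) on a uniform phi/psi grid.

    ``energies[i, j]`` is the energy at (psi_grid[i], phi_grid[j]) — psi
    rows, phi columns, matching the matrix CSV export.  The global
    minimum is shifted to exactly 0.
    """

    phi_grid: np.ndarray
    psi_grid: np.ndarray
    energies: np.ndarray
    step: float

    def __post_init__(self) -> None:
        self.phi_grid = np.asarray(self.phi_grid, dtype=float)
        self.psi_grid = np.asarray(self.psi_grid, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != (len(self.psi_grid), len(self.phi_grid)):
            raise ValidationError(
                f"energies shape {self.energies.shape} does not match grids "
                f"({len(self.psi_grid)}, {len(self.phi_grid)})"
            )
        if not np.all(np.isfinite(self.energies)):
            raise ValidationError("map energies must be finite")

    @property
    def n_points(self) -> int:
        return self.energies.size

    def to_long_dataframe(self) -> pd.DataFrame:
        psi, phi = np.meshgrid(self.psi_grid, self.phi_grid, indexing="ij")
        return pd.DataFrame(
            {"phi_deg": phi.ravel(), "psi_deg": psi.ravel(),
             "energy_kcal": self.energies.ravel()}
        )

    def to_matrix_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.energies, index=self.psi_grid, columns=self.phi_grid)
        df.index.name = "psi_deg\\phi_deg"
        return df


def scan(energy: EnergyFunction, step: float = 10.0) -> ConformationalMap:
    """Rigid dihedral-driving scan of ``energy`` on a step x step grid.

    The grid covers [-180, 180) exactly once per step (360/step points per
    torsion; the canonical 10-degree step gives a 36x36 = 1296-point map).
    Periodicity of the energy function is spot-checked at the grid edges.
    """
    if step <= 0 or 360.0 % step != 0:
        raise ValidationError(f"step must be a positive divisor of 360, got {step}")
    grid = np.arange(-180.0, 180.0, step)
    for phi0, psi0 in ((-180.0, 0.0), (0.0, -180.0), (-180.0, -180.0)):
        if not np.isclose(energy(phi0, psi0), energy(phi0 + 360.0, psi0 + 360.0),
                          rtol=1e-8, atol=1e-8):
            raise ValidationError(
                "energy function is not 360-degree periodic "
                f"(checked at phi={phi0}, psi={psi0})"
            )
    e = np.empty((len(grid), len(grid)))
    for i, psi in enumerate(grid):
        for j, phi in enumerate(grid):
            e[i, j] = energy(phi, psi)
    e = e - e.min()
    return ConformationalMap(phi_grid=grid.copy(), psi_grid=grid.copy(),
                             energies=e, step=float(step))


def find_minima(cmap: ConformationalMap, energy_window: float = 5.0
                ) -> list[tuple[float, float, float]]:
    """Grid-local minima within ``energy_window`` kcal/mol of the global one.

    A node is a local minimum when strictly below all 8 neighbours under
    periodic wrapping.  Returned as (phi, psi, energy) sorted by energy;
    the global minimum is first.
    """
    if energy_window < 0:
        raise ValidationError(f"energy window must be >= 0, got {energy_window}")
    e = cmap.energies
    is_min = np.ones_like(e, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_min &= e < np.roll(np.roll(e, di, axis=0), dj, axis=1)
    out = [
        (float(cmap.phi_grid[j]), float(cmap.psi_grid[i]), float(e[i, j]))
        for i, j in zip(*np.nonzero(is_min))
        if e[i, j] <= energy_window
    ]
    out.sort(key=lambda t: (t[2], t[0], t[1]))
    return out


def boltzmann_population(energies: Sequence[float], temperature: float = 298.0
                         ) -> np.ndarray:
    """Boltzmann fractions exp(-E/RT), normalized to sum to 1.

    ``energies`` in kcal/mol (relative values are enough — a constant
    shift cancels), temperature in Kelvin.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValidationError("need at least one energy")
    if temperature <= 0:
        raise ValidationError(f"temperature must be > 0 K, got {temperature}")
    w = np.exp(-(e - e.min()) / (GAS_CONSTANT_KCAL * temperature))
    return w / w.sum()


# ---------------------------------------------------------------------------
# shipped toy potentials


def single_well_potential(phi: float, psi: float) -> float:
    """One minimum at (30, 40): E = 2(1-cos(phi-30)) + 2(1-cos(psi-40))."""
    return 2.0 * (1.0 - np.cos(np.radians(phi - 30.0))) + 2.0 * (
        1.0 - np.cos(np.radians(psi - 40.0))
    )


def two_well_potential(phi: float, psi: float) -> float:
    """Exo-anomeric-like well on phi plus a double well on psi.

    E = 2(1-cos(phi-30)) + 2(1-cos 2(psi-40)) + 1.5(1-cos(psi-40)).

    Analytic minima: global at (30, 40) with E=0 and a second at
    (30, -140) with E=+3 kcal/mol (the only other stationary minimum of
    the psi double well).
    """
    p = np.radians(phi - 30.0)
    s = np.radians(psi - 40.0)
    return (
        2.0 * (1.0 - np.cos(p))
        + 2.0 * (1.0 - np.cos(2.0 * s))
        + 1.5 * (1.0 - np.cos(s))
    )


ENERGY_FUNCTIONS: dict[str, EnergyFunction] = {
    "single_well": single_well_potential,
    "two_well": two_well_potential,
}


def get_energy_function(name: str) -> EnergyFunction:
    try:
        return ENERGY_FUNCTIONS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown energy function {name!r}; registered: {sorted(ENERGY_FUNCTIONS)}"
        ) from None
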
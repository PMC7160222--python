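"""Nuclear constants of the ``176Lu -> 176Hf`` decay and LYSO photon-interaction data.

``176Lu`` (2.6% of natural lutetium) beta-decays with a half-life of
3.76e10 years to excited states of ``176Hf``.  The de-excitation cascade
emits up to three prompt gamma rays -- gamma1 = 307 keV, gamma2 = 202 keV and
gamma3 = 88 keV -- where the 202 and 88 keV transitions compete with internal
conversion (IC).  In a LYSO scintillator this activity amounts to roughly
300 Bq/cm^3 of self-detected background.

This module holds the decay-scheme constants and the vendored LYSO photon
attenuation table with log-log interpolation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "DecayScheme",
    "AttenuationTable",
    "LinearAttenuation",
    "EnergyRangeError",
    "default_decay_scheme",
    "attenuation_lookup",
    "LYSO_DENSITY",
]

#: Nominal LYSO (Lu1.8Y0.2SiO5:Ce) density, g/cm^3.
LYSO_DENSITY = 7.1


class EnergyRangeError(ValueError):
    """Photon energy outside the tabulated attenuation grid."""


@dataclass(frozen=True)
class DecayScheme:
    """Constants of the ``176Lu -> 176Hf`` beta decay and its gamma cascade.

    Parameters
    ----------
    beta_endpoint : float
        Maximum beta kinetic energy, keV.
    gamma_energies : tuple of float
        Cascade transition energies in emission order (gamma1, gamma2,
        gamma3), keV, strictly decreasing.
    gamma_emission_probs : tuple of float
        Probability per decay that each transition proceeds by gamma
        emission rather than internal conversion.  The complement
        ``1 - P_i`` is the IC branch (zero for the 307 keV transition).
    half_life_years : float
        ``176Lu`` half-life, years.
    activity_concentration : float
        Intrinsic activity of LYSO, Bq/cm^3.
    daughter_z : int
        Atomic number of the daughter (Hf), used by the beta-spectrum
        Fermi function.
    """

    beta_endpoint: float = 593.0
    gamma_energies: tuple[float, float, float] = (307.0, 202.0, 88.0)
    gamma_emission_probs: tuple[float, float, float] = (1.000, 0.833, 0.155)
    half_life_years: float = 3.76e10
    activity_concentration: float = 300.0
    daughter_z: int = 72

    def __post_init__(self) -> None:
        if self.beta_endpoint <= 0:
            raise ValueError("beta endpoint must be positive")
        if len(self.gamma_energies) != 3 or len(self.gamma_emission_probs) != 3:
            raise ValueError("exactly three cascade transitions are modelled")
        e = self.gamma_energies
        if not (e[0] > e[1] > e[2] > 0):
            raise ValueError("gamma energies must be positive and strictly decreasing")
        for p in self.gamma_emission_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError("emission probabilities must lie in [0, 1]")
        if self.activity_concentration < 0 or self.half_life_years <= 0:
            raise ValueError("activity and half-life must be positive")

    @property
    def q_value(self) -> float:
        """Ground-state decay energy, keV (1190 for the default constants)."""
        return self.beta_endpoint + float(sum(self.gamma_energies))

    def replace(self, **changes) -> "DecayScheme":
        return replace(self, **changes)


def default_decay_scheme(**overrides) -> DecayScheme:
    """Return the default ``176Lu`` decay scheme, with optional field overrides.

    The gamma emission probabilities (1.000, 0.833, 0.155) correspond to
    total internal-conversion coefficients of approximately (0, 0.20, 5.45)
    for the 307/202/88 keV transitions of ``176Hf``.
    """
    return DecayScheme(**overrides)


class LinearAttenuation(NamedTuple):
    """Per-interaction linear attenuation coefficients, 1/cm."""

    photoelectric: np.ndarray
    incoherent: np.ndarray
    coherent: np.ndarray
    total: np.ndarray


@dataclass
class AttenuationTable:
    """Mass attenuation coefficients of a scintillator on an energy grid.

    Coefficients are cm^2/g on a strictly increasing grid in keV; lookups
    interpolate log-log (exact at the nodes, geometric-mean between them).
    The ``total`` column includes the coherent contribution; transport
    decides separately whether coherent scattering is active.
    """

    energy: np.ndarray
    photoelectric: np.ndarray
    incoherent: np.ndarray
    coherent: np.ndarray
    total: np.ndarray
    density: float = LYSO_DENSITY
    material: str = "LYSO"
    _logs: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name in ("energy", "photoelectric", "incoherent", "coherent", "total"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.energy) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        for name in ("photoelectric", "incoherent", "coherent", "total"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} coefficients must be non-negative")
        if np.any(self.total + 1e-12 < np.maximum(self.photoelectric, self.incoherent)):
            raise ValueError("total must bound every component")
        if self.density <= 0:
            raise ValueError("density must be positive")
        self._logs = {
            "e": np.log(self.energy),
            "pe": np.log(np.maximum(self.photoelectric, 1e-300)),
            "inc": np.log(np.maximum(self.incoherent, 1e-300)),
            "coh": np.log(np.maximum(self.coherent, 1e-300)),
        }

    @classmethod
    def from_csv(cls, path, density: float = LYSO_DENSITY,
                 material: str = "LYSO") -> "AttenuationTable":
        import pandas as pd

        data = pd.read_csv(path, comment="#")
        return cls(
            energy=data["energy_keV"],
            photoelectric=data["pe_cm2g"],
            incoherent=data["incoh_cm2g"],
            coherent=data["coh_cm2g"],
            total=data["total_cm2g"],
            density=density,
            material=material,
        )

    @classmethod
    def lyso(cls, density: float = LYSO_DENSITY) -> "AttenuationTable":
        """The vendored synthetic LYSO table (see package data for provenance)."""
        ref = importlib.resources.files("lutebg.data") / "lyso_attenuation_synthetic.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path, density=density, material="LYSO")

    @property
    def energy_min(self) -> float:
        return float(self.energy[0])

    @property
    def energy_max(self) -> float:
        return float(self.energy[-1])

    def linear(self, energy) -> LinearAttenuation:
        """Linear attenuation coefficients (1/cm) at ``energy`` (keV).

        Vectorized; raises :class:`EnergyRangeError` outside the grid.
        """
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.energy[0]) or np.any(e > self.energy[-1]):
            raise EnergyRangeError(
                f"energy outside tabulated range "
                f"[{self.energy[0]:g}, {self.energy[-1]:g}] keV"
            )
        loge = np.log(e)
        pe = np.exp(np.interp(loge, self._logs["e"], self._logs["pe"])) * self.density
        inc = np.exp(np.interp(loge, self._logs["e"], self._logs["inc"])) * self.density
        coh = np.exp(np.interp(loge, self._logs["e"], self._logs["coh"])) * self.density
        return LinearAttenuation(pe, inc, coh, pe + inc + coh)


def attenuation_lookup(table: AttenuationTable, energy) -> LinearAttenuation:
    """Functional alias for :meth:`AttenuationTable.linear`."""
    return table.linear(energy)
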
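"""Normalized beta- kinetic-energy density of ``176Lu`` and sampling from it.

The continuum is modelled with the allowed Fermi shape

    N(E) dE  ~  p * E_tot * (Q - E)^2 * F(Z, E) dE,

with ``p`` the electron momentum, ``E_tot`` its total energy, ``Q`` the
endpoint and ``F`` the nonrelativistic point-charge Fermi function of the
daughter nucleus (Z = 72).  The first-forbidden character of the real decay
mildly reshapes the continuum only; every discrete probability in the model
is independent of this choice.  A hook accepts a tabulated spectrum instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nuclear_data import DecayScheme

__all__ = ["BetaDensity", "beta_pdf", "beta_pdf_from_table", "sample_beta"]

_ME_KEV = 510.99895  # electron rest energy
_ALPHA = 7.2973525693e-3  # fine-structure constant

#: normalization tightness enforced on construction
_NORM_TOL = 1e-9


@dataclass(frozen=True)
class BetaDensity:
    """Beta spectrum as probability mass per 1-keV bin on an integer grid.

    ``energy[i]`` is the bin energy in keV (0 ... endpoint, 1-keV spacing)
    and ``density[i]`` the probability carried by that bin; the masses sum
    to one.
    """

    energy: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if e.shape != d.shape or e.ndim != 1 or len(e) < 2:
            raise ValueError("energy and density must be matching 1-D arrays")
        if np.any(np.diff(e) != 1.0):
            raise ValueError("grid must have 1-keV spacing")
        if np.any(d < 0):
            raise ValueError("density must be non-negative")
        total = d.sum()
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError("density must be normalized to unit total mass")
        object.__setattr__(self, "energy", e)
        object.__setattr__(self, "density", d)

    @property
    def endpoint(self) -> float:
        return float(self.energy[-1])

    @property
    def mean(self) -> float:
        return float(np.sum(self.energy * self.density))

    def cdf(self) -> np.ndarray:
        """Cumulative mass at each grid point (ends at 1)."""
        return np.cumsum(self.density)


def fermi_function(z: int, kinetic_kev: np.ndarray) -> np.ndarray:
    """Nonrelativistic point-charge Fermi function F(Z, E) for beta- decay."""
    e = np.asarray(kinetic_kev, dtype=float)
    etot = e + _ME_KEV
    beta = np.sqrt(np.clip(1.0 - (_ME_KEV / etot) ** 2, 1e-30, None))
    x = 2.0 * np.pi * _ALPHA * z / beta
    return x / (1.0 - np.exp(-x))


def allowed_shape(scheme: DecayScheme, kinetic_kev: np.ndarray) -> np.ndarray:
    """Unnormalized allowed-shape integrand; zero outside (0, endpoint]."""
    e = np.asarray(kinetic_kev, dtype=float)
    q = scheme.beta_endpoint
    etot = e + _ME_KEV
    p = np.sqrt(np.clip(etot**2 - _ME_KEV**2, 0.0, None))
    val = p * etot * np.clip(q - e, 0.0, None) ** 2 * fermi_function(scheme.daughter_z, e)
    return np.where((e >= 0) & (e <= q), val, 0.0)


def beta_pdf(scheme: DecayScheme, shape: str = "allowed") -> BetaDensity:
    """Normalized ``176Lu`` beta density on a 1-keV grid from 0 to the endpoint.

    Each grid mass is the integral of the continuous shape over its 1-keV
    bin (trapezoid rule on a 0.1-keV subgrid), so grid moments track the
    continuous distribution to well below the bin width.
    """
    if shape != "allowed":
        raise ValueError(f"unknown shape {shape!r}; use beta_pdf_from_table for data")
    grid = np.arange(0.0, np.floor(scheme.beta_endpoint) + 1.0)
    fine = np.linspace(0.0, scheme.beta_endpoint, 10 * len(grid) + 1)
    y = allowed_shape(scheme, fine)
    w = np.full_like(fine, fine[1] - fine[0])
    w[0] *= 0.5
    w[-1] *= 0.5
    dens = np.zeros_like(grid)
    np.add.at(dens, np.clip(np.rint(fine).astype(int), 0, len(grid) - 1), y * w)
    dens = dens / dens.sum()
    # wash out any residual rounding so the unit-mass invariant holds exactly
    dens[-1] += 1.0 - dens.sum()
    return BetaDensity(grid, dens)


def beta_pdf_from_table(energy_kev, intensity) -> BetaDensity:
    """Build a :class:`BetaDensity` from a tabulated (energy, intensity) spectrum.

    The table is interpolated onto the package's 1-keV grid and renormalized.
    Raises ``ValueError`` for negative intensities or a non-increasing grid.
    """
    e = np.asarray(energy_kev, dtype=float)
    w = np.asarray(intensity, dtype=float)
    if e.ndim != 1 or e.shape != w.shape or len(e) < 2:
        raise ValueError("tabulated spectrum must be two matching 1-D columns")
    if np.any(np.diff(e) <= 0):
        raise ValueError("tabulated energies must be strictly increasing")
    if np.any(w < 0):
        raise ValueError("tabulated intensities must be non-negative")
    grid = np.arange(0.0, np.floor(e[-1]) + 1.0)
    dens = np.interp(grid, e, w, left=0.0, right=0.0)
    total = dens.sum()
    if total <= 0:
        raise ValueError("tabulated spectrum has no positive intensity")
    dens = dens / total
    dens[-1] += 1.0 - dens.sum()
    return BetaDensity(grid, dens)


def sample_beta(density: BetaDensity, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` beta kinetic energies (keV) by inverse-CDF sampling.

    ``seed`` may be an int or a ``numpy.random.Generator``; fixed seeds give
    identical samples.  The piecewise-linear inverse of the cumulative mass
    makes the samples continuous on [0, endpoint].
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cdf = np.concatenate([[0.0], density.cdf()])
    # spread each 1-keV mass over its bin, [E_i - 1/2, E_i + 1/2] clipped to the support
    edges = np.concatenate(
        [[density.energy[0]], density.energy[:-1] + 0.5, [density.endpoint]]
    )
    u = rng.random(int(n))
    return np.interp(u, cdf, edges)
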
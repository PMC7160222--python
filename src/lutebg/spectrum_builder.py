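"""Assembly of the analytic coincidence energy spectrum and the rate-distance fit.

The spectrum on a 1-keV grid (0-1200 keV) is the weighted sum of

* the beta continuum translated by each discrete source-crystal cascade
  deposit ``E`` and scaled to the area ``c1_probs[E]``, and
* single-bin photopeak lines at each detector-crystal deposit ``E`` with
  weight ``c2_probs[E]``.

Detector resolution enters afterwards as a variable Gaussian blur with
``sigma(E) = a E^b`` (default ``1.15 E^0.52`` keV), followed by an 80-keV
hardware threshold and area normalization.  The grid extends to 1200 keV to
contain the 1190 keV random-pile-up bound even though true coincidences end
at 1102 keV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import erf

from .beta_spectrum import BetaDensity
from .cascade_model import CoincidenceTable

__all__ = [
    "EnergySpectrum",
    "ResponseModel",
    "DistanceLawFit",
    "assemble_spectrum",
    "convolve_response",
    "finalize",
    "fit_distance_law",
    "distance_law",
    "peak_intensity_ratio",
]

DEFAULT_E_MAX = 1200


@dataclass
class EnergySpectrum:
    """1-keV-binned energy spectrum; bin ``i`` is centred on ``i`` keV and
    covers ``[i - 1/2, i + 1/2)``."""

    content: np.ndarray
    e_max: int = DEFAULT_E_MAX
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.content = np.asarray(self.content, dtype=float)
        if self.content.shape != (self.e_max,):
            raise ValueError("content must have one bin per keV up to e_max")
        if np.any(self.content < 0):
            raise ValueError("bin contents must be non-negative")

    @property
    def energies(self) -> np.ndarray:
        """Bin centres, keV."""
        return np.arange(self.e_max, dtype=float)

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.e_max + 1, dtype=float) - 0.5

    @property
    def area(self) -> float:
        return float(self.content.sum())

    def max_energy(self, threshold: float = 0.0) -> int:
        """Centre energy (keV) of the highest bin with content above threshold."""
        nz = np.flatnonzero(self.content > threshold)
        return int(nz[-1]) if len(nz) else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"energy_keV": np.arange(self.e_max), "density": self.content}
        )


@dataclass(frozen=True)
class ResponseModel:
    """Energy resolution ``sigma(E) = a E^b`` keV of the scintillator chain."""

    a: float = 1.15
    b: float = 0.52

    def __post_init__(self) -> None:
        if self.a <= 0 or not 0.0 < self.b < 1.0:
            raise ValueError("need a > 0 and 0 < b < 1")

    def sigma(self, energy_kev) -> np.ndarray:
        return self.a * np.asarray(energy_kev, dtype=float) ** self.b


def assemble_spectrum(table: CoincidenceTable, beta: BetaDensity,
                      e_max: int = DEFAULT_E_MAX,
                      keep_components: bool = False) -> EnergySpectrum:
    """Build the unconvolved coincidence spectrum from the analytic table.

    The total area equals twice the coincidence probability: both crystals
    contribute one histogram entry per coincidence (the C1 continua and the
    C2 photopeaks are marginals of the same joint).
    """
    nbeta = len(beta.density)
    content = np.zeros(e_max)
    components = {}
    for shift, w in sorted(table.c1_probs.items()):
        if w == 0.0:
            continue
        if shift + nbeta > e_max:
            raise ValueError(
                f"beta continuum shifted by {shift} keV exceeds the "
                f"{e_max} keV grid"
            )
        comp = np.zeros(e_max)
        comp[shift:shift + nbeta] = w * beta.density
        content += comp
        if keep_components:
            components[f"C1+{shift}"] = comp
    for e, w in sorted(table.c2_probs.items()):
        if w == 0.0:
            continue
        if e >= e_max:
            raise ValueError(f"photopeak at {e} keV exceeds the grid")
        content[int(e)] += w
        if keep_components:
            comp = np.zeros(e_max)
            comp[int(e)] = w
            components[f"C2@{e}"] = comp
    meta = {"distance": table.distance, "convolved": False, "thresholded": False}
    if keep_components:
        meta["components"] = components
    return EnergySpectrum(content, e_max, meta)


def convolve_response(spec: EnergySpectrum,
                      model: ResponseModel | None = None) -> EnergySpectrum:
    """Blur each bin with a Gaussian of width ``sigma(E_bin)``.

    The kernel is truncated at +-5 sigma and integrated exactly over the
    destination bins (erf differences), so the area is conserved except for
    the mass that would land below 0 keV, which is dropped and logged in
    ``meta['truncated_mass']``.
    """
    if spec.meta.get("convolved"):
        raise ValueError("spectrum is already convolved")
    model = model or ResponseModel()
    edges = spec.edges
    out = np.zeros_like(spec.content)
    truncated = 0.0
    root2 = np.sqrt(2.0)
    for j in np.flatnonzero(spec.content):
        c = float(j)
        w = spec.content[j]
        s = float(model.sigma(max(c, 1.0)))
        lo = max(0, int(np.floor(c - 5.0 * s)))
        hi = min(spec.e_max, int(np.ceil(c + 5.0 * s)))
        z = (edges[lo:hi + 1] - c) / (s * root2)
        mass = 0.5 * (erf(z[1:]) - erf(z[:-1]))
        out[lo:hi] += w * mass
        # loss below the grid floor (the upper edge loses nothing at 1200 keV)
        truncated += w * 0.5 * (1.0 + erf((edges[0] - c) / (s * root2)))
    meta = dict(spec.meta)
    meta.update(convolved=True, truncated_mass=truncated)
    meta.pop("components", None)
    return EnergySpectrum(out, spec.e_max, meta)


def finalize(spec: EnergySpectrum, threshold: float = 80.0) -> EnergySpectrum:
    """Apply the lower energy threshold and normalize the area to one."""
    content = spec.content.copy()
    content[spec.energies < threshold] = 0.0
    area = content.sum()
    if area <= 0:
        raise ValueError("spectrum is empty after thresholding")
    meta = dict(spec.meta)
    meta.update(thresholded=True, threshold_keV=threshold)
    return EnergySpectrum(content / area, spec.e_max, meta)


def peak_intensity_ratio(spec: EnergySpectrum, e_low: float = 202.0,
                         e_high: float = 307.0, halfwidth: float = 40.0) -> float:
    """``I_max`` near ``e_low`` divided by ``I_max`` near ``e_high``."""
    def local_max(e0):
        sel = np.abs(spec.energies - e0) <= halfwidth
        return float(spec.content[sel].max())
    return local_max(e_low) / local_max(e_high)


def distance_law(d, c):
    """Coincidence-rate falloff ``f(d) = 1 / (1 + c d^2)``."""
    return 1.0 / (1.0 + c * np.asarray(d, dtype=float) ** 2)


@dataclass(frozen=True)
class DistanceLawFit:
    c: float
    r_squared: float
    sse: float


def fit_distance_law(distances, rates) -> DistanceLawFit:
    """Least-squares fit of ``1 / (1 + c d^2)`` to normalized rates.

    ``rates`` must contain ``d = 0`` and be normalized there (``rate(0) = 1``).
    """
    d = np.asarray(distances, dtype=float)
    r = np.asarray(rates, dtype=float)
    if len(d) < 3 or 0.0 not in d:
        raise ValueError("need at least three distances including d = 0")
    if abs(r[d == 0.0][0] - 1.0) > 1e-9:
        raise ValueError("rates must be normalized to rate(0) = 1")
    (c,), _ = curve_fit(distance_law, d, r, p0=[0.1])
    resid = r - distance_law(d, c)
    sse = float(np.sum(resid**2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    return DistanceLawFit(c=float(c), r_squared=r2, sse=sse)
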
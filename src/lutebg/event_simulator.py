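"""Event-mode Monte Carlo of two LYSO crystals as simultaneous sources and detectors.

Both crystals carry the intrinsic ``176Lu`` activity (300 Bq/cm^3 by
default).  Every decay deposits a sampled beta energy locally, internal
conversion electrons locally, and transports the emitted cascade gammas
through the two-crystal geometry -- *including* partial Compton deposits the
analytic model discards.  A digitizer then emulates the coincidence
electronics: an energy threshold per crystal, a fixed coincidence time
window and a take-all-goods pairing policy.  Coincidences between deposits
of a single decay are *true*; pairs built from two distinct decays inside
the window are *random*; pairs sharing a hit with another pair are flagged
*multiple*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beta_spectrum import BetaDensity, beta_pdf, sample_beta
from .nuclear_data import AttenuationTable, DecayScheme, default_decay_scheme
from .photon_mc import (
    DetectorGeometry,
    _FULL_ABS_TOL,
    _isotropic,
    _uniform_in_crystal,
    transport_batch,
)
from .spectrum_builder import DEFAULT_E_MAX, EnergySpectrum

__all__ = [
    "DigitizerConfig",
    "SimulationResult",
    "simulate_events",
    "count_rate_curve",
    "restricted_cascade_frequencies",
]


@dataclass(frozen=True)
class DigitizerConfig:
    """Coincidence electronics emulation."""

    window_ns: float = 10.0
    threshold_keV: float = 80.0
    policy: str = "takeAllGoods"

    def __post_init__(self) -> None:
        if self.window_ns <= 0:
            raise ValueError("coincidence window must be positive")
        if self.threshold_keV < 0:
            raise ValueError("threshold cannot be negative")
        if self.policy != "takeAllGoods":
            raise ValueError("only the take-all-goods policy is implemented")


@dataclass
class SimulationResult:
    """List-mode output of :func:`simulate_events`."""

    events: pd.DataFrame
    spectrum: EnergySpectrum
    duration_s: float
    n_decays: tuple[int, int]
    singles_rates: tuple[float, float]
    rates: dict = field(default_factory=dict)

    @property
    def coincidence_rate(self) -> float:
        return self.rates.get("total", 0.0)


def _pair_hits(times: np.ndarray, crystals: np.ndarray, decay_ids: np.ndarray,
               window_s: float):
    """All-goods pairing of threshold-qualified hits sorted by time.

    Returns index pairs (i, j) with ``t_j - t_i <= window`` and opposite
    crystals, plus the per-hit pair multiplicity.
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    upper = np.searchsorted(t, t + window_s, side="right")
    pairs = []
    for i in np.flatnonzero(upper > np.arange(len(t)) + 1):
        for j in range(i + 1, upper[i]):
            if crystals[order[i]] != crystals[order[j]]:
                pairs.append((order[i], order[j]))
    mult = np.zeros(len(t), dtype=int)
    for i, j in pairs:
        mult[i] += 1
        mult[j] += 1
    return pairs, mult


def simulate_events(geometry: DetectorGeometry | None = None,
                    scheme: DecayScheme | None = None,
                    beta: BetaDensity | None = None,
                    attenuation: AttenuationTable | None = None,
                    digitizer: DigitizerConfig | None = None,
                    n_decays: int = 900_000,
                    seed=None,
                    gamma_transport: bool = True,
                    **transport_kwargs) -> SimulationResult:
    """Simulate ``n_decays`` expected decays per crystal and digitize coincidences.

    Decay times are a homogeneous Poisson process per crystal at the rate set
    by the activity concentration and crystal volume; positions are uniform
    in each crystal; the cascade is prompt.  With ``gamma_transport=False``
    the cascade gammas are discarded (beta and IC electrons only), which
    isolates random coincidences.
    """
    if n_decays < 1_000:
        raise ValueError("n_decays must be at least 1000 per crystal")
    geometry = geometry or DetectorGeometry()
    scheme = scheme or default_decay_scheme()
    beta = beta or beta_pdf(scheme)
    attenuation = attenuation or AttenuationTable.lyso()
    digitizer = digitizer or DigitizerConfig()
    if geometry.volume_cm3 <= 0 or scheme.activity_concentration <= 0:
        raise ValueError("crystal volume and activity must be positive")
    rng = np.random.default_rng(seed)

    rate = scheme.activity_concentration * geometry.volume_cm3  # Bq per crystal
    duration = n_decays / rate
    counts = rng.poisson(n_decays, size=2)
    n_tot = int(counts.sum())
    home = np.repeat(np.array([0, 1]), counts)
    times = np.concatenate([rng.uniform(0.0, duration, c) for c in counts])
    positions = np.vstack([
        _uniform_in_crystal(geometry, 0, counts[0], rng),
        _uniform_in_crystal(geometry, 1, counts[1], rng),
    ])

    dep = np.zeros((n_tot, 2))
    dep[np.arange(n_tot), home] += sample_beta(beta, n_tot, rng)

    gamma_origin, gamma_dir, gamma_e, gamma_decay = [], [], [], []
    for e, p_emit in zip(scheme.gamma_energies, scheme.gamma_emission_probs):
        emitted = rng.random(n_tot) < p_emit
        ic = np.flatnonzero(~emitted)
        dep[ic, home[ic]] += e  # conversion electron deposits locally
        em = np.flatnonzero(emitted)
        if gamma_transport and len(em):
            gamma_origin.append(positions[em])
            gamma_dir.append(_isotropic(len(em), rng))
            gamma_e.append(np.full(len(em), e))
            gamma_decay.append(em)
    if gamma_transport and gamma_e:
        g_dep, _, _ = transport_batch(
            np.vstack(gamma_origin), np.vstack(gamma_dir),
            np.concatenate(gamma_e), geometry, attenuation, rng,
            **transport_kwargs,
        )
        ids = np.concatenate(gamma_decay)
        np.add.at(dep[:, 0], ids, g_dep[:, 0])
        np.add.at(dep[:, 1], ids, g_dep[:, 1])

    # one hit per (decay, crystal) with non-zero deposit above threshold
    hit_decay, hit_crystal = np.nonzero(dep >= digitizer.threshold_keV)
    hit_time = times[hit_decay]
    hit_e = dep[hit_decay, hit_crystal]
    singles = (
        float(np.sum(hit_crystal == 0) / duration),
        float(np.sum(hit_crystal == 1) / duration),
    )

    pairs, mult = _pair_hits(hit_time, hit_crystal, hit_decay,
                             digitizer.window_ns * 1e-9)
    rows = []
    for i, j in pairs:
        c1_hit, c2_hit = (i, j) if hit_crystal[i] == 0 else (j, i)
        if mult[i] > 1 or mult[j] > 1:
            kind = "multiple"
        elif hit_decay[i] == hit_decay[j]:
            kind = "true"
        else:
            kind = "random"
        rows.append((min(hit_time[i], hit_time[j]),
                     hit_e[c1_hit], hit_e[c2_hit], kind))
    events = pd.DataFrame(rows, columns=["time_s", "e_c1_keV", "e_c2_keV", "kind"])

    content, _ = np.histogram(
        np.concatenate([events["e_c1_keV"], events["e_c2_keV"]])
        if len(events) else np.empty(0),
        bins=np.arange(DEFAULT_E_MAX + 1) - 0.5,
    )
    spectrum = EnergySpectrum(
        content.astype(float), DEFAULT_E_MAX,
        {"distance": geometry.distance, "convolved": False, "thresholded": False,
         "source": "event_simulator"},
    )
    kinds = events["kind"].value_counts().to_dict() if len(events) else {}
    rates = {k: v / duration for k, v in kinds.items()}
    rates["total"] = len(events) / duration
    return SimulationResult(
        events=events, spectrum=spectrum, duration_s=duration,
        n_decays=(int(counts[0]), int(counts[1])), singles_rates=singles,
        rates=rates,
    )


def count_rate_curve(results: dict) -> dict:
    """Coincidence rate per distance, normalized to the ``d = 0`` run."""
    if 0.0 not in {float(d) for d in results}:
        raise ValueError("count-rate curve requires the d = 0 run")
    r0 = next(r for d, r in results.items() if float(d) == 0.0)
    if r0.coincidence_rate <= 0:
        raise ValueError("no coincidences at d = 0")
    return {float(d): r.coincidence_rate / r0.coincidence_rate
            for d, r in results.items()}


def restricted_cascade_frequencies(geometry: DetectorGeometry,
                                   scheme: DecayScheme,
                                   attenuation: AttenuationTable,
                                   n_decays: int,
                                   seed=None) -> tuple[dict, int]:
    """Joint cascade-deposit frequencies under the analytic-model restrictions.

    Simulates single decays in the source crystal with real photon transport
    but books each gamma the way the analytic enumeration does: full
    absorption in C1 keys the source-crystal sum, full absorption in C2
    (the photopeak case) keys the detector-crystal sum, and anything else
    (clean escape or a partial/split deposit) contributes nothing.
    Each gamma starts from its own independent uniform position so that the
    per-transition fates are independent, exactly as the enumeration's
    product of marginal probabilities assumes.

    Returns a mapping ``(E_dep_C1, E_dep_C2) -> count`` over all decays
    (coincident or not) and the number of decays.
    """
    rng = np.random.default_rng(seed)
    e_c1 = np.zeros(n_decays)
    e_c2 = np.zeros(n_decays)
    for e, p_emit in zip(scheme.gamma_energies, scheme.gamma_emission_probs):
        emitted = rng.random(n_decays) < p_emit
        e_c1[~emitted] += e
        em = np.flatnonzero(emitted)
        if not len(em):
            continue
        origins = _uniform_in_crystal(geometry, 0, len(em), rng)
        dirs = _isotropic(len(em), rng)
        dep, _, _ = transport_batch(
            origins, dirs, np.full(len(em), e), geometry, attenuation, rng,
        )
        full_c1 = np.abs(dep[:, 0] - e) < _FULL_ABS_TOL
        full_c2 = np.abs(dep[:, 1] - e) < _FULL_ABS_TOL
        e_c1[em[full_c1]] += e
        e_c2[em[full_c2]] += e
    keys1 = np.rint(e_c1).astype(int)
    keys2 = np.rint(e_c2).astype(int)
    joint: dict = {}
    for k1, k2 in zip(keys1, keys2):
        joint[(int(k1), int(k2))] = joint.get((int(k1), int(k2)), 0) + 1
    return joint, n_decays
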
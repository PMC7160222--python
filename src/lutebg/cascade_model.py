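"""Exact enumeration of the ``176Hf`` cascade fates behind a true coincidence.

Every ``176Lu`` decay in the source crystal (C1) launches the beta particle
plus three isomeric transitions.  Each transition meets one of four fates:

* internal conversion (transitions 2 and 3 only) -- the electron deposits
  the transition energy in C1;
* gamma emitted and fully absorbed in C1;
* gamma emitted, escapes C1 and is fully absorbed in the detector crystal
  C2;
* gamma emitted and lost (escapes both crystals, or leaves only a partial
  Compton deposit -- the analytic model books partial deposits as nothing).

Multiplying the per-transition fate probabilities over the 3 x 4 x 4 = 48
combinations, and keeping only those with at least one gamma absorbed in C2
(a *true coincidence*), yields the probability of each discrete cascade
energy ``E_dep`` in each crystal.  The C1 energies shift the beta continuum;
the C2 energies are photopeak lines.  Both maps are marginals of the same
joint, so their sums are equal by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .nuclear_data import DecayScheme, default_decay_scheme
from .photon_mc import AbsorptionProbabilities

__all__ = [
    "FATE_IC",
    "FATE_C1",
    "FATE_C2",
    "FATE_LOST",
    "CascadeOutcome",
    "CoincidenceTable",
    "enumerate_outcomes",
    "coincidence_table",
    "fate_sampling_oracle",
    "rate_proxy",
    "DEPOSIT_KEYS",
]

FATE_IC = "IC"
FATE_C1 = "absorbed_C1"
FATE_C2 = "escaped_absorbed_C2"
FATE_LOST = "escaped_lost"

#: the eight discrete cascade deposit energies (keV) for the default scheme
DEPOSIT_KEYS = (0, 88, 202, 290, 307, 395, 509, 597)


@dataclass(frozen=True)
class CascadeOutcome:
    """One joint fate assignment of the three cascade transitions."""

    fates: tuple[str, str, str]
    probability: float
    e_dep_c1: int
    e_dep_c2: int

    @property
    def is_coincidence(self) -> bool:
        return self.e_dep_c2 > 0


@dataclass
class CoincidenceTable:
    """Deposit-energy -> probability maps for a true coincidence.

    ``c1_probs[E]`` is the probability that a true coincidence deposits the
    beta energy plus ``E`` keV of cascade energy in the source crystal;
    ``c2_probs[E]`` the probability of the ``E`` keV photopeak in the
    detector crystal.  Both sum to the total coincidence probability.
    """

    c1_probs: dict
    c2_probs: dict
    distance: float
    total: float

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"crystal": "C1", "e_dep_keV": e, "probability": p}
            for e, p in sorted(self.c1_probs.items())
        ] + [
            {"crystal": "C2", "e_dep_keV": e, "probability": p}
            for e, p in sorted(self.c2_probs.items())
        ]
        frame = pd.DataFrame(rows)
        frame["distance_cm"] = self.distance
        return frame


def _fate_probabilities(absprobs: AbsorptionProbabilities, scheme: DecayScheme,
                        distance: float) -> list[dict]:
    """Per-transition fate probability maps (each sums to one)."""
    tables = []
    for e, p_emit in zip(scheme.gamma_energies, scheme.gamma_emission_probs):
        p1 = absprobs.p1(e)
        p2 = absprobs.p2(e, distance)
        if not np.isfinite(p2):
            raise ValueError(f"p_C2 undefined for {e} keV at d={distance} cm")
        tables.append({
            FATE_IC: 1.0 - p_emit,
            FATE_C1: p_emit * p1,
            FATE_C2: p_emit * (1.0 - p1) * p2,
            FATE_LOST: p_emit * (1.0 - p1) * (1.0 - p2),
        })
    return tables


def enumerate_outcomes(absprobs: AbsorptionProbabilities, scheme: DecayScheme,
                       distance: float) -> list[CascadeOutcome]:
    """All 48 joint cascade fates with exact probabilities.

    Transition 1 (307 keV) has no IC channel when ``P1 = 1``; its IC fate is
    still enumerated (with probability zero) so the outcome space is always
    the full 4 x 4 x 4 grid restricted to the three per-transition supports.
    """
    tables = _fate_probabilities(absprobs, scheme, distance)
    fates1 = (FATE_C1, FATE_C2, FATE_LOST)  # gamma1 is always emitted
    outcomes = []
    for f1, f2, f3 in product(fates1, tables[1], tables[2]):
        prob = tables[0][f1] * tables[1][f2] * tables[2][f3]
        e_c1 = e_c2 = 0.0
        for fate, e in zip((f1, f2, f3), scheme.gamma_energies):
            if fate in (FATE_IC, FATE_C1):
                e_c1 += e
            elif fate == FATE_C2:
                e_c2 += e
        outcomes.append(CascadeOutcome(
            fates=(f1, f2, f3), probability=prob,
            e_dep_c1=int(round(e_c1)), e_dep_c2=int(round(e_c2)),
        ))
    return outcomes


def _keys(scheme: DecayScheme) -> tuple[int, ...]:
    e1, e2, e3 = (int(round(e)) for e in scheme.gamma_energies)
    return tuple(sorted({0, e1, e2, e3, e2 + e3, e1 + e3, e1 + e2, e1 + e2 + e3}))


def coincidence_table(absprobs: AbsorptionProbabilities, scheme: DecayScheme | None = None,
                      distance: float = 0.0) -> CoincidenceTable:
    """Aggregate the coincidence outcomes into the two deposit-probability maps."""
    scheme = scheme or default_decay_scheme()
    keys = _keys(scheme)
    c1 = {k: 0.0 for k in keys}
    c2 = {k: 0.0 for k in keys}
    total = 0.0
    for out in enumerate_outcomes(absprobs, scheme, distance):
        if not out.is_coincidence:
            continue
        c1[out.e_dep_c1] += out.probability
        c2[out.e_dep_c2] += out.probability
        total += out.probability
    return CoincidenceTable(c1_probs=c1, c2_probs=c2, distance=distance, total=total)


def fate_sampling_oracle(absprobs: AbsorptionProbabilities, scheme: DecayScheme,
                         distance: float, n: int, seed=None) -> CoincidenceTable:
    """Empirical coincidence table from categorical fate sampling.

    Draws the same per-transition fate probabilities ``n`` times (no
    geometry, no transport) and tallies the deposit maps; an independent
    Monte Carlo cross-check of the exact enumeration.
    """
    if n < 10_000:
        raise ValueError("oracle needs at least 1e4 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tables = _fate_probabilities(absprobs, scheme, distance)
    order = (FATE_IC, FATE_C1, FATE_C2, FATE_LOST)
    e_c1 = np.zeros(n)
    e_c2 = np.zeros(n)
    for table, e in zip(tables, scheme.gamma_energies):
        probs = np.array([table[f] for f in order])
        draw = rng.choice(4, size=n, p=probs)
        e_c1 += np.where(draw <= 1, e, 0.0)
        e_c2 += np.where(draw == 2, e, 0.0)
    coinc = e_c2 > 0
    keys = _keys(scheme)
    c1 = {k: 0.0 for k in keys}
    c2 = {k: 0.0 for k in keys}
    for k in keys:
        c1[k] = float(np.sum(coinc & (np.rint(e_c1).astype(int) == k)) / n)
        c2[k] = float(np.sum(coinc & (np.rint(e_c2).astype(int) == k)) / n)
    return CoincidenceTable(c1_probs=c1, c2_probs=c2, distance=distance,
                            total=float(coinc.mean()))


def rate_proxy(tables: dict) -> dict:
    """Relative coincidence rate vs distance from the analytic tables.

    ``tables`` maps distance (cm) -> :class:`CoincidenceTable`.  The total
    coincidence probability at each distance, normalized by the value at
    ``d = 0``, tracks the measured coincidence count rate.
    """
    if 0.0 not in {float(d) for d in tables}:
        raise ValueError("rate proxy requires the d = 0 table")
    t0 = next(t for d, t in tables.items() if float(d) == 0.0)
    if t0.total <= 0:
        raise ValueError("degenerate configuration: zero coincidence "
                         "probability at d = 0")
    return {float(d): t.total / t0.total for d, t in tables.items()}
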
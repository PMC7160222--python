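import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lutebg.cascade_model import (
    coincidence_table,
    enumerate_outcomes,
    fate_sampling_oracle,
    rate_proxy,
)
from lutebg.nuclear_data import default_decay_scheme
from lutebg.photon_mc import AbsorptionProbabilities

from reference_tables import DISTANCES, PRINTED_RTOL, REFERENCE_C1, REFERENCE_C2


def random_absprobs(p1s, p2s):
    energies = (307.0, 202.0, 88.0)
    return AbsorptionProbabilities(
        energies=energies, distances=(0.0,),
        p_c1={e: p for e, p in zip(energies, p1s)},
        p_c2={e: {0.0: p} for e, p in zip(energies, p2s)},
    )


unit = st.floats(0.0, 1.0, allow_nan=False)
prob_triplet = st.tuples(unit, unit, unit)


class TestEnumeration:
    def test_outcome_space_and_completeness(self, ref_absprobs, scheme):
        outcomes = enumerate_outcomes(ref_absprobs, scheme, 0.0)
        assert len(outcomes) == 48
        assert sum(o.probability for o in outcomes) == pytest.approx(1.0, abs=1e-12)
        assert all(o.probability >= 0 for o in outcomes)

    def test_deposit_keys(self, ref_absprobs, scheme):
        table = coincidence_table(ref_absprobs, scheme, 0.0)
        assert set(table.c1_probs) == {0, 88, 202, 290, 307, 395, 509, 597}
        assert table.c1_probs[597] == 0.0  # all three kept -> no coincidence
        assert table.c2_probs[0] == 0.0    # a coincidence needs a C2 deposit

    @pytest.mark.parametrize("k", range(len(DISTANCES)))
    def test_reproduces_reference_table(self, ref_absprobs, scheme, k):
        """All printed coincidence probabilities match to 3 significant figures."""
        d = DISTANCES[k]
        table = coincidence_table(ref_absprobs, scheme, d)
        for e, row in REFERENCE_C1.items():
            if row[k] == 0.0:
                assert table.c1_probs[e] == 0.0
            else:
                assert table.c1_probs[e] == pytest.approx(row[k], rel=PRINTED_RTOL)
        for e, row in REFERENCE_C2.items():
            if row[k] == 0.0:
                assert table.c2_probs[e] == 0.0
            else:
                assert table.c2_probs[e] == pytest.approx(row[k], rel=PRINTED_RTOL)

    def test_zero_reach_means_zero_table(self, scheme):
        probs = random_absprobs((0.5, 0.6, 0.7), (0.0, 0.0, 0.0))
        table = coincidence_table(probs, scheme, 0.0)
        assert table.total == 0.0
        assert all(v == 0.0 for v in table.c1_probs.values())
        assert all(v == 0.0 for v in table.c2_probs.values())

    def test_missing_energy_raises(self, scheme):
        probs = AbsorptionProbabilities(
            energies=(307.0,), distances=(0.0,),
            p_c1={307.0: 0.6}, p_c2={307.0: {0.0: 0.2}},
        )
        with pytest.raises(KeyError):
            coincidence_table(probs, scheme, 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(p1s=prob_triplet, p2s=prob_triplet, emis=prob_triplet)
    def test_marginal_equality_property(self, p1s, p2s, emis):
        """Both deposit maps are marginals of one joint: their sums agree."""
        scheme = default_decay_scheme(
            gamma_emission_probs=(1.0, emis[1], emis[2])
        )
        table = coincidence_table(random_absprobs(p1s, p2s), scheme, 0.0)
        s1 = sum(table.c1_probs.values())
        s2 = sum(table.c2_probs.values())
        assert abs(s1 - s2) <= 1e-14
        assert abs(s1 - table.total) <= 1e-14
        assert 0.0 <= table.total <= 1.0 + 1e-12
        assert all(v >= 0.0 for v in table.c1_probs.values())

    def test_entries_monotone_in_distance(self, ref_absprobs, scheme):
        tables = [coincidence_table(ref_absprobs, scheme, d) for d in DISTANCES]
        for e in REFERENCE_C1:
            vals = [t.c1_probs[e] for t in tables]
            assert all(a >= b for a, b in zip(vals, vals[1:]))
        for e in REFERENCE_C2:
            vals = [t.c2_probs[e] for t in tables]
            assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestFateSamplingOracle:
    def test_converges_to_enumeration(self, ref_absprobs, scheme):
        n = 1_000_000
        exact = coincidence_table(ref_absprobs, scheme, 0.0)
        emp = fate_sampling_oracle(ref_absprobs, scheme, 0.0, n, seed=17)
        for key, p in exact.c1_probs.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(emp.c1_probs[key] - p) <= 3 * se + 1e-12
        for key, p in exact.c2_probs.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(emp.c2_probs[key] - p) <= 3 * se + 1e-12
        se_tot = np.sqrt(exact.total * (1 - exact.total) / n)
        assert abs(emp.total - exact.total) <= 3 * se_tot

    def test_small_n_rejected(self, ref_absprobs, scheme):
        with pytest.raises(ValueError):
            fate_sampling_oracle(ref_absprobs, scheme, 0.0, 5_000, seed=0)


class TestRateProxy:
    def test_self_normalization_and_monotonicity(self, ref_absprobs, scheme):
        tables = {d: coincidence_table(ref_absprobs, scheme, d) for d in DISTANCES}
        proxy = rate_proxy(tables)
        assert proxy[0.0] == 1.0
        vals = [proxy[d] for d in DISTANCES]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_matches_printed_column_sums(self, ref_absprobs, scheme):
        # independent oracle: ratio of the printed detector-column sums
        tables = {d: coincidence_table(ref_absprobs, scheme, d) for d in DISTANCES}
        proxy = rate_proxy(tables)
        col0 = sum(row[0] for row in REFERENCE_C2.values())
        for k, d in enumerate(DISTANCES[1:], start=1):
            colk = sum(row[k] for row in REFERENCE_C2.values())
            assert proxy[d] == pytest.approx(colk / col0, rel=2 * PRINTED_RTOL)

    def test_requires_zero_distance(self, ref_absprobs, scheme):
        tables = {2.5: coincidence_table(ref_absprobs, scheme, 2.5)}
        with pytest.raises(ValueError):
            rate_proxy(tables)

    def test_degenerate_total_rejected(self, scheme):
        probs = random_absprobs((0.5, 0.6, 0.7), (0.0, 0.0, 0.0))
        tables = {0.0: coincidence_table(probs, scheme, 0.0)}
        with pytest.raises(ValueError):
            rate_proxy(tables)
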
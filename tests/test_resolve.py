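"""OIE_CARE abundance partitioning: the three-step arithmetic and its
proportional-allocation identity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oiecare.matching import OIPGroup, SearchParams, find_oips
from oiecare.resolve import (
    ideal_abundance,
    partition_oip,
    relative_deviation,
    resolve_spectrum,
)


def _make_group(ea_oip, claimants, rng=None):
    """Synthetic OIP group from (ta_i, ea_r, ta_r) triples.

    Builds minimal two-peak matches: the shared peak (index 0) plus a clean
    reference peak (index 1).
    """
    from oiecare.fragments import FragmentIon
    from oiecare.isotopes import ElementalComposition, TheoreticalEnvelope
    from oiecare.matching import EnvelopeMatch

    members = []
    for k, (ta_i, ea_r, ta_r) in enumerate(claimants):
        env = TheoreticalEnvelope(
            mz=np.array([1000.0, 1001.0 + k * 2]),
            rel_abundance=np.array([ta_i, ta_r]),
            charge=1,
            monoisotopic_mz=1000.0,
            base_index=int(np.argmax([ta_i, ta_r])),
        )
        ion = FragmentIon("y", k + 1, "", 1, ElementalComposition(), env)
        match = EnvelopeMatch(
            ion=ion,
            links=np.array([0, k + 1]),
            assigned_abundance=np.array([ea_oip, ea_r]),
            reference_index=1,
        )
        members.append((match, 0))
    return OIPGroup(exp_index=0, observed_abundance=ea_oip, claimants=members)


class TestIdealAbundance:
    def test_printed_y10(self):
        assert ideal_abundance(23.01, 128926.921875, 63.64) == pytest.approx(
            46615.469396, abs=1e-6
        )

    def test_printed_y72(self):
        assert ideal_abundance(55.06, 120854.796875, 100.00) == pytest.approx(
            66542.651159, abs=1e-6
        )

    def test_reference_is_its_own_ideal(self):
        assert ideal_abundance(63.64, 5000.0, 63.64) == pytest.approx(5000.0)

    def test_zero_reference_abundance_rejected(self):
        with pytest.raises(ValueError):
            ideal_abundance(10.0, 100.0, 0.0)


class TestRelativeDeviation:
    def test_printed_value(self):
        rd = relative_deviation(
            480992.3125, [46615.469396, 416521.895787, 66542.651159]
        )
        assert round(rd, 2) == -0.09
        assert rd == pytest.approx(-0.0919188, abs=1e-6)

    def test_zero_when_observed_equals_ideal(self):
        assert relative_deviation(100.0, [60.0, 40.0]) == 0.0

    def test_doubling(self):
        assert relative_deviation(200.0, [50.0, 50.0]) == 1.0


class TestPartitionOip:
    def test_printed_three_ion_group(self):
        group = _make_group(
            480992.3125,
            [
                (23.01, 128926.921875, 63.64),
                (100.00, 281777.062500, 67.65),
                (55.06, 120854.796875, 100.00),
            ],
        )
        res = partition_oip(group)
        assert res.final_abundance[0] == pytest.approx(42330.617979, abs=1e-6)
        assert [round(x) for x in res.ipad_before] == [214, 15, 343]
        assert [round(x) for x in res.ipad_after] == [-2, -9, -5]

    def test_full_precision_rd_not_printed_rd(self):
        """46615.469396 * (1 - 0.09) differs from the correct result: the
        two-decimal RD is display only."""
        group = _make_group(
            480992.3125,
            [
                (23.01, 128926.921875, 63.64),
                (100.00, 281777.062500, 67.65),
                (55.06, 120854.796875, 100.00),
            ],
        )
        res = partition_oip(group)
        assert abs(46615.469396 * (1 - 0.09) - res.final_abundance[0]) > 1.0

    def test_single_claimant_identity(self):
        group = _make_group(7500.0, [(40.0, 9000.0, 80.0)])
        res = partition_oip(group)
        assert res.final_abundance[0] == pytest.approx(7500.0)

    @given(
        st.integers(2, 5),
        st.floats(1e2, 1e7),
        st.integers(0, 2**31 - 1),
    )
    def test_equals_proportional_allocation(self, n, ea_oip, seed):
        rng = np.random.default_rng(seed)
        claimants = [
            (rng.uniform(1, 100), rng.uniform(1e3, 1e6), rng.uniform(20, 100))
            for _ in range(n)
        ]
        res = partition_oip(_make_group(ea_oip, claimants))
        dea = np.array(res.dea)
        oracle = ea_oip * dea / dea.sum()
        np.testing.assert_allclose(res.final_abundance, oracle, rtol=1e-9)

    def test_conservation(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(2, 8)
            ea = rng.uniform(1e3, 1e6)
            claimants = [
                (rng.uniform(1, 100), rng.uniform(1e3, 1e6), rng.uniform(20, 100))
                for _ in range(n)
            ]
            res = partition_oip(_make_group(ea, claimants))
            assert sum(res.final_abundance) == pytest.approx(ea, rel=1e-6)

    def test_linear_operation_count(self):
        for n in (2, 5, 11, 26):
            claimants = [(10.0, 1000.0, 50.0)] * n
            res = partition_oip(_make_group(5000.0 * n, claimants))
            assert res.op_count <= 6 * n

    def test_degenerate_reference_skipped(self):
        group = _make_group(1000.0, [(10.0, 100.0, 50.0), (10.0, 100.0, 50.0)])
        group.claimants[0][0].reference_degenerate = True
        with pytest.raises(ValueError):
            partition_oip(group)


class TestResolveSpectrum:
    def test_worked_example_flips_verdicts(self, worked_matches, product_params):
        from oiecare.matching import assign_references, classify

        matches, spec = worked_matches
        groups = find_oips(matches, spec)
        assign_references(matches, groups)
        before = {m.ion.label: classify(m, product_params, spec) for m in matches}
        assert before == {
            "y10-1+": "non-matching",
            "y20-2+": "matching",
            "y72-7+": "non-matching",
        }
        resolve_spectrum(matches, spec, product_params)
        after = {m.ion.label: m.verdict for m in matches}
        assert set(after.values()) == {"matching"}

    def test_matching_count_never_decreases(self, worked_matches, product_params):
        from oiecare.matching import assign_references, classify

        matches, spec = worked_matches
        groups = find_oips(matches, spec)
        assign_references(matches, groups)
        n_before = sum(
            classify(m, product_params, spec) == "matching" for m in matches
        )
        resolve_spectrum(matches, spec, product_params)
        n_after = sum(m.verdict == "matching" for m in matches)
        assert n_after >= n_before

    def test_no_oips_leaves_matches_untouched(self, overlap_trio, product_params):
        import numpy as np

        from oiecare.matching import CentroidSpectrum, fish_ion

        ion = overlap_trio[0]
        spec = CentroidSpectrum(
            ion.envelope.mz.copy(), ion.envelope.rel_abundance * 1e5
        )
        m = fish_ion(ion, spec, product_params)
        before = m.assigned_abundance.copy()
        results = resolve_spectrum([m], spec, product_params)
        assert results == []
        np.testing.assert_array_equal(m.assigned_abundance, before)

    def test_negative_ipad_gate_leaves_group_unpartitioned(self):
        # observed abundance far below every ideal: all provisional IPADs < 0
        group_claims = [(50.0, 1000.0, 100.0), (50.0, 1000.0, 100.0)]
        group = _make_group(100.0, group_claims)
        matches = [m for m, _ in group.claimants]
        spec_mz = np.array([1000.0, 1002.0, 1004.0])
        from oiecare.matching import CentroidSpectrum

        spec = CentroidSpectrum(spec_mz, np.array([100.0, 1000.0, 1000.0]))
        results = resolve_spectrum(matches, spec, SearchParams(), gate_nonneg=True)
        assert results == []
        forced = resolve_spectrum(matches, spec, SearchParams(), gate_nonneg=False)
        assert len(forced) == 1
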
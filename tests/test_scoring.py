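"""PrSM metrics, PTM localization, decoys and FDR control."""

from dataclasses import dataclass

import numpy as np
import pytest

from oiecare.fragments import FragmentIon, Proteoform, generate_fragments
from oiecare.scoring import (
    bond_coverage,
    fdr_filter,
    group_proteoforms,
    interpreted_fractions,
    make_decoy,
    pmp,
    ptm_score,
    sequence_coverage,
)


def _ion(series, index, charge=1, nl=""):
    from oiecare.isotopes import ElementalComposition, TheoreticalEnvelope

    env = TheoreticalEnvelope(
        mz=np.array([100.0 + index]),
        rel_abundance=np.array([100.0]),
        charge=charge,
        monoisotopic_mz=100.0 + index,
        base_index=0,
    )
    return FragmentIon(series, index, nl, charge, ElementalComposition(), env)


@dataclass
class _Scored:
    rank_score: float


class TestSequenceCoverage:
    def test_full_when_j_plus_k_reaches_n(self):
        assert sequence_coverage(60, 50, 100) == 100.0

    def test_partial(self):
        assert sequence_coverage(40, 30, 100) == 70.0

    def test_zero(self):
        assert sequence_coverage(0, 0, 50) == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            sequence_coverage(0, 0, 0)


class TestBondCoverage:
    def test_all_bonds(self):
        ions = [_ion("b", i) for i in range(1, 10)]
        assert bond_coverage(ions, 10) == 100.0

    def test_single_b(self):
        assert bond_coverage([_ion("b", 3)], 10) == pytest.approx(100 / 9)

    def test_b_and_complementary_y_share_a_bond(self):
        ions = [_ion("b", 3), _ion("y", 7)]
        assert bond_coverage(ions, 10) == pytest.approx(100 / 9)

    def test_monotone_under_growth(self):
        base = [_ion("b", 3)]
        grown = base + [_ion("y", 2)]
        assert bond_coverage(grown, 10) >= bond_coverage(base, 10)


class TestPmp:
    def test_five_percent(self):
        ions = [_ion("b", i) for i in range(1, 11)]
        assert pmp(ions, 200) == 5.0

    def test_zero_and_full(self):
        assert pmp([], 50) == 0.0
        ions = [_ion("y", i) for i in range(1, 51)]
        assert pmp(ions, 50) == 100.0

    def test_charge_collapse(self):
        once = [_ion("b", 4, charge=1)]
        twice = once + [_ion("b", 4, charge=2)]
        assert pmp(once, 100) == pmp(twice, 100)

    def test_neutral_loss_excluded(self):
        assert pmp([_ion("b", 4, nl="H2O")], 100) == 0.0


class TestInterpretedFractions:
    def test_three_of_four_peaks(self, product_params):
        from oiecare.matching import CentroidSpectrum, fish_ion
        from oiecare.isotopes import ElementalComposition, TheoreticalEnvelope

        spec = CentroidSpectrum(
            np.array([100.0, 200.0, 300.0, 400.0]),
            np.array([10.0, 10.0, 10.0, 70.0]),
        )
        env = TheoreticalEnvelope(
            mz=np.array([100.0, 200.0, 300.0]),
            rel_abundance=np.array([100.0, 50.0, 25.0]),
            charge=1,
            monoisotopic_mz=100.0,
            base_index=0,
        )
        ion = FragmentIon("b", 1, "", 1, ElementalComposition(), env)
        m = fish_ion(ion, spec, product_params)
        assert interpreted_fractions([m], spec) == (75.0, 30.0)

    def test_none_linked_is_zero(self, worked_matches):
        matches, spec = worked_matches
        assert interpreted_fractions([], spec) == (0.0, 0.0)


class TestPtmScore:
    def test_single_candidate_charge_collapsed(self):
        ions = [
            _ion("b", 5, charge=1),
            _ion("b", 5, charge=2),
            _ion("b", 7, charge=1),
            _ion("b", 7, charge=3),
            _ion("y", 8, charge=1),
            _ion("y", 8, charge=2),
        ]
        loc = ptm_score(ions, length=10, site=3, candidate_sites=[3])
        assert loc.score == 3

    def test_discriminating_ions_only(self):
        # sites 3 and 8 on n=10: b5 contains 3 but not 8 -> discriminates;
        # b9 contains both -> does not
        ions = [_ion("b", 5), _ion("b", 9)]
        loc = ptm_score(ions, length=10, site=3, candidate_sites=[3, 8])
        assert loc.score == 1

    def test_no_ion_contains_site(self):
        loc = ptm_score([_ion("b", 2)], length=10, site=5, candidate_sites=[5])
        assert loc.score == 0


class TestMakeDecoy:
    def test_reverse(self):
        assert make_decoy("P1", "PEPTIDE", "reverse") == ("DECOY_P1", "EDITPEP")

    def test_random_deterministic(self):
        a = make_decoy("P1", "PEPTIDEKR", "random", seed=42)
        b = make_decoy("P1", "PEPTIDEKR", "random", seed=42)
        assert a == b

    def test_residue_multiset_preserved(self):
        for mode in ("reverse", "random"):
            _, seq = make_decoy("P1", "PEPTIDEKR", mode, seed=3)
            assert sorted(seq) == sorted("PEPTIDEKR")


class TestFdrFilter:
    def test_hand_enumerated_cutoff(self):
        targets = [_Scored(s) for s in (10, 9, 8, 7)]
        decoys = [_Scored(s) for s in (7, 6)]
        accepted, cutoff = fdr_filter(targets, decoys, 0.25)
        assert cutoff == 8
        assert len(accepted) == 3

    def test_no_decoys_accepts_all(self):
        targets = [_Scored(s) for s in (5, 4, 3)]
        accepted, _ = fdr_filter(targets, [], 0.01)
        assert len(accepted) == 3

    def test_dominating_decoys_accept_none(self):
        targets = [_Scored(s) for s in (3, 2, 1)]
        decoys = [_Scored(s) for s in (9, 8, 7)]
        accepted, cutoff = fdr_filter(targets, decoys, 0.1)
        assert accepted == [] and cutoff is None

    def test_calibration_on_simulated_scores(self):
        """Aggregated over >= 200 replicates the empirical FDR among
        accepted PrSMs stays within binomial error of alpha."""
        rng = np.random.default_rng(2024)
        alpha = 0.05
        null_accept = 0
        false_acc = true_acc = 0
        for _ in range(200):
            # null: targets and decoys share one score distribution
            t_null = [_Scored(s) for s in rng.poisson(5, 60)]
            d_null = [_Scored(s) for s in rng.poisson(5, 60)]
            acc, _ = fdr_filter(t_null, d_null, 0.01)
            null_accept += len(acc)
            # signal: most targets shifted upward, a known fraction null
            true_scores = rng.poisson(18, 90)
            false_scores = rng.poisson(5, 10)
            targets = [_Scored(s) for s in true_scores] + [
                _Scored(s) for s in false_scores
            ]
            decoys = [_Scored(s) for s in rng.poisson(5, 100)]
            accepted, cutoff = fdr_filter(targets, decoys, alpha)
            if cutoff is None:
                continue
            false_acc += sum(1 for s in false_scores if s >= cutoff)
            true_acc += sum(1 for s in true_scores if s >= cutoff)
        # essentially nothing survives under the null at alpha 1%
        assert null_accept / 200 < 1.0
        total = false_acc + true_acc
        fdr_hat = false_acc / total
        assert fdr_hat <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / total)


class TestGroupProteoforms:
    def _prsm(self, seq, ptms, scan, ions):
        from oiecare.scoring import PrSM

        pf = Proteoform("P1", seq, ptms)
        return PrSM(
            proteoform=pf,
            spectrum_id=scan,
            matching_ions=ions,
            fished_ions=ions,
            sequence_coverage=50.0,
            bond_coverage=10.0,
            pmp=10.0,
            interpreted_peak_pct=50.0,
            interpreted_abundance_pct=50.0,
        )

    def test_keeps_max_matching_earliest_scan(self):
        ions12 = [_ion("b", i) for i in range(1, 13)]
        ions9 = [_ion("b", i) for i in range(1, 10)]
        prsms = [
            self._prsm("PEPTIDEK", (), "scan3", ions12),
            self._prsm("PEPTIDEK", (), "scan2", ions9),
            self._prsm("PEPTIDEK", (), "scan1", ions12),
        ]
        kept = group_proteoforms(prsms)
        assert len(kept) == 1
        assert kept[0].spectrum_id == "scan1"
        assert kept[0].rank_score == 12

    def test_distinct_ptm_sets_stay_separate(self):
        from oiecare.isotopes import parse_formula

        ac = parse_formula("C2H2O")
        prsms = [
            self._prsm("PEPTIDEK", (), "s1", [_ion("b", 1)]),
            self._prsm("PEPTIDEK", ((8, "ac", ac),), "s2", [_ion("b", 1)]),
        ]
        assert len(group_proteoforms(prsms)) == 2

    def test_empty(self):
        assert group_proteoforms([]) == []


def test_charge_collapse_leaves_metrics_unchanged(myoglobin):
    """Duplicating every matching ion at a new charge changes nothing."""
    ions = [_ion("b", 3), _ion("y", 5), _ion("b", 7)]
    doubled = ions + [_ion(i.series, i.index, charge=9) for i in ions]
    n = 20
    assert pmp(ions, 19) == pmp(doubled, 19)
    assert bond_coverage(ions, n) == bond_coverage(doubled, n)
    a = ptm_score(ions, n, 2, [2, 18])
    b = ptm_score(doubled, n, 2, [2, 18])
    assert a.score == b.score
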
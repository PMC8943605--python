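"""Formula-prediction engine: tolerance policy, enumeration, assignment."""

import numpy as np
import pytest

import simsfilter as sf
from simsfilter.engine import enumerate_candidates_bruteforce

from conftest import random_box

f = sf.parse_formula


class TestTolerancePolicy:
    @pytest.mark.parametrize("mz, expected", [(94.0, 3.0), (200.0, 2.0), (95.0, 2.0)])
    def test_default_segments_and_boundary(self, mz, expected):
        # boundary m/z belongs to the higher (tighter) segment
        assert sf.tolerance_for(mz) == expected

    def test_invalid_policies_rejected(self):
        with pytest.raises(ValueError):
            sf.TolerancePolicy.from_pairs([(95, 3), (90, 2), (None, 1)])
        with pytest.raises(ValueError):
            sf.TolerancePolicy.from_pairs([(95, 3)])  # not open-ended
        with pytest.raises(ValueError):
            sf.TolerancePolicy.from_pairs([(None, -2)])

    def test_constraints_json_round_trip(self, serum_constraints):
        rebuilt = sf.SearchConstraints.from_dict(serum_constraints.to_dict())
        assert rebuilt == serum_constraints


class TestEnumerate:
    def test_methane_in_tiny_cho_box(self):
        c = sf.SearchConstraints(
            ranges=(
                sf.ElementRange("C", 0, 2),
                sf.ElementRange("H", 0, 6),
                sf.ElementRange("O", 0, 1),
            ),
            tolerance=sf.TolerancePolicy.constant(5.0),
            charge=0,
        )
        cands = sf.enumerate_candidates(16.0313, c)
        assert [x.formula for x in cands] == [f("CH4")]

    def test_all_zero_maxima_give_empty(self):
        c = sf.SearchConstraints(
            ranges=(sf.ElementRange("C", 0, 0), sf.ElementRange("H", 0, 0)),
            tolerance=sf.TolerancePolicy.constant(5.0),
            charge=0,
        )
        assert sf.enumerate_candidates(100.0, c) == []

    def test_serum_box_contains_printed_fragment(self, serum_constraints):
        cands = sf.enumerate_candidates(329.1585, serum_constraints)
        assert f("C15H22N4O3Na") in [x.formula for x in cands]

    def test_sorted_by_abs_ppm(self, serum_constraints):
        cands = sf.enumerate_candidates(329.1585, serum_constraints)
        errs = [abs(x.error_ppm) for x in cands]
        assert errs == sorted(errs)

    def test_soundness_all_candidates_within_tolerance(self, serum_constraints):
        for mz in (150.0, 329.1585, 700.123):
            tol = sf.tolerance_for(mz, serum_constraints.tolerance)
            for cand in sf.enumerate_candidates(mz, serum_constraints):
                assert abs(cand.error_ppm) <= tol

    def test_self_consistency_exact_mass_hits_at_zero_ppm(self, serum_constraints):
        target = f("C24H44N6O5Na")
        mz = sf.ion_mz(target, +1)
        cands = sf.enumerate_candidates(mz, serum_constraints)
        assert cands and cands[0].formula == target
        assert cands[0].error_ppm == pytest.approx(0.0, abs=1e-9)

    def test_mass_bounded_maximum_unbounded_aluminium_search(self):
        # Al/O/H species with open-ended counts, as on a foil substrate
        c = sf.SearchConstraints(
            ranges=(
                sf.ElementRange("Al", 0, None),
                sf.ElementRange("O", 0, None),
                sf.ElementRange("H", 0, None),
            ),
            charge=-1,
        )
        mz = sf.ion_mz(f("Al2O4H"), -1)
        cands = sf.enumerate_candidates(mz, c)
        assert f("Al2O4H") in [x.formula for x in cands]

    def test_monotone_in_tolerance_and_ranges(self, serum_constraints):
        mz = 329.1585
        tight = sf.enumerate_candidates(mz, serum_constraints)
        loose_tol = sf.SearchConstraints(
            ranges=serum_constraints.ranges,
            tolerance=sf.TolerancePolicy.constant(5.0),
            charge=+1,
        )
        wider = sf.enumerate_candidates(mz, loose_tol)
        assert set(map(str, (c.formula for c in tight))) <= set(
            map(str, (c.formula for c in wider))
        )
        grown = sf.SearchConstraints(
            ranges=serum_constraints.ranges + (sf.ElementRange("P", 0, 2),),
            tolerance=serum_constraints.tolerance,
            charge=+1,
        )
        wider_box = sf.enumerate_candidates(mz, grown)
        assert set(map(str, (c.formula for c in tight))) <= set(
            map(str, (c.formula for c in wider_box))
        )

    def test_plausibility_flags_only_remove(self, serum_constraints):
        mz = 329.1585
        base = sf.enumerate_candidates(329.1585, serum_constraints)
        filtered = sf.enumerate_candidates(
            mz, serum_constraints, require_nonneg_dbe=True
        )
        assert set(map(str, (c.formula for c in filtered))) <= set(
            map(str, (c.formula for c in base))
        )
        assert all(c.dbe_value >= 0 for c in filtered)

    def test_pruned_search_equals_bruteforce_oracle(self):
        """The pruned descent returns exactly the brute-force Cartesian set
        on 100 random small constraint boxes."""
        rng = np.random.default_rng(20260922)
        checked_nonempty = 0
        for _ in range(100):
            mz, constraints = random_box(rng)
            fast = sf.enumerate_candidates(mz, constraints)
            slow = enumerate_candidates_bruteforce(mz, constraints)
            assert [str(c.formula) for c in fast] == [str(c.formula) for c in slow]
            checked_nonempty += bool(fast)
        assert checked_nonempty >= 30  # the comparison must actually bite


class TestAssignPeaklist:
    def test_two_assigned_one_unassigned(self, three_peak_fixture):
        pl, constraints, inside = three_peak_fixture
        aset = sf.assign_peaklist(pl, constraints)
        assert set(aset.candidates) == {"p0", "p1"}
        assert aset.unassigned == ["p2"]
        for pid, truth in zip(["p0", "p1"], inside):
            assert truth in [c.formula for c in aset.candidates[pid]]

    def test_shifted_peaks_all_unassigned(self, three_peak_fixture):
        pl, constraints, _ = three_peak_fixture
        shifted = sf.PeakList(
            peaks=[
                sf.Peak(id=p.id, mz=p.mz * (1 + 10e-6), total_intensity=p.total_intensity)
                for p in pl.peaks
            ],
            polarity=pl.polarity,
        )
        aset = sf.assign_peaklist(shifted, constraints)
        assert not aset.candidates and len(aset.unassigned) == 3

    def test_deterministic(self, three_peak_fixture):
        pl, constraints, _ = three_peak_fixture
        a1 = sf.assign_peaklist(pl, constraints)
        a2 = sf.assign_peaklist(pl, constraints)
        assert a1.to_dataframe().equals(a2.to_dataframe())

    def test_empty_peaklist(self):
        aset = sf.assign_peaklist(
            sf.PeakList(),
            sf.SearchConstraints(ranges=(sf.ElementRange("C", 0, 5),), charge=-1),
        )
        assert not aset.candidates and not aset.unassigned

    def test_every_peak_appears_exactly_once(self, three_peak_fixture):
        pl, constraints, _ = three_peak_fixture
        aset = sf.assign_peaklist(pl, constraints)
        assert sorted(aset.peak_ids) == sorted(pl.ids())


class TestFilterUnique:
    def test_single_candidate_retained_multi_dropped(self, serum_constraints):
        # p_many sits at the crowded serum m/z; p_one is an exact unique hit
        pl = sf.PeakList(
            peaks=[
                sf.Peak(id="p_many", mz=329.1585, total_intensity=10.0),
                sf.Peak(
                    id="p_one",
                    mz=sf.ion_mz(f("C4H8NO"), +1),
                    total_intensity=10.0,
                ),
            ],
            polarity="positive",
        )
        tight = sf.SearchConstraints(
            ranges=(
                sf.ElementRange("C", 0, 30),
                sf.ElementRange("H", 0, 60),
                sf.ElementRange("N", 0, 5),
                sf.ElementRange("O", 0, 5),
            ),
            tolerance=sf.TolerancePolicy.constant(2.0),
            charge=+1,
        )
        aset = sf.assign_peaklist(pl, tight)
        assert aset.n_candidates("p_one") == 1
        uniq = sf.filter_unique(aset)
        assert "p_one" in uniq.candidates and uniq.candidates["p_one"][0].unique
        if aset.n_candidates("p_many") > 1:
            assert "p_many" in uniq.unassigned

    def test_widening_tolerance_never_grows_unique_set(self, three_peak_fixture):
        pl, constraints, _ = three_peak_fixture
        sizes = []
        for ppm in (1.0, 5.0, 20.0):
            c = sf.SearchConstraints(
                ranges=constraints.ranges,
                tolerance=sf.TolerancePolicy.constant(ppm),
                charge=constraints.charge,
            )
            uniq = sf.filter_unique(sf.assign_peaklist(pl, c))
            sizes.append(len(uniq.candidates))
        assert sizes == sorted(sizes, reverse=True)
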
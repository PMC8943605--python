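"""Database annotation, peptide database, DBE-vs-carbon tables."""

import math

import pytest

import simsfilter as sf
from simsfilter.engine import CandidateAssignment

f = sf.parse_formula


def _aset_from_ions(formulas, charge):
    """Assignment set with one exact candidate per ion composition."""
    aset = sf.AssignmentSet(polarity="positive" if charge > 0 else "negative")
    for i, text in enumerate(formulas):
        formula = f(text)
        mz = sf.ion_mz(formula, charge)
        aset.candidates[f"p{i}"] = [
            CandidateAssignment(
                peak_id=f"p{i}",
                formula=formula,
                theoretical_mz=mz,
                error_ppm=0.0,
                dbe_value=sf.dbe(formula),
                carbon_number=formula.get("C", 0),
                unique=True,
            )
        ]
    return aset


class TestCompoundDatabase:
    def test_load_fixture(self, tmp_path):
        path = tmp_path / "db.csv"
        path.write_text(
            "formula,class,name\n"
            "C16H32O2,FA,FA 16:0\nC18H34O2,FA,FA 18:1\nC27H46O,ST,cholesterol\n"
            "C42H82NO8P,GP,PC 34:1\nC16H32O2,FA,isomer of palmitic\n"
        )
        db = sf.load_database(path)
        assert len(db) == 5
        hits = db.lookup(f("C16H32O2"))
        assert len(hits) == 2  # isomers all returned

    def test_round_trip_write_load(self, tmp_path):
        db = sf.bundled_lipid_database()
        out = tmp_path / "copy.csv"
        db.to_csv(out)
        back = sf.load_database(out)
        assert len(back) == len(db)
        assert [r.formula for r in back.records] == [r.formula for r in db.records]

    def test_malformed_formula_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("formula,class\nC6H6,ok\n!!bad,x\n")
        with pytest.raises(ValueError, match="row 3"):
            sf.load_database(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("formula,class\n")
        with pytest.warns(UserWarning):
            db = sf.load_database(path)
        assert len(db) == 0


class TestMatchDatabase:
    def test_deprotonated_fatty_acid_matches_via_minus_h(self):
        aset = _aset_from_ions(["C16H31O2"], charge=-1)
        db = sf.CompoundDatabase(
            [sf.CompoundRecord(formula=f("C16H32O2"), class_label="FA", name="FA 16:0")]
        )
        out = sf.match_database(aset, db, adducts=["-H"])
        hits = out.candidates["p0"][0].db_matches
        assert len(hits) == 1
        assert hits[0].adduct == "-H" and hits[0].record.name == "FA 16:0"

    def test_empty_database_no_matches(self):
        aset = _aset_from_ions(["C16H31O2"], charge=-1)
        out = sf.match_database(aset, sf.CompoundDatabase(), adducts=["-H"])
        assert out.candidates["p0"][0].db_matches == ()

    def test_adduct_none_does_not_match_protonated_ion(self):
        aset = _aset_from_ions(["C16H31O2"], charge=-1)
        db = sf.CompoundDatabase(
            [sf.CompoundRecord(formula=f("C16H32O2"), class_label="FA")]
        )
        out = sf.match_database(aset, db, adducts=["none"])
        assert out.candidates["p0"][0].db_matches == ()

    def test_sodiated_lookup_and_row_order_invariance(self):
        aset = _aset_from_ions(["C42H82NO8PNa"], charge=+1)
        recs = [
            sf.CompoundRecord(formula=f("C42H82NO8P"), class_label="GP", name="PC 34:1"),
            sf.CompoundRecord(formula=f("C27H46O"), class_label="ST"),
        ]
        for order in (recs, recs[::-1]):
            out = sf.match_database(aset, sf.CompoundDatabase(order), adducts=["+H", "+Na"])
            hits = out.candidates["p0"][0].db_matches
            assert [h.adduct for h in hits] == ["+Na"]

    def test_impossible_adduct_skipped_silently(self):
        aset = _aset_from_ions(["C2H5"], charge=+1)  # no Na to subtract
        db = sf.CompoundDatabase([sf.CompoundRecord(formula=f("C2H4"), class_label="x")])
        out = sf.match_database(aset, db, adducts=["+H", "+Na"])
        assert [h.adduct for h in out.candidates["p0"][0].db_matches] == ["+H"]

    def test_polarity_inconsistent_adducts_rejected(self):
        aset = _aset_from_ions(["C16H31O2"], charge=-1)
        with pytest.raises(ValueError):
            sf.match_database(aset, sf.CompoundDatabase(), adducts=["+H"], polarity="negative")

    def test_round_trip_record_to_ion_and_back(self):
        """Every database record reached through an allowed adduct is
        matched back to itself."""
        db = sf.bundled_lipid_database()
        for rec in db.records[:10]:
            for adduct, delta, charge in (
                ("+H", f("H"), +1),
                ("+Na", f("Na"), +1),
                ("-H", None, -1),
            ):
                ion = rec.formula - f("H") if adduct == "-H" else rec.formula + delta
                if any(n < 0 for n in ion.values()):
                    continue
                aset = _aset_from_ions([str(ion)], charge=charge)
                out = sf.match_database(aset, db, adducts=[adduct])
                matched = [h.record for h in out.candidates["p0"][0].db_matches]
                assert rec in matched


class TestPeptideDatabase:
    def test_single_residue_counts(self):
        db = sf.build_peptide_database(1)
        assert len(db) == 20
        assert db.n_distinct_formulas() == 19  # Leu/Ile share a formula

    def test_glycine_record_formula(self):
        db = sf.build_peptide_database(1)
        gly = [r for r in db.records if r.name == "G"]
        assert len(gly) == 1 and gly[0].formula == f("C2H5NO2")

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_counts_match_multiset_closed_form(self, k):
        expected = sum(math.comb(19 + j, j) for j in range(1, k + 1))
        assert len(sf.build_peptide_database(k)) == expected

    def test_dipeptide_masses_are_residue_sums_plus_water(self):
        db = sf.build_peptide_database(2)
        water = sf.monoisotopic_mass(f("H2O"))
        residue_mass = {
            aa: sf.monoisotopic_mass(res) for aa, res in sf.AMINO_ACID_RESIDUES.items()
        }
        for rec in db.records:
            expected = sum(residue_mass[aa] for aa in rec.name) + water
            assert sf.monoisotopic_mass(rec.formula) == pytest.approx(expected, abs=1e-9)

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            sf.build_peptide_database(0)


class TestDbeVsCarbonTable:
    def test_homologous_sulfonate_series_constant_dbe(self):
        series = [f"C{12 + n}H{17 + 2 * n}SO3" for n in range(6)]
        aset = _aset_from_ions(series, charge=-1)
        table = sf.dbe_vs_carbon_table(aset)
        assert table["DBE"].nunique() == 1
        assert sorted(table["C"]) == list(range(12, 18))
        neutral = sf.dbe_vs_carbon_table(aset, dbe_convention="neutral")
        assert neutral["DBE"].nunique() == 1
        assert neutral["DBE"].iloc[0] == table["DBE"].iloc[0] - 0.5

    def test_saturated_fatty_acid_series_dbe_three_halves(self):
        series = [f"C{n}H{2 * n - 1}O2" for n in (12, 14, 16, 18)]
        table = sf.dbe_vs_carbon_table(_aset_from_ions(series, charge=-1))
        assert set(table["DBE"]) == {1.5}

    def test_empty_assignment_gives_empty_table(self):
        table = sf.dbe_vs_carbon_table(sf.AssignmentSet())
        assert len(table) == 0

    def test_plot_writes_file(self, tmp_path):
        series = [f"C{n}H{2 * n - 1}O2" for n in (12, 16)]
        table = sf.dbe_vs_carbon_table(_aset_from_ions(series, charge=-1))
        out = tmp_path / "dbe.png"
        sf.plot_dbe_vs_carbon(table, out)
        assert out.exists() and out.stat().st_size > 0
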
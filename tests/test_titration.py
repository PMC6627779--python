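import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quenchbind import (
    AbsorbanceReading,
    TitrationSeries,
    concentration_from_absorbance,
    correct_inner_filter,
    quench_percent,
    read_titration_table,
    write_titration_table,
)


class TestInnerFilter:
    @pytest.mark.parametrize(
        "f_obs,a_ex,a_em,expected",
        [
            (100.0, 0.0, 0.0, 100.0),
            (100.0, 0.1, 0.1, 100.0 * 10**0.1),
            (50.0, 0.2, 0.0, 50.0 * 10**0.1),
        ],
    )
    def test_correction_values(self, f_obs, a_ex, a_em, expected):
        assert correct_inner_filter(f_obs, a_ex, a_em) == pytest.approx(expected, rel=1e-12)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            correct_inner_filter(100.0, -0.1, 0.0)

    @given(
        a_ex=st.floats(0, 2),
        a_em=st.floats(0, 2),
        bump=st.floats(1e-6, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_absorbance_and_identity(self, a_ex, a_em, bump):
        base = correct_inner_filter(100.0, a_ex, a_em)
        assert base >= 100.0
        assert correct_inner_filter(100.0, a_ex + bump, a_em) > base
        assert correct_inner_filter(100.0, a_ex, a_em + bump) > base
        if a_ex + a_em == 0:
            assert base == 100.0


class TestQuenchPercent:
    @pytest.mark.parametrize(
        "f0,f,expected", [(100, 100, 0), (100, 75, 25), (200, 90, 55)]
    )
    def test_values(self, f0, f, expected):
        assert quench_percent(f0, f) == pytest.approx(expected)

    @given(x=st.floats(0, 1), f0=st.floats(1e-3, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_fractional_quench_identity(self, x, f0):
        """quench_percent(f0, f0*(1-x)) == 100x, exactly in [0, 100]."""
        df = quench_percent(f0, f0 * (1 - x))
        assert df == pytest.approx(100 * x, rel=1e-9, abs=1e-9)
        assert 0 <= df <= 100 + 1e-9

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ValueError):
            quench_percent(0.0, 10.0)


class TestBeerLambert:
    @pytest.mark.parametrize(
        "a,eps,l,expected",
        [
            (0.0, 16500, 1.0, 0.0),
            (0.165, 16500, 1.0, 1.0e-5),
            (0.389, 38915, 1.0, 0.389 / 38915),
        ],
    )
    def test_values(self, a, eps, l, expected):
        reading = AbsorbanceReading(absorbance=a, epsilon=eps, path_length=l)
        assert concentration_from_absorbance(reading) == pytest.approx(expected, rel=1e-12)

    def test_zero_epsilon_rejected(self):
        with pytest.raises(ValueError):
            concentration_from_absorbance(AbsorbanceReading(0.1, 0.0, 1.0))


class TestSeriesValidation:
    def test_non_monotone_ligand_grid_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            TitrationSeries(4e-6, 288.0, [0, 2e-6, 1e-6], [100, 90, 80])

    def test_f0_requires_zero_ligand_point(self):
        s = TitrationSeries(4e-6, 288.0, [1e-6, 2e-6, 3e-6], [90, 85, 80])
        with pytest.raises(ValueError, match="F0"):
            s.f0

    def test_double_correction_rejected(self):
        s = TitrationSeries(
            4e-6, 288.0, [0, 1e-6, 2e-6], [100, 90, 80],
            absorbance_ex=[0.01, 0.02, 0.03], absorbance_em=[0.0, 0.0, 0.0],
        )
        corrected = s.with_inner_filter_correction()
        assert corrected.inner_filter_applied
        with pytest.raises(ValueError, match="already applied"):
            corrected.with_inner_filter_correction()


class TestTableIO:
    def test_round_trip_bit_identical(self, titration_csv, tmp_path):
        s1 = read_titration_table(titration_csv)
        assert len(s1) == 16
        path2 = tmp_path / "round.csv"
        write_titration_table(s1, path2)
        s2 = read_titration_table(path2)
        assert np.array_equal(s1.ligand_total, s2.ligand_total)
        assert np.array_equal(s1.intensity, s2.intensity)
        assert s1.protein_conc == s2.protein_conc
        assert s1.temperature == s2.temperature

    def test_missing_intensity_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# protein_conc=4e-6\n# temperature=288\nligand_total\n0\n1\n")
        with pytest.raises(ValueError, match="intensity"):
            read_titration_table(p)

    def test_micromolar_dialect_scales_to_molar(self, tmp_path):
        p = tmp_path / "um.csv"
        p.write_text(
            "# protein_conc=4\n# temperature=288\n# units=uM\n"
            "ligand_total,intensity\n0,100\n1,95\n2,91\n"
        )
        s = read_titration_table(p)
        assert s.ligand_total == pytest.approx([0.0, 1e-6, 2e-6])
        assert s.protein_conc == pytest.approx(4e-6)

    def test_inner_filter_applied_at_load(self, tmp_path):
        p = tmp_path / "abs.csv"
        p.write_text(
            "# protein_conc=4e-6\n# temperature=288\n"
            "ligand_total,intensity,a_ex,a_em\n0,100,0.1,0.1\n1e-6,90,0.1,0.1\n2e-6,80,0.1,0.1\n"
        )
        s = read_titration_table(p)
        assert s.inner_filter_applied
        assert s.intensity[0] == pytest.approx(100 * 10**0.1)
        raw = read_titration_table(p, apply_inner_filter=False)
        assert not raw.inner_filter_applied
        assert raw.intensity[0] == 100

    def test_dilution_correction_rescales_intensity(self, tmp_path):
        p = tmp_path / "dil.csv"
        p.write_text(
            "# protein_conc=4e-6\n# temperature=288\n# initial_volume=3000\n"
            "ligand_total,intensity,added_volume\n0,100,0\n1e-6,90,30\n2e-6,80,60\n"
        )
        off = read_titration_table(p)
        on = read_titration_table(p, correct_dilution=True)
        assert np.array_equal(off.intensity, [100, 90, 80])
        assert on.intensity == pytest.approx([100, 90 * 3030 / 3000, 80 * 3060 / 3000])
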
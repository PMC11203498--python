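"""Set metrics (Valid/Unique/Novel), Wasserstein distance, property
profiles, good ranges and activity classes."""

import numpy as np
import pytest

from targen.metrics import (GOOD_RANGES, PropertyProfile, classify_activity,
                            good_range_report, novel_fraction,
                            property_profile, unique_fraction, valid_fraction,
                            wasserstein_1d)


def sorted_quantile_wasserstein(a, b):
    """Independent oracle: W1 of two equal-size samples is the mean absolute
    difference of their order statistics."""
    a, b = np.sort(a), np.sort(b)
    assert len(a) == len(b)
    return float(np.mean(np.abs(a - b)))


class TestValid:
    def test_counts_unparsable_strings(self):
        frac, P = valid_fraction(["CCO", "c1ccccc1", "C(((", "CC"])
        assert frac == 0.75
        assert P == ["CCO", "c1ccccc1", "CC"]

    def test_duplicates_do_not_matter(self):
        frac, _ = valid_fraction(["CCO"] * 5)
        assert frac == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            valid_fraction([])


class TestUnique:
    def test_tiny_multiset(self):
        assert unique_fraction(["CCO", "CCO", "CCC"], c=3) == pytest.approx(2 / 3)

    def test_all_distinct(self):
        mols = [f"{'C' * n}O" for n in range(1, 21)]
        assert unique_fraction(mols, c=20) == 1.0

    def test_counting_oracle_with_known_multiplicities(self):
        """100 distinct molecules, 10 of them duplicated once: 100/110."""
        distinct = [f"{'C' * n}N" for n in range(1, 101)]
        pool = distinct + distinct[:10]
        assert unique_fraction(pool, c=110) == pytest.approx(100 / 110)

    def test_canonicalization_collapses_aliases(self):
        assert unique_fraction(["CCO", "OCC", "C(C)O"], c=3) == pytest.approx(1 / 3)

    def test_shortfall_reported(self):
        with pytest.raises(ValueError, match="2"):
            unique_fraction(["CCO", "CC"], c=1000)


class TestNovel:
    def test_basic_fraction(self):
        assert novel_fraction(["CCO", "CC", "CCC"], ["CC"]) == pytest.approx(2 / 3)

    def test_fully_known_and_fully_novel(self):
        assert novel_fraction(["CCO", "CC"], ["CC", "CCO", "CCC"]) == 0.0
        assert novel_fraction(["CCO", "CC"], ["c1ccccc1"]) == 1.0

    def test_invariant_to_smiles_aliasing(self):
        """Spelling either side differently cannot change novelty."""
        P = ["OCC", "C(C)C"]
        X = ["CCO"]
        assert novel_fraction(P, X) == novel_fraction(["CCO", "CCC"], ["OCC"])
        assert novel_fraction(P, X) == 0.5

    def test_empty_valid_set_rejected(self):
        with pytest.raises(ValueError):
            novel_fraction([], ["CC"])


class TestWasserstein:
    def test_identity_and_translation(self, rng):
        a = rng.normal(size=40)
        assert wasserstein_1d(a, a) == 0.0
        assert wasserstein_1d([0.0], [3.0]) == pytest.approx(3.0)
        assert wasserstein_1d(a, a + 1.7) == pytest.approx(1.7)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=50)
        assert wasserstein_1d(a, b) == pytest.approx(wasserstein_1d(b, a))

    def test_matches_sorted_quantile_oracle(self, rng):
        a, b = rng.normal(size=50), rng.normal(loc=0.5, size=50)
        assert wasserstein_1d(a, b) == pytest.approx(
            sorted_quantile_wasserstein(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [1.0])


class TestPropertyProfile:
    def test_ethanol_textbook_values(self):
        p = property_profile("CCO")
        assert p.MW == pytest.approx(46.07, abs=0.01)
        assert p.HBD == 1 and p.HBA == 1
        assert 0 <= p.QED <= 1 and 1 <= p.SA <= 10

    def test_benzene_has_no_hydrogen_bonding(self):
        p = property_profile("c1ccccc1")
        assert p.HBD == 0 and p.HBA == 0

    def test_deterministic(self):
        assert property_profile("CC(=O)O") == property_profile("CC(=O)O")

    def test_unparsable_rejected(self):
        with pytest.raises(ValueError):
            property_profile("((((")


class TestGoodRanges:
    inside = PropertyProfile(MW=350, TPSA=60, LogP=2, HBD=1, HBA=3,
                             QED=0.6, SA=3)

    def test_single_molecule_inside_all_ranges(self):
        report = good_range_report([self.inside])
        assert all(v == 100.0 for v in report.values())
        assert set(report) == set(GOOD_RANGES)

    def test_heavy_molecule_fails_only_mw(self):
        heavy = PropertyProfile(MW=600, TPSA=60, LogP=2, HBD=1, HBA=3,
                                QED=0.6, SA=3)
        report = good_range_report([heavy])
        assert report["MW"] == 0.0 and report["TPSA"] == 100.0

    def test_percentage_arithmetic(self):
        heavy = PropertyProfile(MW=600, TPSA=60, LogP=2, HBD=1, HBA=3,
                                QED=0.6, SA=3)
        report = good_range_report([self.inside] * 7 + [heavy] * 3)
        assert report["MW"] == pytest.approx(70.0)


class TestActivityClasses:
    @pytest.mark.parametrize("value, cls", [
        (5.9, "low"), (6.0, "middle"), (6.9, "middle"), (7.0, "high"),
        (7.5, "high"), (7.999, "high"), (8.0, "ultra-high"),
        (8.1, "ultra-high"),
    ])
    def test_boundaries_are_left_closed(self, value, cls):
        assert classify_activity(value) == cls

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_activity(float("nan"))
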
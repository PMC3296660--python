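"""Amino-acid composition percentages and length-bias correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protlen import (
    STANDARD_AA,
    BiasProfile,
    ProteinRecord,
    SyntheticSpec,
    composition_percent,
    group_bias_summary,
    length_bias_correlations,
    simulate_proteome,
)


class TestCompositionPercent:
    def test_single_residue(self):
        v = composition_percent("CCCC")
        assert v.percent["C"] == 100.0
        assert sum(v.percent.values()) == pytest.approx(100.0)
        assert v.n_standard == 4 and v.n_ambiguous == 0

    def test_uniform_sequence(self):
        v = composition_percent("ACDEFGHIKLMNPQRSTVWY")
        assert all(p == pytest.approx(5.0) for p in v.percent.values())

    def test_ambiguous_excluded_from_denominator(self):
        v = composition_percent("CXC")
        assert v.percent["C"] == 100.0
        assert v.n_standard == 2 and v.n_ambiguous == 1

    def test_all_ambiguous_is_undefined(self):
        v = composition_percent("XXXB")
        assert v.percent is None and v.n_standard == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            composition_percent("")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYXBZ", min_size=1, max_size=300))
    @settings(max_examples=150, deadline=None)
    def test_percentages_sum_to_100(self, seq):
        v = composition_percent(seq)
        if v.percent is not None:
            assert sum(v.percent.values()) == pytest.approx(100.0, abs=1e-9)
            assert all(p >= 0 for p in v.percent.values())
        assert v.n_standard + v.n_ambiguous == len(seq)


def _boosted_baseline(*residues, level=0.05):
    """Baseline frequencies with the given residues raised to ``level`` so a
    linear length tilt stays positive over the realistic length range."""
    from protlen import BASELINE_AA_FREQS

    base = dict(BASELINE_AA_FREQS)
    others = [aa for aa in base if aa not in residues]
    spare = 1.0 - level * len(residues)
    total_others = sum(base[aa] for aa in others)
    out = {aa: base[aa] * spare / total_others for aa in others}
    out.update({aa: level for aa in residues})
    return out


class TestLengthBiasCorrelations:
    def test_programmed_negative_cysteine_trend(self):
        spec = SyntheticSpec(
            species_code="BIA",
            model="gamma_free",
            params_dict={"shape": 2.3, "rate": 0.006},
            n=2000,
            seed=17,
            min_length=30,
            baseline_freqs=_boosted_baseline("C", "E"),
            aa_bias={"C": -2e-5, "E": 2e-5},
        )
        proteome, _ = simulate_proteome(spec)
        prof = length_bias_correlations(proteome)
        assert prof.r_by_aa["C"] < -0.3
        assert prof.r_by_aa["E"] > 0.3

    def test_null_bias_bound(self):
        spec = SyntheticSpec(
            species_code="NUL", n=2000, seed=23, min_length=30, aa_bias={}
        )
        proteome, _ = simulate_proteome(spec)
        prof = length_bias_correlations(proteome)
        assert all(abs(r) < 0.1 for r in prof.r_by_aa.values())

    def test_programmed_sign_pattern_recovered(self):
        spec = SyntheticSpec(
            species_code="SGN",
            n=3000,
            seed=29,
            min_length=30,
            baseline_freqs=_boosted_baseline("C", "D", "E", "K"),
            aa_bias={"D": 2e-5, "E": 2e-5, "C": -1.5e-5, "K": -2e-5},
        )
        proteome, _ = simulate_proteome(spec)
        prof = length_bias_correlations(proteome)
        assert prof.r_by_aa["D"] > 0.1 and prof.r_by_aa["E"] > 0.1
        assert prof.r_by_aa["C"] < -0.1 and prof.r_by_aa["K"] < -0.1

    def test_too_few_proteins_rejected(self):
        recs = [ProteinRecord(id=f"r{i}", sequence="MKV" * (i + 1)) for i in range(2)]
        with pytest.raises(ValueError):
            length_bias_correlations(recs)

    def test_constant_lengths_rejected(self):
        recs = [ProteinRecord(id=f"r{i}", sequence="MKVA") for i in range(5)]
        with pytest.raises(ValueError):
            length_bias_correlations(recs)

    def test_absent_residue_is_missing(self):
        recs = [
            ProteinRecord(id="a", sequence="AAAA"),
            ProteinRecord(id="b", sequence="AAKAA"),
            ProteinRecord(id="c", sequence="AAKKAA"),
        ]
        prof = length_bias_correlations(recs)
        assert np.isnan(prof.r_by_aa["W"])  # tryptophan never observed


class TestGroupBiasSummary:
    @staticmethod
    def _profile(value):
        return BiasProfile(r_by_aa={aa: value for aa in STANDARD_AA}, n=100)

    def test_mean_and_se(self):
        profiles = {"sp1": self._profile(0.2), "sp2": self._profile(0.4)}
        df = group_bias_summary(profiles, {"sp1": "g", "sp2": "g"})
        row = df[(df.group == "g") & (df.aa == "C")].iloc[0]
        assert row.mean_r == pytest.approx(0.3)
        assert row.se_r == pytest.approx(0.1)
        assert row.n_species == 2

    def test_singleton_group_has_no_se(self):
        df = group_bias_summary({"sp1": self._profile(0.25)}, {"sp1": "g"})
        row = df.iloc[0]
        assert row.mean_r == pytest.approx(0.25) and np.isnan(row.se_r)

    def test_order_invariance(self):
        profiles = {f"sp{i}": self._profile(0.1 * i) for i in range(5)}
        grouping = {f"sp{i}": "g" for i in range(5)}
        a = group_bias_summary(profiles, grouping)
        b = group_bias_summary(dict(reversed(list(profiles.items()))), grouping)
        assert a.equals(b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_bias_summary({}, {})
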
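import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mthet import peak_calls
from mthet.errors import NoSignalError, SchemaError
from mthet.peak_calls import (
    CallTable,
    SpecimenMeta,
    call_site,
    call_trace_set,
    confirm_replicates,
    count_het_offspring,
    count_het_tissues,
    proportion_from_heights,
    read_percent_csv,
)
from mthet.trace_sim import MixtureState, simulate_trace_set

from .conftest import POSITIONS_16S, POSITIONS_COI, make_mixture


class TestProportionFromHeights:
    def test_average_of_two_reads(self):
        props = proportion_from_heights({"T": 60, "C": 40}, {"T": 80, "C": 20})
        assert props.proportions["T"] == pytest.approx(0.70)
        assert props.proportions["C"] == pytest.approx(0.30)
        assert not props.single_read

    def test_single_read_flag(self):
        props = proportion_from_heights({"T": 100, "C": 0}, None)
        assert props.proportions["T"] == pytest.approx(1.0)
        assert props.single_read

    def test_published_ratio(self):
        # heights in ratio 78.4:21.6 on both reads reproduce the printed row
        props = proportion_from_heights({"T": 784, "C": 216}, {"T": 78.4, "C": 21.6})
        assert props.proportions["T"] == pytest.approx(0.784)
        assert props.proportions["C"] == pytest.approx(0.216)

    def test_all_zero_heights(self):
        with pytest.raises(NoSignalError):
            proportion_from_heights({"A": 0, "C": 0, "G": 0, "T": 0}, None)

    def test_read_swap_symmetry(self):
        f, r = {"T": 55, "C": 45}, {"T": 91, "C": 9}
        a = proportion_from_heights(f, r).proportions
        b = proportion_from_heights(r, f).proportions
        assert a == pytest.approx(b)

    @given(
        ht=st.floats(1.0, 1e4),
        hc=st.floats(0.0, 1e4),
        scale=st.floats(0.1, 10.0),
    )
    def test_proportions_sum_to_one_and_scale_invariant(self, ht, hc, scale):
        p1 = proportion_from_heights({"T": ht, "C": hc}, {"T": ht * scale, "C": hc * scale})
        assert sum(p1.proportions.values()) == pytest.approx(1.0)
        p2 = proportion_from_heights({"T": ht * scale, "C": hc * scale}, {"T": ht, "C": hc})
        assert p1.proportions == pytest.approx(p2.proportions)


class TestCallSite:
    def test_published_heteroplasmic_adult(self):
        call = call_site({"T": 0.935, "C": 0.065}, min_minor_fraction=0.05)
        assert call.heteroplasmic
        assert (call.major_base, call.minor_base) == ("T", "C")

    def test_homoplasmic(self):
        call = call_site({"C": 1.0}, min_minor_fraction=0.05)
        assert not call.heteroplasmic
        assert call.major_base == "C" and call.minor_base is None

    def test_tie_major_by_base_order(self):
        call = call_site({"T": 0.5, "A": 0.5})
        assert call.heteroplasmic
        assert call.major_base == "A" and call.minor_base == "T"

    def test_baseline_veto(self):
        call = call_site({"T": 0.8, "C": 0.2}, baseline_ok=False)
        assert not call.heteroplasmic

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            call_site({"T": 1.0}, min_minor_fraction=0.6)

    @given(minor=st.floats(0.0, 0.5), thr_lo=st.floats(0.01, 0.2), thr_hi=st.floats(0.2, 0.49))
    def test_threshold_monotonicity(self, minor, thr_lo, thr_hi):
        props = {"T": 1 - minor, "C": minor}
        lo = call_site(props, min_minor_fraction=min(thr_lo, thr_hi))
        hi = call_site(props, min_minor_fraction=max(thr_lo, thr_hi))
        assert lo.heteroplasmic or not hi.heteroplasmic  # hi het implies lo het


class TestCallerSimulatorRoundTrip:
    @pytest.mark.parametrize("fraction", [0.5, 0.65, 0.784, 0.95, 1.0])
    def test_noiseless_traces_recover_mixture_exactly(self, two_haplotypes, fraction):
        mix = MixtureState({"H1": fraction, "H2": 1 - fraction})
        ts = simulate_trace_set(list(two_haplotypes), mix, noise_sd=0, baseline_sd=0)
        call = [c for c in call_trace_set(ts) if c.position == 5][0]
        assert call.proportion_major == pytest.approx(max(fraction, 1 - fraction), abs=1e-9)

    def test_baseline_criterion_suppresses_faint_second_peak(self, two_haplotypes):
        # minor fraction 6% of amplitude, baseline level 2.5% -> 3x rule vetoes
        mix = make_mixture(0.94)
        ts = simulate_trace_set(list(two_haplotypes), mix, noise_sd=0, baseline_sd=0)
        for read in ts.reads.values():
            read.baseline_level = 0.025 * read.heights.max()
        call = [c for c in call_trace_set(ts) if c.position == 5][0]
        assert not call.heteroplasmic


class TestConfirmReplicates:
    def _one_site_table(self, het: bool, pair=("T", "C")) -> CallTable:
        t = CallTable()
        props = {pair[0]: 0.8, pair[1]: 0.2} if het else {pair[0]: 1.0}
        t.add(SpecimenMeta("s1", "adult", sex="female"),
              [call_site(props, specimen="s1", position=365)])
        return t

    def test_both_heteroplasmic_confirmed(self):
        out = confirm_replicates(self._one_site_table(True), self._one_site_table(True))
        assert out.calls[0].confirmed is True

    def test_het_in_one_replicate_unconfirmed(self):
        out = confirm_replicates(self._one_site_table(True), self._one_site_table(False))
        assert out.calls[0].confirmed is False
        assert out.calls[0].heteroplasmic  # kept, not dropped

    def test_both_homoplasmic_confirmed(self):
        out = confirm_replicates(self._one_site_table(False), self._one_site_table(False))
        assert out.calls[0].confirmed is True

    def test_different_base_pair_not_confirmed(self):
        out = confirm_replicates(self._one_site_table(True, ("T", "C")),
                                 self._one_site_table(True, ("T", "A")))
        assert out.calls[0].confirmed is False

    def test_coverage_warning(self):
        t1 = self._one_site_table(True)
        out = confirm_replicates(t1, CallTable())
        assert out.warnings


class TestCounts:
    def test_p7_five_of_seven(self, table_16s):
        assert count_het_offspring(table_16s, "MbraAG-P7", POSITIONS_16S) == (5, 7)

    def test_m3_zero_of_two(self, table_16s):
        assert count_het_offspring(table_16s, "MbraAG-M3", POSITIONS_16S) == (0, 2)

    def test_unknown_mother(self, table_16s):
        with pytest.raises(KeyError):
            count_het_offspring(table_16s, "MbraAG-NOPE", POSITIONS_16S)

    def test_5dv_two_het_tissues(self, table_coi_families):
        n_het, n_total = count_het_tissues(table_coi_families, "MbraAG-5DV", POSITIONS_COI)
        assert n_het == 2
        het = {s for s in table_coi_families.specimens
               if s.startswith("MbraAG-5DV") and table_coi_families.is_het(s, POSITIONS_COI)}
        assert het == {"MbraAG-5DV-stomach", "MbraAG-5DV-eye"}

    def test_4d2v_het_everywhere_except_four(self, table_coi_families):
        hom = {s.rsplit("-", 1)[1] for s in table_coi_families.specimens
               if s.startswith("MbraAG-4D2V") and not table_coi_families.is_het(s, POSITIONS_COI)}
        assert hom == {"pleopod", "muscle", "stomach", "nerve"}

    def test_simulated_homoplasmic_family(self, two_haplotypes):
        from mthet.peak_calls import call_family
        from mthet.trace_sim import ScenarioConfig, simulate_family

        cfg = ScenarioConfig(scenario="maternal_strict", n_eggs=6, seed=0)
        fam = simulate_family(list(two_haplotypes), MixtureState({"H1": 1.0}), cfg)
        table = call_family(fam, [5])
        assert count_het_offspring(table, fam.truth["mother"], [5]) == (0, 6)


class TestPercentCSV:
    def test_schema_error_on_negative_pct(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "specimen,role,sex,tissue,mother_id,population,position,base1,base2,pct1,pct2\n"
            "s1,adult,female,,,pop,10,T,C,-5,105\n"
        )
        with pytest.raises(SchemaError, match="row 2"):
            read_percent_csv(path)

    def test_schema_error_on_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("specimen,role\ns1,adult\n")
        with pytest.raises(SchemaError, match="missing columns"):
            read_percent_csv(path)

    def test_rounding_in_printed_percentages_absorbed(self, tmp_path):
        # pairs that do not sum to exactly 100 (as printed) are renormalised
        path = tmp_path / "t.csv"
        path.write_text(
            "specimen,role,sex,tissue,mother_id,population,position,base1,base2,pct1,pct2\n"
            "s1,adult,male,,,pop,264,T,C,74,26.3\n"
        )
        table = read_percent_csv(path)
        call = table.calls[0]
        assert call.proportion_major + call.proportion_minor == pytest.approx(1.0)
        assert call.heteroplasmic

    def test_fixture_proportions_sum_to_one(self, all_tables):
        for table in all_tables.values():
            for c in table.calls:
                assert c.proportion_major + c.proportion_minor == pytest.approx(1.0, abs=1e-9)
                assert c.proportion_major >= c.proportion_minor


class TestBoldAnnotationReproduction:
    """Default-threshold calls must match the published heteroplasmy marks."""

    def test_16s_heteroplasmic_adults_match_bold_rows(self, table_16s):
        het_somatic = {
            m.specimen
            for m in table_16s.somatic_records()
            if table_16s.is_het(m.specimen, POSITIONS_16S)
        }
        assert het_somatic == {
            "MbraAG-M26-pleopod",
            "MbraAG-P6-pleopod",
            "MbraAG-P6-setae",
            "MbraAG-P7-pleopod",
            "MbraAG-5IN-pleopod",
        }

    def test_coi_adults_all_heteroplasmic(self, table_coi_adults):
        # the published adult table lists exactly the 16 double-peak adults
        for meta in table_coi_adults.specimens.values():
            assert table_coi_adults.is_het(meta.specimen, POSITIONS_COI)

    def test_sex_split_of_coi_adults(self, table_coi_adults):
        males = [m for m in table_coi_adults.specimens.values() if m.sex == "male"]
        females = [m for m in table_coi_adults.specimens.values() if m.sex == "female"]
        assert (len(males), len(females)) == (4, 12)


@settings(max_examples=200)
@given(
    minor=st.floats(0.0, 0.5),
    thresholds=st.tuples(st.floats(0.01, 0.49), st.floats(0.01, 0.49)),
)
def test_monotonicity_threshold_never_adds_calls(minor, thresholds):
    lo, hi = sorted(thresholds)
    props = {"T": 1 - minor, "C": minor}
    n_lo = int(call_site(props, min_minor_fraction=lo).heteroplasmic)
    n_hi = int(call_site(props, min_minor_fraction=hi).heteroplasmic)
    assert n_hi <= n_lo
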
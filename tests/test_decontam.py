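import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lbqc.decontam import (
    call_contaminants,
    classify_contaminants,
    combined_pvalue,
    frequency_pvalue,
    identify_ntconly,
    prevalence_pvalue,
    shift_report,
    subtract_contaminants,
)
from lbqc.io import CountTable, ProportionTable, Role, to_proportions

from conftest import make_records


def _ptable(cols: dict, index=None) -> ProportionTable:
    df = pd.DataFrame(cols)
    df.index = index or [f"o{i}" for i in range(len(df))]
    return ProportionTable(df)


class TestIdentifyNTConly:
    def _setup(self):
        # o0: specimens only; o1: NTC + specimen; o2: NTC only
        counts = CountTable(
            pd.DataFrame(
                {"S1": [5, 3, 0], "S2": [5, 0, 0], "N1": [0, 1, 9]},
                index=["o0", "o1", "o2"],
            )
        )
        return to_proportions(counts), make_records(n_spec=2, n_ntc=1)

    def test_presence_rule(self):
        p, recs = self._setup()
        rep = identify_ntconly(p, recs)
        calls = rep.table["is_contaminant"]
        assert not calls["o0"] and calls["o1"] and not calls["o2"]
        assert rep.max_ntc_proportion("o0") == 0.0
        assert rep.max_ntc_proportion("o1") == pytest.approx(0.1)

    def test_requires_ntc(self):
        p, recs = self._setup()
        only_spec = [r for r in recs if r.role == Role.SPECIMEN]
        with pytest.raises(ValueError, match="NTC"):
            identify_ntconly(p, only_spec)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n_otu, n_spec, n_ntc = 30, 12, 4
            mat = rng.integers(0, 3, size=(n_otu, n_spec + n_ntc))
            mat[:, 0] += 1  # avoid degenerate columns
            ids = [f"S{i}" for i in range(n_spec)] + [f"N{i}" for i in range(n_ntc)]
            counts = CountTable(
                pd.DataFrame(mat, index=[f"o{i}" for i in range(n_otu)],
                             columns=ids)
            )
            recs = make_records(n_spec=0, n_ntc=0)
            from lbqc.io import SampleRecord

            recs = [
                SampleRecord(s, Role.SPECIMEN, 1000.0, 1.0, "r", "w", f"G{s}")
                for s in ids[:n_spec]
            ] + [SampleRecord(s, Role.NTC, 0.0) for s in ids[n_spec:]]
            p = to_proportions(counts)
            rep = identify_ntconly(p, recs)
            for i, otu in enumerate(counts.otu_ids):
                expect = any(mat[i, j] > 0 for j in range(n_spec)) and any(
                    mat[i, n_spec + j] > 0 for j in range(n_ntc)
                )
                assert bool(rep.table["is_contaminant"][otu]) == expect


class TestFrequencyPvalue:
    def test_exact_inverse_proportionality_gives_zero(self):
        c = np.array([10.0, 20, 50, 100, 200, 500])
        f = 100.0 / c
        assert frequency_pvalue(f, c) == 0.0

    def test_constant_frequency_gives_one(self):
        c = np.array([10.0, 20, 50, 100, 200, 500])
        f = np.full(6, 0.05)
        assert frequency_pvalue(f, c) == pytest.approx(1.0)

    def test_too_few_positive_samples_is_missing(self):
        assert math.isnan(frequency_pvalue([0.1, 0.2, 0.0], [10, 20, 30]))

    def test_scale_invariance_in_concentration(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(10, 1000, size=15)
        f = rng.uniform(0.001, 0.2, size=15)
        assert frequency_pvalue(f, c) == pytest.approx(
            frequency_pvalue(f, 1000.0 * c), rel=1e-9
        )

    def test_simulated_contaminant_detected(self):
        """f = 1000/c with mild lognormal noise: p < 0.05 nearly always."""
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            c = rng.uniform(2e3, 2e5, size=20)  # keeps f = 1000/c below 1
            f = (1000.0 / c) * rng.lognormal(0.0, 0.1, size=20)
            if frequency_pvalue(f, c) < 0.05:
                hits += 1
        assert hits / n_rep >= 0.95


class TestPrevalencePvalue:
    def test_no_ntc_presence_cannot_support_contamination(self):
        assert prevalence_pvalue(0, 5, 3, 10) == pytest.approx(1.0)

    def test_exact_hypergeometric_value(self):
        assert prevalence_pvalue(2, 2, 0, 8) == pytest.approx(1 / 45, abs=1e-12)

    def test_equal_prevalence_is_not_significant(self):
        assert prevalence_pvalue(5, 10, 50, 100) > 0.5

    def test_matches_hypergeometric_enumeration(self):
        """Exact tail agreement for every table with n_ntc + n_spec <= 12."""
        for n_ntc in range(1, 7):
            for n_spec in range(1, 13 - n_ntc):
                for k_ntc in range(n_ntc + 1):
                    for k_spec in range(n_spec + 1):
                        k = k_ntc + k_spec
                        # P(X >= k_ntc), X ~ Hypergeom(N, n_ntc, k)
                        expected = float(
                            stats.hypergeom.sf(
                                k_ntc - 1, n_ntc + n_spec, k, n_ntc
                            )
                        )
                        got = prevalence_pvalue(k_ntc, n_ntc, k_spec, n_spec)
                        assert got == pytest.approx(expected, abs=1e-10)


class TestCombinedPvalue:
    def test_two_null_pvalues_stay_null(self):
        assert combined_pvalue(1.0, 1.0) == pytest.approx(1.0)

    def test_fisher_combination_value(self):
        x = -2 * (math.log(0.01) + math.log(0.01))
        expected = math.exp(-x / 2) * (1 + x / 2)  # chi2_4 survival
        assert combined_pvalue(0.01, 0.01) == pytest.approx(expected, rel=1e-9)
        assert combined_pvalue(0.01, 0.01) == pytest.approx(1.02e-3, rel=0.01)

    def test_missing_evidence_passes_through(self):
        assert combined_pvalue(math.nan, 0.03) == pytest.approx(0.03)
        assert combined_pvalue(0.2, math.nan) == pytest.approx(0.2)
        assert math.isnan(combined_pvalue(math.nan, math.nan))


class TestCallContaminants:
    def _report(self, p):
        table = pd.DataFrame(
            {
                "max_ntc_proportion": [0.1],
                "p_freq": [p],
                "p_prev": [np.nan],
                "p_comb": [p],
                "is_contaminant": [False],
            },
            index=["o0"],
        )
        from lbqc.io import ContaminantReport

        return ContaminantReport("combined", table, 0.1)

    def test_strict_threshold_boundary(self):
        assert call_contaminants(self._report(0.05), 0.1).contaminants == ["o0"]
        assert call_contaminants(self._report(0.1), 0.1).contaminants == []
        assert call_contaminants(self._report(0.05), 0.0).contaminants == []


class TestSubtraction:
    def _simple(self):
        p = _ptable({"S1": [0.5, 0.3, 0.2], "N1": [0.5, 0.25, 0.25]})
        recs = make_records(n_spec=1, n_ntc=1)
        rep = identify_ntconly(p, recs)
        return p, recs, rep

    def test_subtraction_and_renormalization(self):
        p, recs, rep = self._simple()
        # all OTUs present in both -> all flagged, m = NTC column
        out = subtract_contaminants(p, rep, recs)
        # pre-closure: (0, .05, 0) but renormalized -> (0, 1, 0)
        assert out.data["S1"].tolist() == pytest.approx([0.0, 1.0, 0.0])
        # NTC column untouched
        assert out.data["N1"].tolist() == pytest.approx([0.5, 0.25, 0.25])

    def test_clipping_at_zero_without_renormalization(self):
        p, recs, rep = self._simple()
        out = subtract_contaminants(p, rep, recs, renormalize=False)
        assert out.data["S1"].tolist() == pytest.approx([0.0, 0.05, 0.0])
        assert not out.closed

    def test_random_tables_contract(self):
        """No negatives; unflagged OTUs unchanged pre-closure; columns
        re-close to one."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_otu = rng.integers(4, 20)
            mat = rng.integers(0, 20, size=(n_otu, 6))
            mat[0] += 1
            ids = ["S1", "S2", "S3", "S4", "N1", "N2"]
            counts = CountTable(
                pd.DataFrame(mat, index=[f"o{i}" for i in range(n_otu)],
                             columns=ids)
            )
            from lbqc.io import SampleRecord

            recs = [
                SampleRecord(s, Role.SPECIMEN, 1000.0, 1.0, "r", "w", f"G{s}")
                for s in ids[:4]
            ] + [SampleRecord(s, Role.NTC, 0.0) for s in ids[4:]]
            p = to_proportions(counts)
            rep = identify_ntconly(p, recs)
            raw = subtract_contaminants(p, rep, recs, renormalize=False)
            closed = subtract_contaminants(p, rep, recs, renormalize=True)
            flagged = rep.table["is_contaminant"].to_numpy()
            m = rep.table["max_ntc_proportion"].to_numpy()
            for s in ids[:4]:
                orig = p.data[s].to_numpy()
                got = raw.data[s].to_numpy()
                assert (got >= 0).all()
                assert got[~flagged] == pytest.approx(orig[~flagged])
                assert got[flagged] == pytest.approx(
                    np.maximum(orig[flagged] - m[flagged], 0.0)
                )
                total = closed.data[s].sum()
                if s not in closed.degenerate:
                    assert total == pytest.approx(1.0, abs=1e-9)


class TestShiftReport:
    def _taxonomy(self):
        return {
            "o0": ("Staphylococcus", "aureus"),
            "o1": ("Staphylococcus", "epidermidis"),
            "o2": ("Moraxella", "catarrhalis"),
        }

    def test_no_removal_means_zero_fractions(self):
        p = _ptable({"S1": [0.2, 0.3, 0.5], "S2": [0.1, 0.1, 0.8]})
        recs = shift_report(p, {"none": p}, self._taxonomy())
        for rec in recs:
            assert rec.fraction_completely_removed["none"] == 0.0
            assert rec.mean_after["none"] == pytest.approx(rec.mean_before)

    def test_partial_removal_fraction(self):
        cols_before = {f"S{i}": [0.5, 0.0, 0.5] for i in range(4)}
        before = _ptable(cols_before)
        after_cols = {
            "S0": [0.0, 0.0, 1.0],
            "S1": [0.0, 0.0, 1.0],
            "S2": [0.0, 0.0, 1.0],
            "S3": [0.4, 0.0, 0.6],
        }
        after = _ptable(after_cols)
        recs = shift_report(before, {"m": after}, self._taxonomy())
        staph = {r.taxon: r for r in recs}["Staphylococcus"]
        assert staph.n_positive == 4
        assert staph.fraction_completely_removed["m"] == pytest.approx(0.75)

    def test_absent_genus_omitted(self):
        p = _ptable({"S1": [0.0, 0.0, 1.0]})
        recs = shift_report(p, {"m": p}, self._taxonomy())
        assert {r.taxon for r in recs} == {"Moraxella"}
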
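"""Genotype table parsing, marker maps and the cohort QC filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gametecross import (
    GenotypeMatrix,
    MarkerMap,
    informative_markers,
    qc_filter,
    read_genotype_table,
    write_genotype_table,
)
from gametecross._codes import ALLELE_A, ALLELE_B, HET, MISSING


def _write(tmp_path, text, name="g.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGenotypeTable:
    def test_basic_parse_counts_missing(self, tmp_path):
        p = _write(tmp_path, "id,m1,m2,m3\ns1,A,B,NA\ns2,B,B,A\n")
        gm = read_genotype_table(p, "haploid")
        assert gm.sample_ids == ["s1", "s2"]
        assert (gm.calls == MISSING).sum() == 1
        assert gm.calls[0, 0] == ALLELE_A and gm.calls[1, 0] == ALLELE_B

    def test_heterozygous_token_in_haploid_rejected(self, tmp_path):
        p = _write(tmp_path, "id,m1,m2\ns1,A,AB\n")
        with pytest.raises(ValueError, match="heterozygous"):
            read_genotype_table(p, "haploid")

    def test_unknown_token_reported(self, tmp_path):
        p = _write(tmp_path, "id,m1,m2\ns1,A,Z\n")
        with pytest.raises(ValueError, match="Z"):
            read_genotype_table(p, "haploid")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicated sample"):
            GenotypeMatrix(["s1", "s1"], ["m1"], np.zeros((2, 1), np.int8), "haploid")
        with pytest.raises(ValueError, match="duplicated marker"):
            GenotypeMatrix(["s1"], ["m1", "m1"], np.zeros((1, 2), np.int8), "haploid")

    def test_round_trip_byte_identical(self, tmp_path):
        text = "id,m1,m2,m3\ns1,A,B,NA\ns2,AB,B,A\n"
        p = _write(tmp_path, text)
        gm = read_genotype_table(p, "diploid")
        out = tmp_path / "out.csv"
        write_genotype_table(gm, out)
        assert out.read_text() == text

    def test_tab_delimiter_autodetected(self, tmp_path):
        p = _write(tmp_path, "id\tm1\tm2\ns1\tA\tB\n")
        gm = read_genotype_table(p, "haploid")
        assert gm.marker_ids == ["m1", "m2"]


class TestMarkerMap:
    def test_sorted_and_relative_positions(self):
        tab = pd.DataFrame(
            {
                "marker_id": ["b", "a", "c"],
                "chromosome": ["2R", "1R", "1R"],
                "position_bp": [50, 100, 20],
            }
        )
        mm = MarkerMap(tab, {"1R": 200, "2R": 100})
        assert list(mm.marker_ids) == ["c", "a", "b"]  # (chromosome, position) order
        assert mm.table["rel_position"].tolist() == [0.1, 0.5, 0.5]
        assert mm.genome_length_bp == 300
        assert mm.rel_length("1R") == pytest.approx(2 / 3)

    def test_undeclared_chromosome_length_rejected(self):
        tab = pd.DataFrame({"marker_id": ["a"], "chromosome": ["3R"], "position_bp": [5]})
        with pytest.raises(ValueError, match="3R"):
            MarkerMap(tab, {"1R": 100})


def _qc_matrix(n_markers=50):
    """Six nuclei for one individual; nucleus 1 has call rate 0.04."""
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 2, size=(6, n_markers)).astype(np.int8)
    calls[0, 2:] = MISSING  # 2/50 called = 0.04 < 0.10
    ids = [f"i1_n{j}" for j in range(1, 7)]
    return GenotypeMatrix(ids, [f"m{j}" for j in range(n_markers)], calls, "haploid"), ids


class TestQCFilter:
    def test_low_call_rate_nucleus_dropped_individual_kept(self):
        gm, ids = _qc_matrix()
        sets, report = qc_filter(gm, {"i1": ids})
        assert len(sets) == 1 and sets[0].n_nuclei == 5
        assert ids[0] not in sets[0].nuclei_ids
        assert (report.removals["reason"] == "call_rate").sum() == 1

    def test_individual_with_two_passing_nuclei_dropped(self):
        gm, ids = _qc_matrix()
        sets, report = qc_filter(gm, {"i1": ids[:4]})  # nuclei n1..n4, n1 fails -> 3 kept
        assert len(sets) == 1
        sets, report = qc_filter(gm, {"i1": ids[:3]})  # n1 fails -> only 2 left
        assert sets == []
        assert (report.removals["reason"] == "too_few_nuclei").sum() == 1

    def test_boundary_call_rate_exactly_threshold_retained(self):
        calls = np.full((3, 10), MISSING, dtype=np.int8)
        calls[:, 0] = ALLELE_A  # call rate exactly 0.10
        gm = GenotypeMatrix(["n1", "n2", "n3"], [f"m{j}" for j in range(10)], calls, "haploid")
        sets, _ = qc_filter(gm, {"i1": ["n1", "n2", "n3"]}, max_missing=1.0)
        assert len(sets) == 1 and sets[0].n_nuclei == 3

    def test_boundary_missing_exactly_half_retained(self):
        calls = np.zeros((3, 10), dtype=np.int8)
        calls[:, :5] = MISSING  # joint missing fraction exactly 0.50
        gm = GenotypeMatrix(["n1", "n2", "n3"], [f"m{j}" for j in range(10)], calls, "haploid")
        sets, _ = qc_filter(gm, {"i1": ["n1", "n2", "n3"]})
        assert len(sets) == 1

    def test_excess_missing_individual_dropped(self):
        calls = np.zeros((3, 10), dtype=np.int8)
        calls[:, :6] = MISSING  # 0.6 > 0.5
        gm = GenotypeMatrix(["n1", "n2", "n3"], [f"m{j}" for j in range(10)], calls, "haploid")
        sets, report = qc_filter(gm, {"i1": ["n1", "n2", "n3"]})
        assert sets == []
        assert (report.removals["reason"] == "missing_fraction").sum() == 1

    def test_empty_input_warns(self):
        gm = GenotypeMatrix([], ["m1"], np.zeros((0, 1), np.int8), "haploid")
        with pytest.warns(UserWarning, match="empty"):
            sets, _ = qc_filter(gm, {})
        assert sets == []

    def test_idempotent(self):
        gm, ids = _qc_matrix()
        sets1, _ = qc_filter(gm, {"i1": ids})
        kept = sets1[0].nuclei_ids
        gm2 = gm.subset_samples(kept)
        sets2, report2 = qc_filter(gm2, {"i1": kept})
        assert sets2[0].nuclei_ids == kept
        assert len(report2.removals) == 0
        np.testing.assert_array_equal(sets1[0].calls, sets2[0].calls)

    def test_cohort_survival_matches_binomial_expectation(self):
        """700 individuals, each nucleus failing independently: survivors within CI.

        A nucleus 'fails' with probability q = 0.38 (call rate 0.04, below the
        10% threshold); an individual survives if at least 3 of its 6 nuclei
        pass. The expected survival P(Binom(6, 1-q) >= 3) is computed
        analytically and the realised count must fall within 4 standard
        errors.
        """
        rng = np.random.default_rng(99)
        q = 0.38
        n_ind, n_mark = 700, 50
        fails = rng.random((n_ind, 6)) < q
        calls = np.zeros((n_ind * 6, n_mark), dtype=np.int8)
        calls[fails.ravel(), 2:] = MISSING  # failed: 2/50 = 0.04
        calls[~fails.ravel(), 45:] = MISSING  # passing: 45/50 = 0.90
        ids = [f"i{k}_n{j}" for k in range(n_ind) for j in range(6)]
        gm = GenotypeMatrix(ids, [f"m{j}" for j in range(n_mark)], calls, "haploid")
        nuclei_of = {f"i{k}": ids[6 * k : 6 * k + 6] for k in range(n_ind)}
        sets, _ = qc_filter(gm, nuclei_of)
        p_survive = 1.0 - sps.binom.cdf(2, 6, 1 - q)
        se = np.sqrt(p_survive * (1 - p_survive) / n_ind)
        assert abs(len(sets) / n_ind - p_survive) < 4 * se


class TestInformativeMarkers:
    def _setup(self):
        mm = MarkerMap(
            pd.DataFrame(
                {
                    "marker_id": ["m1", "m2", "m3", "m4"],
                    "chromosome": ["1R"] * 4,
                    "position_bp": [10, 20, 30, 40],
                }
            ),
            {"1R": 100},
        )
        calls = np.array([[HET, ALLELE_A, HET, MISSING]], dtype=np.int8)
        dip = GenotypeMatrix(["i1"], ["m1", "m2", "m3", "m4"], calls, "diploid")
        return mm, dip

    def test_heterozygous_markers_selected_in_order(self):
        mm, dip = self._setup()
        assert informative_markers(dip, "i1", mm) == ["m1", "m3"]

    def test_absent_individual_is_hard_error(self):
        mm, dip = self._setup()
        with pytest.raises(KeyError):
            informative_markers(dip, "nobody", mm)

    def test_homozygous_individual_warns_empty(self):
        mm, _ = self._setup()
        calls = np.array([[ALLELE_A, ALLELE_B, ALLELE_A, ALLELE_B]], dtype=np.int8)
        dip = GenotypeMatrix(["i1"], ["m1", "m2", "m3", "m4"], calls, "diploid")
        with pytest.warns(UserWarning, match="no heterozygous"):
            assert informative_markers(dip, "i1", mm) == []

    def test_subset_size_matches_binomial_expectation(self):
        """Heterozygosity 0.4 over 4285 markers gives ~1714 informative markers."""
        rng = np.random.default_rng(5)
        n = 4285
        mm = MarkerMap(
            pd.DataFrame(
                {
                    "marker_id": [f"m{j}" for j in range(n)],
                    "chromosome": ["1R"] * n,
                    "position_bp": np.arange(1, n + 1) * 10,
                }
            ),
            {"1R": n * 10 + 10},
        )
        het = rng.random(n) < 0.4
        calls = np.where(het, HET, ALLELE_A).astype(np.int8)[None, :]
        dip = GenotypeMatrix(["i1"], [f"m{j}" for j in range(n)], calls, "diploid")
        got = len(informative_markers(dip, "i1", mm))
        se = np.sqrt(n * 0.4 * 0.6)
        assert abs(got - 0.4 * n) < 4 * se
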
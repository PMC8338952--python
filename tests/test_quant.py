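"""Protein-group filtering, MaxLFQ-lite reconstruction, digestion and iBAQ."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sotp import (
    SampleDesign,
    SimulationConfig,
    count_theoretical_peptides,
    digest_tryptic,
    dynamic_range,
    filter_protein_groups,
    ibaq,
    log2_transform,
    maxlfq_lite,
)
from sotp.simulate import generate_peptide_intensities


def brute_force_tryptic(sequence, min_len=6, max_len=30):
    """Independent cleavage oracle: enumerate cut sites, then slice."""
    sites = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            sites.append(i + 1)
    sites.append(len(sequence))
    frags = [sequence[a:b] for a, b in zip(sites, sites[1:])]
    return sum(1 for f in frags if min_len <= len(f) <= max_len)


def pg_table(design, rows):
    """Build a protein-group table from (flags, unique, lfq-values) rows."""
    records = []
    for i, (cont, rev, site, unique, lfq) in enumerate(rows):
        rec = {
            "group_id": f"PG{i}",
            "is_contaminant": cont,
            "is_reverse": rev,
            "only_by_site": site,
            "unique_peptide_count": unique,
        }
        for s, v in zip(design.sample_ids, lfq):
            rec[f"LFQ intensity {s}"] = v
        records.append(rec)
    return pd.DataFrame(records)


NA = np.nan


class TestFilterProteinGroups:
    def test_hand_enumerated_six_row_table(self, two_line_design):
        rows = [
            (True, False, False, 3, [1, 1, 1, 1, 1, 1]),     # contaminant: drop
            (False, True, False, 3, [1, 1, 1, 1, 1, 1]),     # reverse: drop
            (False, False, True, 3, [1, 1, 1, 1, 1, 1]),     # site-only: drop
            (False, False, False, 0, [1, 1, 1, 1, 1, 1]),    # no unique pep: drop
            (False, False, False, 1, [1, 1, NA, NA, NA, NA]),  # 2 valid in A: keep
            (False, False, False, 2, [1, NA, NA, 1, NA, NA]),  # 1 valid each: drop
        ]
        table = pg_table(two_line_design, rows)
        kept = filter_protein_groups(table, two_line_design)
        assert list(kept["group_id"]) == ["PG4"]

    def test_two_valid_in_one_line_kept(self, two_line_design):
        table = pg_table(
            two_line_design, [(False, False, False, 1, [5, 6, NA, NA, NA, NA])]
        )
        assert len(filter_protein_groups(table, two_line_design)) == 1

    def test_design_mismatch_errors(self, two_line_design):
        table = pg_table(two_line_design, [(False, False, False, 1, [1] * 6)])
        table = table.drop(columns=["LFQ intensity S5"])
        with pytest.raises(ValueError, match="LFQ"):
            filter_protein_groups(table, two_line_design)

    def test_single_replicate_line_rejected(self):
        design = SampleDesign(["S0", "S1", "S2"],
                              {"S0": "A", "S1": "A", "S2": "B"})
        table = pg_table(design, [(False, False, False, 1, [1, 1, 1])])
        with pytest.raises(ValueError, match="min_valid"):
            filter_protein_groups(table, design)


class TestLog2Transform:
    def test_powers_of_two_and_missing(self):
        m = pd.DataFrame({"S1": [8.0, np.nan], "S2": [1.0, 1024.0]})
        out = log2_transform(m)
        assert out.loc[0, "S1"] == 3.0
        assert np.isnan(out.loc[1, "S1"])
        assert out.loc[1, "S2"] == 10.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(pd.DataFrame({"S1": [0.0]}))

    def test_matches_reference_log(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame({"S1": rng.lognormal(10, 2, 50)})
        np.testing.assert_allclose(
            log2_transform(m)["S1"], np.log2(m["S1"]), atol=1e-12
        )


class TestMaxLFQLite:
    samples = ["S1", "S2", "S3"]

    def pep(self, rows):
        df = pd.DataFrame(rows, columns=["Sequence", "Proteins"] + [
            f"Intensity {s}" for s in self.samples
        ])
        return df

    def test_single_peptide_profile_is_raw(self):
        prof = maxlfq_lite(
            self.pep([("A", "P1", 2.0, 4.0, 8.0)]), self.samples
        )
        np.testing.assert_allclose(prof.loc["P1"], [2.0, 4.0, 8.0])

    def test_noiseless_proportional_peptides_recover_truth(self):
        truth = np.array([3.0, 1.0, 5.0])
        rows = [
            (f"pep{k}", "P1", *(truth * ion)) for k, ion in enumerate([1, 7, 40])
        ]
        prof = maxlfq_lite(self.pep(rows), self.samples)
        rec = prof.loc["P1"].to_numpy()
        np.testing.assert_allclose(rec / rec[0], truth / truth[0], rtol=1e-10)
        assert rec.sum() == pytest.approx(truth.sum() * (1 + 7 + 40), rel=1e-10)

    def test_sparse_sharing_solved_through_connection(self):
        # S1-S2 share pepA (ratio 1:2), S2-S3 share pepB (ratio 1:2):
        # hand solution has profile ratios 1:2:4 and total anchored to raw sum
        rows = [
            ("pepA", "P1", 2.0, 4.0, NA),
            ("pepB", "P1", NA, 1.0, 2.0),
        ]
        prof = maxlfq_lite(self.pep(rows), self.samples)
        rec = prof.loc["P1"].to_numpy()
        np.testing.assert_allclose(rec / rec[0], [1.0, 2.0, 4.0], rtol=1e-10)
        assert rec.sum() == pytest.approx(9.0)

    def test_disconnected_sample_gets_missing(self):
        rows = [
            ("pepA", "P1", 2.0, 4.0, NA),
            ("pepB", "P1", NA, NA, 7.0),
        ]
        prof = maxlfq_lite(self.pep(rows), self.samples)
        assert np.isnan(prof.loc["P1", "S3"])
        assert not np.isnan(prof.loc["P1", "S1"])

    def test_unquantified_protein_skipped(self):
        rows = [
            ("pepA", "P1", 1.0, 2.0, 4.0),
            ("pepB", "P2", NA, NA, NA),
        ]
        prof = maxlfq_lite(self.pep(rows), self.samples)
        assert list(prof.index) == ["P1"]

    def test_median_protects_against_outlier_peptide(self):
        truth = np.array([1.0, 2.0, 4.0])
        rows = [(f"p{k}", "P1", *(truth * 10)) for k in range(3)]
        rows.append(("bad", "P1", 5.0, 5.0, 5.0))  # contradicting peptide
        prof = maxlfq_lite(self.pep(rows), self.samples)
        rec = prof.loc["P1"].to_numpy()
        np.testing.assert_allclose(rec / rec[0], truth, rtol=1e-9)

    def test_simulated_parameter_recovery(self):
        cfg = SimulationConfig(seed=21, missing_fraction=0.0,
                               venn_counts=(2, 1, 1), n_genes=10)
        peptides, truth = generate_peptide_intensities(
            cfg, n_proteins=40, n_samples=5, noise_log_sd=0.0
        )
        prof = maxlfq_lite(peptides, truth.columns, intensity_prefix="Intensity ")
        for protein in truth.index:
            rec = prof.loc[protein].to_numpy()
            t = truth.loc[protein].to_numpy()
            np.testing.assert_allclose(rec / rec[0], t / t[0], rtol=1e-8)


class TestDigestion:
    def test_two_fragment_example(self):
        assert digest_tryptic("AAAAAKAAAAAAR") == ["AAAAAK", "AAAAAAR"]
        assert count_theoretical_peptides("AAAAAKAAAAAAR") == 2

    def test_no_cut_sites_over_max_length(self):
        assert count_theoretical_peptides("A" * 40) == 0

    def test_all_single_residue_fragments(self):
        assert count_theoretical_peptides("KRKRKR") == 0

    def test_proline_blocks_cleavage(self):
        assert digest_tryptic("AAAKPAAAK") == ["AAAKPAAAK"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            digest_tryptic("")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=120))
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_enumeration(self, seq):
        assert count_theoretical_peptides(seq) == brute_force_tryptic(seq)
        assert "".join(digest_tryptic(seq)) == seq


class TestIbaq:
    samples = ["S1", "S2"]

    def records(self, intensity, sequence):
        return pd.DataFrame(
            {
                "group_id": ["P1"],
                "Intensity S1": [intensity],
                "Intensity S2": [intensity],
                "sequence": [sequence],
            }
        )

    def test_direct_division(self):
        # 4 theoretical peptides of length >= 6
        seq = "AAAAAK" * 4
        rec = self.records(1e6, seq)
        out = ibaq(rec, self.samples)
        assert out.loc[0, "iBAQ S1"] == pytest.approx(2.5e5)
        assert out.loc[0, "iBAQ total"] == pytest.approx(5e5)

    def test_linearity_in_intensity(self):
        seq = "AAAAAK" * 3
        base = ibaq(self.records(10.0, seq), self.samples)
        doubled = ibaq(self.records(20.0, seq), self.samples)
        np.testing.assert_allclose(
            doubled["iBAQ total"], 2 * base["iBAQ total"]
        )

    def test_zero_theoretical_peptides_warns_and_is_missing(self):
        with pytest.warns(UserWarning, match="no theoretical peptides"):
            out = ibaq(self.records(10.0, "KKKK"), self.samples)
        assert np.isnan(out.loc[0, "iBAQ total"])

    def test_correlates_with_molar_quantity_on_simulation(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(31)
        n = 100
        molar = rng.lognormal(0, 2, n)
        n_peps = rng.integers(2, 20, n)
        sequences = ["AAAAAK" * int(k) for k in n_peps]
        # summed intensity proportional to molar amount times peptide count
        intensity = molar * n_peps * rng.lognormal(0, 0.2, n)
        rec = pd.DataFrame(
            {
                "Intensity S1": intensity,
                "Intensity S2": np.zeros(n),
                "sequence": sequences,
            }
        )
        out = ibaq(rec, self.samples)
        rho, _ = spearmanr(out["iBAQ S1"], molar)
        assert rho > 0.95


class TestDynamicRange:
    def test_six_orders(self):
        assert dynamic_range([1.0, 1e6]) == pytest.approx(6.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            dynamic_range([5.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dynamic_range([0.0, 1.0])

    def test_random_fixture_matches_direct_computation(self):
        rng = np.random.default_rng(17)
        vals = rng.lognormal(10, 3, 100)
        assert dynamic_range(vals) == pytest.approx(
            np.log10(vals.max() / vals.min())
        )
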
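"""Reading, validation, harmonisation, proxy search and round-tripping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cismr.estimators import wald_ratio
from cismr.simulate import SimScenario, simulate_two_sample
from cismr.sumstats import (
    LDMatrix,
    SumstatsError,
    VariantNotInLD,
    find_proxy,
    harmonise,
    harmonised_as_outcome,
    read_sumstats,
    write_results,
    write_sumstats,
)

from conftest import make_panel


class TestReadSumstats:
    def test_well_formed_table_reads_all_rows(self, tmp_path):
        panel = make_panel([{}, {}, {}])
        path = tmp_path / "sumstats.tsv"
        write_sumstats(panel, path)
        df = read_sumstats(path)
        assert len(df) == 3
        assert df.attrs["n_dropped"] == 0

    def test_invalid_rows_dropped_with_count(self, tmp_path):
        panel = make_panel([{}, {"se": 0.0}, {"pvalue": 0.0}, {"effect_allele": "A", "other_allele": "A"}])
        path = tmp_path / "sumstats.tsv"
        write_sumstats(panel, path)
        df = read_sumstats(path)
        assert len(df) == 1
        assert df.attrs["n_dropped"] == 3

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        panel = make_panel([{}]).drop(columns=["se"])
        path = tmp_path / "sumstats.tsv"
        panel.to_csv(path, sep="\t", index=False)
        with pytest.raises(SumstatsError, match="SE"):
            read_sumstats(path)

    def test_zero_valid_rows_is_hard_error(self, tmp_path):
        panel = make_panel([{"se": 0.0}])
        path = tmp_path / "sumstats.tsv"
        write_sumstats(panel, path)
        with pytest.raises(SumstatsError, match="no valid"):
            read_sumstats(path)

    def test_custom_column_map(self, tmp_path):
        panel = make_panel([{}, {}])
        path = tmp_path / "other_dialect.tsv"
        write_sumstats(panel, path, column_map={"variant_id": "rsid", "beta": "effect"})
        df = read_sumstats(path, column_map={"variant_id": "rsid", "beta": "effect"})
        assert list(df["variant_id"]) == ["rs1", "rs2"]

    def test_cis_instrument_panel_round_trips(self, tmp_path, cis_fixture):
        panel, _ = cis_fixture
        path = tmp_path / "cis.tsv"
        write_sumstats(panel, path)
        df = read_sumstats(path)
        assert len(df) == 26


class TestHarmonise:
    def test_swapped_alleles_flip_outcome_sign(self):
        exp = make_panel([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = make_panel([{"effect_allele": "G", "other_allele": "A", "beta": 0.05}])
        harm, excl = harmonise(exp, out)
        assert len(harm) == 1 and len(excl) == 0
        assert harm.loc[0, "beta_out"] == pytest.approx(-0.05)
        assert harm.loc[0, "effect_allele"] == "A"

    def test_strand_flip_resolved_without_sign_change(self):
        exp = make_panel([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = make_panel([{"effect_allele": "T", "other_allele": "C", "beta": 0.05}])
        harm, _ = harmonise(exp, out)
        assert harm.loc[0, "beta_out"] == pytest.approx(0.05)

    def test_strand_flip_plus_swap_flips_sign(self):
        exp = make_panel([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = make_panel([{"effect_allele": "C", "other_allele": "T", "beta": 0.05}])
        harm, _ = harmonise(exp, out)
        assert harm.loc[0, "beta_out"] == pytest.approx(-0.05)

    def test_irreconcilable_alleles_excluded_with_reason(self):
        exp = make_panel([{"effect_allele": "A", "other_allele": "G"}])
        out = make_panel([{"effect_allele": "A", "other_allele": "C"}])
        harm, excl = harmonise(exp, out)
        assert len(harm) == 0
        assert excl.loc[0, "reason"] == "incompatible_alleles"

    def test_palindrome_inferred_from_concordant_frequencies(self):
        exp = make_panel([{"effect_allele": "A", "other_allele": "T", "eaf": 0.10}])
        out = make_panel([{"effect_allele": "A", "other_allele": "T", "eaf": 0.12, "beta": 0.05}])
        harm, _ = harmonise(exp, out, freq_window=0.08)
        assert len(harm) == 1
        assert bool(harm.loc[0, "inferred_by_freq"])
        assert harm.loc[0, "beta_out"] == pytest.approx(0.05)

    def test_palindrome_discordant_frequencies_flip_sign(self):
        exp = make_panel([{"effect_allele": "A", "other_allele": "T", "eaf": 0.10}])
        out = make_panel([{"effect_allele": "A", "other_allele": "T", "eaf": 0.88, "beta": 0.05}])
        harm, _ = harmonise(exp, out, freq_window=0.08)
        assert harm.loc[0, "beta_out"] == pytest.approx(-0.05)
        assert harm.loc[0, "eaf_out"] == pytest.approx(0.12)

    def test_palindrome_near_half_frequency_dropped(self):
        exp = make_panel([{"effect_allele": "A", "other_allele": "T", "eaf": 0.10}])
        out = make_panel([{"effect_allele": "T", "other_allele": "A", "eaf": 0.49}])
        harm, excl = harmonise(exp, out, freq_window=0.08)
        assert len(harm) == 0
        assert excl.loc[0, "reason"] == "ambiguous_palindrome"

    def test_palindrome_drop_policy(self):
        exp = make_panel([{"effect_allele": "C", "other_allele": "G", "eaf": 0.1}])
        out = make_panel([{"effect_allele": "C", "other_allele": "G", "eaf": 0.1}])
        harm, excl = harmonise(exp, out, palindrome_policy="drop")
        assert len(harm) == 0 and excl.loc[0, "reason"] == "ambiguous_palindrome"

    def test_palindrome_missing_eaf_dropped(self):
        exp = make_panel([{"effect_allele": "A", "other_allele": "T", "eaf": np.nan}])
        out = make_panel([{"effect_allele": "A", "other_allele": "T", "eaf": 0.1}])
        harm, excl = harmonise(exp, out)
        assert excl.loc[0, "reason"] == "missing_eaf_palindrome"

    def test_unmatched_variants_reported(self):
        exp = make_panel([{}, {}])
        out = make_panel([{}]).iloc[:1]
        harm, excl = harmonise(exp, out)
        assert len(harm) + len(excl) == 2
        assert "absent_from_outcome" in set(excl["reason"])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_count_conservation_and_idempotence(self, seed):
        """matched + excluded == exposure size; re-harmonising changes nothing."""
        exp, out, _ = simulate_two_sample(SimScenario(n_snps=12, seed=seed))
        harm, excl = harmonise(exp, out)
        assert len(harm) + len(excl) == len(exp)
        again, excl2 = harmonise(exp, harmonised_as_outcome(harm))
        again = again.set_index("variant_id").loc[harm["variant_id"]]
        np.testing.assert_allclose(again["beta_out"], harm["beta_out"], rtol=0, atol=0)
        assert not (excl2["reason"] == "incompatible_alleles").any()

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_double_flip_invariance(self, seed):
        """Flipping (EA, OA, beta sign, eaf) in the outcome panel is a no-op."""
        exp, out, _ = simulate_two_sample(SimScenario(n_snps=12, seed=seed))
        flipped = out.copy()
        flipped[["effect_allele", "other_allele"]] = out[["other_allele", "effect_allele"]]
        flipped["beta"] = -out["beta"]
        flipped["eaf"] = 1.0 - out["eaf"]
        h1, e1 = harmonise(exp, out)
        h2, e2 = harmonise(exp, flipped)
        assert list(h1["variant_id"]) == list(h2["variant_id"])
        np.testing.assert_allclose(h1["beta_out"], h2["beta_out"], rtol=1e-12)
        assert sorted(e1["reason"]) == sorted(e2["reason"])


class TestProxySearch:
    @staticmethod
    def _ld():
        r = np.array(
            [
                [1.0, np.sqrt(0.95), np.sqrt(0.85), np.sqrt(0.5)],
                [np.sqrt(0.95), 1.0, 0.9, 0.3],
                [np.sqrt(0.85), 0.9, 1.0, 0.3],
                [np.sqrt(0.5), 0.3, 0.3, 1.0],
            ]
        )
        return LDMatrix(["target", "p1", "p2", "p3"], r)

    def test_target_proxies_itself(self):
        cands = make_panel([{"variant_id": "target"}])
        cands["variant_id"] = ["target"]
        assert find_proxy("target", cands, self._ld()) == "target"

    def test_best_r2_candidate_wins(self):
        cands = make_panel([{}, {}, {}])
        cands["variant_id"] = ["p1", "p2", "p3"]
        assert find_proxy("target", cands, self._ld(), r2_min=0.8) == "p1"

    def test_no_candidate_above_threshold_returns_none(self):
        cands = make_panel([{}])
        cands["variant_id"] = ["p3"]
        assert find_proxy("target", cands, self._ld(), r2_min=0.8) is None

    def test_absent_target_is_distinguishable_error(self):
        cands = make_panel([{}])
        cands["variant_id"] = ["p1"]
        with pytest.raises(VariantNotInLD):
            find_proxy("rs_missing", cands, self._ld())

    def test_tie_breaks_to_smaller_position(self):
        r = np.array([[1.0, 0.95, 0.95], [0.95, 1.0, 0.9], [0.95, 0.9, 1.0]])
        ld = LDMatrix(["t", "a", "b"], r)
        cands = make_panel([{"pos": 500}, {"pos": 200}])
        cands["variant_id"] = ["a", "b"]
        assert find_proxy("t", cands, ld) == "b"


class TestLDMatrix:
    @pytest.mark.parametrize(
        "r, msg",
        [
            (np.array([[1.0, 0.5], [0.4, 1.0]]), "symmetric"),
            (np.array([[0.9, 0.5], [0.5, 1.0]]), "diagonal"),
            (np.array([[1.0, 1.5], [1.5, 1.0]]), "-1, 1"),
        ],
    )
    def test_invalid_matrices_rejected(self, r, msg):
        with pytest.raises(ValueError, match=msg):
            LDMatrix(["a", "b"], r)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            LDMatrix(["a"], np.eye(2))


class TestWriteResults:
    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "results.tsv"
        write_results([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1

    def test_round_trip_preserves_ten_significant_digits(self, tmp_path):
        ests = [
            wald_ratio(0.1 + 0.01 * i, 0.01, -0.05 + 0.003 * i, 0.02, tag=f"o{i}")
            for i in range(5)
        ]
        path = tmp_path / "results.tsv"
        frame = write_results(ests, path)
        back = pd.read_csv(path, sep="\t")
        for col in ["beta", "se", "ci_low", "ci_high", "pvalue"]:
            np.testing.assert_allclose(back[col], frame[col], rtol=1e-9)
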
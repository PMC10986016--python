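"""Summary-statistic I/O and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrmediate import (
    FormatError,
    ValidationError,
    harmonize,
    read_summary_stats,
    write_summary_stats,
)
from mrmediate.gwas_io import (
    CANONICAL_COLUMNS,
    COMPLEMENT,
    DROPPED_MISMATCH,
    DROPPED_MISSING,
    DROPPED_PALINDROMIC,
    FLIPPED,
    KEPT,
)

from conftest import make_table

HEADER = "\t".join(CANONICAL_COLUMNS)


def _write(tmp_path, lines, name="t.tsv"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


class TestReadWrite:
    def test_header_only_file_gives_empty_table(self, tmp_path):
        t = read_summary_stats(_write(tmp_path, [HEADER]))
        assert len(t) == 0

    def test_single_row_roundtrip(self, tmp_path):
        line = "rs1\t1\t1000\tA\tG\t0.3\t0.1\t0.01\t1e-10\t100000"
        t = read_summary_stats(_write(tmp_path, [HEADER, line]))
        out = tmp_path / "out.tsv"
        write_summary_stats(t, out)
        t2 = read_summary_stats(out)
        pd.testing.assert_frame_equal(t.records, t2.records)

    def test_empty_table_writes_header_only(self, tmp_path):
        t = read_summary_stats(_write(tmp_path, [HEADER]))
        out = tmp_path / "o.tsv"
        write_summary_stats(t, out)
        assert out.read_text().strip() == HEADER

    def test_hundred_record_roundtrip_bit_exact(self, tmp_path, rng):
        rows = [
            {
                "BP": int(rng.integers(1, 10**8)),
                "EAF": float(rng.uniform(0.01, 0.99)),
                "BETA": float(rng.normal(0, 0.1)),
                "SE": float(rng.uniform(0.001, 0.05)),
                "P": float(rng.uniform(1e-30, 1)),
                "N": int(rng.integers(1000, 10**6)),
            }
            for _ in range(100)
        ]
        t = make_table("x", rows)
        out = tmp_path / "o.tsv"
        write_summary_stats(t, out)
        t2 = read_summary_stats(out)
        pd.testing.assert_frame_equal(t.records, t2.records, check_exact=True)

    @pytest.mark.parametrize(
        "bad",
        [
            "rs1\t1\t1000\tA\tG\t0.3\t0.1\t0\t1e-10\t100000",  # se = 0
            "rs1\t1\t1000\tA\tA\t0.3\t0.1\t0.01\t1e-10\t100000",  # EA == OA
            "rs1\t1\t1000\tA\tG\t0.3\t0.1\t0.01\t1.5\t100000",  # p > 1
            "rs1\t1\t1000\tA\tG\t1.3\t0.1\t0.01\t1e-10\t100000",  # eaf out of range
            "rs1\t1\t1000\tA\tG\t0.3\tnot_a_number\t0.01\t1e-10\t100000",
        ],
    )
    def test_invalid_rows_rejected_with_line_numbers(self, tmp_path, bad):
        with pytest.raises(ValidationError) as exc:
            read_summary_stats(_write(tmp_path, [HEADER, bad]))
        assert exc.value.rows == [2]

    def test_missing_column_is_format_error(self, tmp_path):
        p = _write(tmp_path, ["SNP\tCHR\tBP", "rs1\t1\t1000"])
        with pytest.raises(FormatError, match="missing mandatory"):
            read_summary_stats(p)

    def test_dialect_renames_columns(self, tmp_path):
        hdr = "rsid\tchrom\tpos\tea\toa\tfreq\tb\tstderr\tpval\tsize"
        line = "rs1\t1\t1000\tA\tG\t0.3\t0.1\t0.01\t1e-10\t100000"
        dialect = dict(zip(hdr.split("\t"), CANONICAL_COLUMNS))
        t = read_summary_stats(_write(tmp_path, [hdr, line]), dialect=dialect)
        assert t.records["BETA"].iloc[0] == 0.1

    def test_missing_eaf_is_allowed(self, tmp_path):
        line = "rs1\t1\t1000\tA\tG\tNA\t0.1\t0.01\t1e-10\t100000"
        t = read_summary_stats(_write(tmp_path, [HEADER, line]))
        assert np.isnan(t.records["EAF"].iloc[0])

    def test_duplicate_snp_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            make_table("x", [{"SNP": "rs1"}, {"SNP": "rs1"}])


def _pair(exposure_rows, outcome_rows, limit=0.42):
    ex = make_table("exposure", exposure_rows)
    out = make_table("outcome", outcome_rows)
    return harmonize(ex, [out], palindromic_eaf_limit=limit)


class TestHarmonize:
    def test_aligned_pair_kept_unchanged(self):
        h = _pair([{"EA": "A", "OA": "G", "BETA": 0.1}],
                  [{"EA": "A", "OA": "G", "BETA": 0.05}])
        assert h.n_snp == 1
        assert h.beta[0, 1] == 0.05
        assert h.drop_log["disposition"].iloc[0] == KEPT

    def test_swapped_alleles_flip_beta_and_eaf(self):
        h = _pair([{"EA": "A", "OA": "G"}],
                  [{"EA": "G", "OA": "A", "BETA": 0.05, "EAF": 0.3}])
        assert h.beta[0, 1] == -0.05
        assert h.eaf[0, 1] == pytest.approx(0.7)
        assert h.drop_log["disposition"].iloc[0] == FLIPPED

    def test_ambiguous_palindromic_dropped(self):
        h = _pair([{"EA": "A", "OA": "T", "EAF": 0.3}],
                  [{"EA": "A", "OA": "T", "EAF": 0.50}])
        assert h.n_snp == 0
        assert h.drop_log["disposition"].iloc[0] == DROPPED_PALINDROMIC

    def test_palindromic_opposite_frequency_sides_flips(self):
        h = _pair([{"EA": "A", "OA": "T", "EAF": 0.10}],
                  [{"EA": "A", "OA": "T", "EAF": 0.91, "BETA": 0.05}])
        assert h.n_snp == 1
        assert h.beta[0, 1] == -0.05
        assert h.eaf[0, 1] == pytest.approx(0.09)

    def test_unmatchable_alleles_dropped_with_reason(self):
        h = _pair([{"EA": "A", "OA": "G"}], [{"EA": "A", "OA": "C"}])
        assert h.n_snp == 0
        assert h.drop_log["disposition"].iloc[0] == DROPPED_MISMATCH

    def test_snp_missing_from_one_table_dropped(self):
        ex = make_table("exposure", [{"SNP": "rs1"}, {"SNP": "rs2"}])
        out = make_table("outcome", [{"SNP": "rs1"}])
        h = harmonize(ex, [out])
        log = h.drop_log.set_index("SNP")["disposition"]
        assert log["rs2"] == DROPPED_MISSING
        assert h.n_snp == 1

    def test_exhaustive_allele_configuration_oracle(self):
        """Every representation of the same underlying association must
        harmonize back to the same outcome beta.

        The oracle enumerates representations directly: the outcome's effect
        allele is the exposure's effect allele (identity), its partner
        (swap), or either on the complementary strand; palindromic variants
        additionally vary which side of 0.5 each frequency sits on.
        """
        true_beta, eaf_x = 0.07, 0.2
        # non-palindromic exposure A/G: (outcome EA, OA, beta, eaf as stored)
        cases = [
            ("A", "G", true_beta, eaf_x),
            ("G", "A", -true_beta, 1 - eaf_x),
            ("T", "C", true_beta, eaf_x),        # same, complementary strand
            ("C", "T", -true_beta, 1 - eaf_x),   # swap, complementary strand
        ]
        for ea, oa, b_stored, f_stored in cases:
            h = _pair(
                [{"EA": "A", "OA": "G", "EAF": eaf_x}],
                [{"EA": ea, "OA": oa, "BETA": b_stored, "EAF": f_stored}],
            )
            assert h.n_snp == 1, (ea, oa)
            assert h.beta[0, 1] == pytest.approx(true_beta), (ea, oa)
            assert h.eaf[0, 1] == pytest.approx(eaf_x), (ea, oa)
        # palindromic exposure A/T, informative frequencies
        pal_cases = [
            ("A", "T", true_beta, eaf_x),        # same orientation, same side
            ("T", "A", -true_beta, 1 - eaf_x),   # label swap, opposite side
        ]
        for ea, oa, b_stored, f_stored in pal_cases:
            h = _pair(
                [{"EA": "A", "OA": "T", "EAF": eaf_x}],
                [{"EA": ea, "OA": oa, "BETA": b_stored, "EAF": f_stored}],
            )
            assert h.n_snp == 1, (ea, oa)
            assert h.beta[0, 1] == pytest.approx(true_beta), (ea, oa)

    def test_idempotent_on_already_harmonized_tables(self, rng):
        rows_x, rows_y = [], []
        alleles = [("A", "G"), ("C", "T"), ("A", "T"), ("G", "C")]
        for i in range(20):
            ea, oa = alleles[i % 4]
            eaf = float(rng.uniform(0.05, 0.35))
            rows_x.append({"SNP": f"rs{i}", "EA": ea, "OA": oa, "EAF": eaf,
                           "BETA": float(rng.normal())})
            rows_y.append({"SNP": f"rs{i}", "EA": ea, "OA": oa, "EAF": eaf,
                           "BETA": float(rng.normal())})
        h1 = harmonize(make_table("exposure", rows_x), [make_table("outcome", rows_y)])
        tables = h1.to_tables()
        h2 = harmonize(tables[0], tables[1:])
        assert h2.snp_ids == h1.snp_ids
        np.testing.assert_array_equal(h2.beta, h1.beta)
        np.testing.assert_array_equal(h2.eaf, h1.eaf)

    def test_strand_label_invariance(self):
        """Swapping an input's allele labels (and negating beta, flipping
        eaf) leaves the harmonized result unchanged."""
        base = [{"EA": "A", "OA": "G", "BETA": 0.05, "EAF": 0.3}]
        relabelled = [{"EA": "G", "OA": "A", "BETA": -0.05, "EAF": 0.7}]
        ex = [{"EA": "A", "OA": "G", "EAF": 0.3}]
        h1 = _pair(ex, base)
        h2 = _pair(ex, relabelled)
        np.testing.assert_array_equal(h1.beta, h2.beta)
        np.testing.assert_allclose(h1.eaf, h2.eaf, atol=1e-15)

    def test_kept_plus_dropped_covers_intersection(self, rng):
        n = 30
        alleles = [("A", "G"), ("A", "T"), ("C", "G"), ("T", "C")]
        rows_x = [
            {"SNP": f"rs{i}", "EA": alleles[i % 4][0], "OA": alleles[i % 4][1],
             "EAF": float(rng.uniform(0.05, 0.95))}
            for i in range(n)
        ]
        rows_y = [dict(r, BETA=float(rng.normal()),
                       EAF=float(rng.uniform(0.05, 0.95))) for r in rows_x[:25]]
        h = harmonize(make_table("exposure", rows_x), [make_table("outcome", rows_y)])
        log = h.drop_log["disposition"]
        n_missing = (log == DROPPED_MISSING).sum()
        assert len(h.drop_log) == n  # union covered exactly once
        assert n_missing == 5
        assert h.n_snp + (log.isin([DROPPED_PALINDROMIC, DROPPED_MISMATCH])).sum() == 25
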
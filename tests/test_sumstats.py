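import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.sumstats import (HarmonisedSet, MissingColumnError, SummaryDataset,
                                VariantAssociation, beta_to_or, harmonise,
                                read_sumstats, write_sumstats)

from conftest import make_dataset


class TestVariantAssociation:
    def test_valid_record(self):
        rec = VariantAssociation("rs1", "A", "G", 0.1, 0.01, 1e-8, eaf=0.3)
        assert rec.beta == 0.1
        assert not rec.is_palindromic

    def test_palindromic_detection(self):
        assert VariantAssociation("rs1", "A", "T", 0.1, 0.01, 0.5).is_palindromic
        assert VariantAssociation("rs1", "C", "G", 0.1, 0.01, 0.5).is_palindromic

    @pytest.mark.parametrize("kwargs", [
        dict(effect_allele="A", other_allele="A"),
        dict(se=0.0),
        dict(se=-1.0),
        dict(eaf=1.5),
        dict(pval=0.0),
        dict(effect_allele="N"),
    ])
    def test_invalid_record_rejected(self, kwargs):
        base = dict(variant_id="rs1", effect_allele="A", other_allele="G",
                    beta=0.1, se=0.01, pval=0.5)
        base.update(kwargs)
        with pytest.raises(ValueError):
            VariantAssociation(**base)


class TestReadWrite:
    HEADER = "variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"

    def _write(self, path, lines):
        path.write_text(self.HEADER + "".join(lines))

    def test_three_line_parse(self, tmp_path):
        p = tmp_path / "ss.tsv"
        self._write(p, [
            "rs1\t1\t100\tA\tG\t0.3\t0.10\t0.01\t1e-10\t1000\n",
            "rs2\t1\t200\tC\tT\t0.2\t-0.05\t0.02\t0.01\t1000\n",
            "rs3\t2\t300\tG\tA\t0.4\t0.07\t0.01\t1e-9\t1000\n",
        ])
        ds = read_sumstats(p)
        assert len(ds) == 3
        assert ds["rs2"].beta == -0.05
        assert ds.n_dropped == 0

    def test_na_se_dropped_and_counted(self, tmp_path):
        p = tmp_path / "ss.tsv"
        self._write(p, [
            "rs1\t1\t100\tA\tG\t0.3\t0.10\t0.01\t1e-10\t1000\n",
            "rs2\t1\t200\tC\tT\t0.2\t-0.05\tNA\t0.01\t1000\n",
            "rs3\t2\t300\tG\tA\t0.4\t0.07\t0.01\t1e-9\t1000\n",
        ])
        with pytest.warns(UserWarning, match="dropped 1"):
            ds = read_sumstats(p)
        assert len(ds) == 2
        assert ds.n_dropped == 1

    def test_missing_mandatory_column_named(self, tmp_path):
        p = tmp_path / "ss.tsv"
        p.write_text("variant_id\teffect_allele\tother_allele\tbeta\tpval\n"
                     "rs1\tA\tG\t0.1\t1e-8\n")
        with pytest.raises(MissingColumnError, match="'se'"):
            read_sumstats(p)

    def test_column_map(self, tmp_path):
        p = tmp_path / "ss.csv"
        p.write_text("SNP,EA,NEA,b,stderr,p\nrs1,A,G,0.1,0.01,1e-8\n")
        ds = read_sumstats(p, column_map={
            "variant_id": "SNP", "effect_allele": "EA", "other_allele": "NEA",
            "beta": "b", "se": "stderr", "pval": "p"})
        assert len(ds) == 1

    def test_round_trip_identity(self, tmp_path):
        ds = make_dataset([
            {"variant_id": "rs1", "chrom": "1", "pos": 100, "eaf": 0.3, "n": 500},
            {"variant_id": "rs2", "beta": -0.2, "se": 0.05, "pval": 0.5},
        ])
        p = tmp_path / "rt.tsv"
        write_sumstats(ds, p)
        back = read_sumstats(p, trait_label=ds.trait_label)
        assert back.records == ds.records


class TestHarmonise:
    def test_allele_swap_negates_beta(self):
        exp = make_dataset([{"variant_id": "rs1", "effect_allele": "A",
                             "other_allele": "G", "beta": 0.10}])
        out = make_dataset([{"variant_id": "rs1", "effect_allele": "G",
                             "other_allele": "A", "beta": -0.05}], label="out")
        h = harmonise(exp, out, ["rs1"])
        assert h.n_snp == 1
        assert h.effect_alleles == ["A"]
        assert h.by[0] == pytest.approx(0.05)

    def test_strand_complement_kept(self):
        exp = make_dataset([{"variant_id": "rs2", "effect_allele": "A",
                             "other_allele": "G", "beta": 0.10}])
        out = make_dataset([{"variant_id": "rs2", "effect_allele": "T",
                             "other_allele": "C", "beta": 0.07}], label="out")
        h = harmonise(exp, out, ["rs2"])
        assert h.n_snp == 1
        assert h.by[0] == pytest.approx(0.07)

    def test_strand_complement_swapped_negates(self):
        exp = make_dataset([{"variant_id": "rs2", "effect_allele": "A",
                             "other_allele": "G", "beta": 0.10}])
        out = make_dataset([{"variant_id": "rs2", "effect_allele": "C",
                             "other_allele": "T", "beta": 0.07}], label="out")
        h = harmonise(exp, out, ["rs2"])
        assert h.by[0] == pytest.approx(-0.07)

    def test_palindromic_midfrequency_dropped(self):
        exp = make_dataset([{"variant_id": "rs3", "effect_allele": "A",
                             "other_allele": "T", "eaf": 0.50}])
        out = make_dataset([{"variant_id": "rs3", "effect_allele": "A",
                             "other_allele": "T", "eaf": 0.50}], label="out")
        h = harmonise(exp, out, ["rs3"], palindromic_eaf_window=0.08)
        assert h.n_snp == 0
        assert h.dropped == [("rs3", "palindromic_ambiguous")]

    def test_palindromic_missing_eaf_dropped(self):
        exp = make_dataset([{"variant_id": "rs3", "effect_allele": "A",
                             "other_allele": "T", "eaf": 0.1}])
        out = make_dataset([{"variant_id": "rs3", "effect_allele": "A",
                             "other_allele": "T"}], label="out")
        h = harmonise(exp, out, ["rs3"])
        assert h.dropped == [("rs3", "palindromic_ambiguous")]

    def test_palindromic_clear_frequency_kept_with_eaf_alignment(self):
        exp = make_dataset([{"variant_id": "rs3", "effect_allele": "A",
                             "other_allele": "T", "eaf": 0.1, "beta": 0.2}])
        # same nominal alleles but frequency on the opposite side: strand flip
        out = make_dataset([{"variant_id": "rs3", "effect_allele": "A",
                             "other_allele": "T", "eaf": 0.9, "beta": 0.3}],
                           label="out")
        h = harmonise(exp, out, ["rs3"])
        assert h.n_snp == 1
        assert h.by[0] == pytest.approx(-0.3)

    def test_missing_variant_dropped(self):
        exp = make_dataset([{"variant_id": "rs1"}])
        out = make_dataset([{"variant_id": "rs9"}], label="out")
        h = harmonise(exp, out, ["rs1"])
        assert h.dropped == [("rs1", "missing")]

    def test_allele_mismatch_dropped_not_fatal(self):
        exp = make_dataset([{"variant_id": "rs1", "effect_allele": "A",
                             "other_allele": "G"}])
        out = make_dataset([{"variant_id": "rs1", "effect_allele": "A",
                             "other_allele": "C"}], label="out")
        h = harmonise(exp, out, ["rs1"])
        assert h.dropped == [("rs1", "allele_mismatch")]

    def test_row_plus_dropped_counts(self):
        exp = make_dataset([{"variant_id": f"rs{i}"} for i in range(1, 6)])
        out = make_dataset([{"variant_id": f"rs{i}"} for i in range(1, 4)],
                           label="out")
        h = harmonise(exp, out, [f"rs{i}" for i in range(1, 6)])
        assert h.n_snp + len(h.dropped) == 5

    def test_idempotent(self):
        exp = make_dataset([
            {"variant_id": "rs1", "beta": 0.1},
            {"variant_id": "rs2", "effect_allele": "C", "other_allele": "T",
             "beta": -0.2},
        ])
        out = make_dataset([
            {"variant_id": "rs1", "beta": 0.05},
            {"variant_id": "rs2", "effect_allele": "C", "other_allele": "T",
             "beta": 0.02},
        ], label="out")
        h1 = harmonise(exp, out, ["rs1", "rs2"])
        # rebuild datasets from the harmonised rows and harmonise again
        exp2 = make_dataset([
            {"variant_id": v, "effect_allele": ea, "other_allele": oa, "beta": b}
            for v, ea, oa, b in zip(h1.variant_ids, h1.effect_alleles,
                                    h1.other_alleles, h1.bx[:, 0])
        ])
        out2 = make_dataset([
            {"variant_id": v, "effect_allele": ea, "other_allele": oa, "beta": b}
            for v, ea, oa, b in zip(h1.variant_ids, h1.effect_alleles,
                                    h1.other_alleles, h1.by)
        ], label="out")
        h2 = harmonise(exp2, out2, h1.variant_ids)
        np.testing.assert_array_equal(h1.bx, h2.bx)
        np.testing.assert_array_equal(h1.by, h2.by)

    @given(beta=st.floats(-2, 2, allow_nan=False), )
    @settings(max_examples=50, deadline=None)
    def test_sign_round_trip(self, beta):
        """Swapping outcome alleles then harmonising recovers beta exactly."""
        exp = make_dataset([{"variant_id": "rs1", "effect_allele": "A",
                             "other_allele": "G", "beta": 0.1}])
        out = make_dataset([{"variant_id": "rs1", "effect_allele": "G",
                             "other_allele": "A", "beta": -beta}], label="out")
        h = harmonise(exp, out, ["rs1"])
        assert h.by[0] == beta


class TestBetaToOr:
    def test_null_beta(self):
        res = beta_to_or(0.0, 0.1)
        assert res.odds_ratio == pytest.approx(1.0)
        # closed form exp(-1.959964*0.1), exp(+1.959964*0.1)
        assert res.ci_low == pytest.approx(0.82202, abs=1e-4)
        assert res.ci_high == pytest.approx(1.21653, abs=1e-4)

    def test_zero_se_collapses(self):
        res = beta_to_or(math.log(2), 0.0)
        assert res.odds_ratio == pytest.approx(2.0)
        assert res.ci_low == pytest.approx(2.0)
        assert res.ci_high == pytest.approx(2.0)

    @pytest.mark.parametrize("beta", [-1.0, 0.0, 1.0])
    def test_log_inverse_identity(self, beta):
        assert math.log(beta_to_or(beta, 0.1).odds_ratio) == pytest.approx(beta)
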
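"""Data model, I/O round-trips and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrmediation.summary_data import (
    HarmonizedSet,
    SummaryDataset,
    harmonize,
    read_summary_table,
    write_summary_table,
)

from conftest import make_dataset, make_variant


def write_raw(path, rows, header="snp\tchr\tpos\tea\toa\teaf\tbeta\tse\tp\tn"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))


class TestReadWrite:
    def test_well_formed_table_loads_all_rows(self, tmp_path):
        f = tmp_path / "a.tsv"
        write_raw(f, [f"rs{i}\t1\t{1000 * i}\tA\tG\t0.3\t0.1\t0.02\t1e-6\t3757"
                      for i in range(1, 6)])
        ds = read_summary_table(f)
        assert ds.n_variants == 5

    def test_invalid_rows_dropped_not_fatal(self, tmp_path):
        f = tmp_path / "a.tsv"
        write_raw(f, [
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-6\t3757",
            "rs2\t1\t200\tA\tG\t0.3\t0.1\t0.0\t1e-6\t3757",   # se = 0
            "rs3\t1\t300\tA\tA\t0.3\t0.1\t0.02\t1e-6\t3757",  # identical alleles
            "rs4\t1\t400\tA\tG\t1.3\t0.1\t0.02\t1e-6\t3757",  # eaf out of range
        ])
        ds = read_summary_table(f)
        assert list(ds.records["snp_id"]) == ["rs1"]

    def test_missing_column_is_named_in_error(self, tmp_path):
        f = tmp_path / "a.tsv"
        write_raw(f, ["rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-6"],
                  header="snp\tchr\tpos\tea\toa\teaf\tbeta\tse\tp")
        with pytest.raises(ValueError, match="n"):
            read_summary_table(f)

    def test_zero_valid_rows_is_hard_error(self, tmp_path):
        f = tmp_path / "a.tsv"
        write_raw(f, [])
        with pytest.raises(ValueError, match="zero valid rows"):
            read_summary_table(f)

    def test_dialect_mapping_equals_canonical(self, tmp_path):
        canon = tmp_path / "canon.tsv"
        write_raw(canon, ["rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-6\t3757"])
        alt = tmp_path / "alt.tsv"
        write_raw(alt, ["rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-6\t3757"],
                  header="rsid\tchr\tpos\tea\toa\tFREQ\tbeta\tse\tp\tn")
        a = read_summary_table(canon, trait_id="t")
        b = read_summary_table(alt, dialect={"rsid": "snp", "FREQ": "eaf"}, trait_id="t")
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_duplicate_snp_keeps_lowest_p(self, tmp_path):
        f = tmp_path / "a.tsv"
        write_raw(f, [
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-6\t3757",
            "rs1\t1\t100\tA\tG\t0.3\t0.2\t0.02\t1e-8\t3757",
        ])
        ds = read_summary_table(f)
        assert ds.n_variants == 1
        assert ds.records.loc[0, "beta"] == 0.2

    def test_write_is_byte_stable(self, tmp_path):
        ds = make_dataset([make_variant(snp_id=f"rs{i}", pos=i * 100, beta=0.1 * i + 0.05)
                           for i in range(1, 5)])
        write_summary_table(ds, tmp_path / "a.tsv")
        write_summary_table(ds, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_empty_dataset_roundtrip_raises(self, tmp_path):
        ds = make_dataset([make_variant()])
        ds.records = ds.records.iloc[0:0]
        write_summary_table(ds, tmp_path / "a.tsv")
        with pytest.raises(ValueError, match="zero valid rows"):
            read_summary_table(tmp_path / "a.tsv")

    def test_gzip_transparent(self, tmp_path):
        ds = make_dataset([make_variant()])
        write_summary_table(ds, tmp_path / "a.tsv.gz")
        back = read_summary_table(tmp_path / "a.tsv.gz", trait_id="trait")
        pd.testing.assert_frame_equal(ds.records, back.records)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_roundtrip_reproduces_every_field(self, tmp_path_factory, data):
        n = data.draw(st.integers(2, 30))
        variants = []
        for i in range(n):
            variants.append(make_variant(
                snp_id=f"rs{i}", chrom=data.draw(st.sampled_from(["1", "2", "X"])),
                pos=data.draw(st.integers(1, 10**8)),
                eaf=data.draw(st.floats(1e-6, 1 - 1e-6, exclude_min=True, exclude_max=True)),
                beta=data.draw(st.floats(-10, 10, allow_nan=False)),
                se=data.draw(st.floats(1e-12, 10, exclude_min=True)),
                pvalue=data.draw(st.floats(5e-324, 1.0, exclude_min=False)),
                n=data.draw(st.integers(3, 10**6)),
            ))
        ds = make_dataset(variants)
        path = tmp_path_factory.mktemp("rt") / "x.tsv"
        write_summary_table(ds, path)
        back = read_summary_table(path, trait_id="trait")
        pd.testing.assert_frame_equal(ds.records, back.records)


class TestHarmonize:
    def base_pair(self, ea_y="A", oa_y="G", beta_y=0.05, eaf_y=0.3,
                  ea_x="A", oa_x="G", eaf_x=0.3):
        exp = make_dataset([make_variant(ea=ea_x, oa=oa_x, eaf=eaf_x, beta=0.10)],
                           trait_id="exp")
        out = make_dataset([make_variant(ea=ea_y, oa=oa_y, eaf=eaf_y, beta=beta_y)],
                           trait_id="out", trait_type="outcome")
        return exp, out

    def test_already_aligned_unchanged(self):
        h = harmonize(*self.base_pair())
        assert h.rows.loc[0, "beta_x"] == 0.10
        assert h.rows.loc[0, "beta_y"] == 0.05

    def test_allele_swap_flips_sign(self):
        h = harmonize(*self.base_pair(ea_y="G", oa_y="A", eaf_y=0.7))
        assert h.rows.loc[0, "beta_y"] == -0.05

    def test_strand_complement_resolves(self):
        # exposure A/G; outcome reported on the other strand as T/C
        h = harmonize(*self.base_pair(ea_y="T", oa_y="C"))
        assert h.rows.loc[0, "beta_y"] == 0.05

    def test_palindrome_mid_frequency_dropped(self):
        exp, out = self.base_pair(ea_x="A", oa_x="T", eaf_x=0.50,
                                  ea_y="A", oa_y="T", eaf_y=0.50)
        with pytest.raises(ValueError, match="zero resolvable"):
            harmonize(exp, out, palindrome_eaf_window=0.08)

    def test_palindrome_opposite_side_flips(self):
        exp, out = self.base_pair(ea_x="A", oa_x="T", eaf_x=0.2,
                                  ea_y="A", oa_y="T", eaf_y=0.8)
        h = harmonize(exp, out)
        assert h.rows.loc[0, "beta_y"] == -0.05

    def test_unresolvable_alleles_dropped(self):
        exp, out = self.base_pair(ea_y="A", oa_y="C")
        with pytest.raises(ValueError, match="zero resolvable"):
            harmonize(exp, out)

    def test_empty_intersection_is_hard_error(self):
        exp = make_dataset([make_variant(snp_id="rs1")], trait_id="exp")
        out = make_dataset([make_variant(snp_id="rs2")], trait_id="out",
                           trait_type="outcome")
        with pytest.raises(ValueError, match="no shared variants"):
            harmonize(exp, out)

    def test_idempotent_on_aligned_pair(self, rng):
        n = 15
        variants_x, variants_y = [], []
        for i in range(n):
            eaf = float(rng.uniform(0.05, 0.95))
            variants_x.append(make_variant(snp_id=f"rs{i}", pos=1000 * (i + 1),
                                           eaf=eaf, beta=float(rng.normal(0, 0.1))))
            variants_y.append(make_variant(snp_id=f"rs{i}", pos=1000 * (i + 1),
                                           eaf=eaf, beta=float(rng.normal(0, 0.1))))
        exp = make_dataset(variants_x, trait_id="exp")
        out = make_dataset(variants_y, trait_id="out", trait_type="outcome")
        first = harmonize(exp, out)
        again = harmonize(exp, out)
        pd.testing.assert_frame_equal(first.rows, again.rows)

    def test_sign_symmetry_full_relabel(self, rng):
        """Swapping every outcome record's alleles with negated beta and
        complemented eaf describes the same associations, so the
        harmonized set is identical."""
        n = 12
        pairs = [("A", "G"), ("C", "T"), ("A", "T"), ("C", "G")]
        vx, vy, vy_flipped = [], [], []
        for i in range(n):
            ea, oa = pairs[i % len(pairs)]
            eaf = float(rng.uniform(0.05, 0.40))
            beta = float(rng.normal(0, 0.1))
            vx.append(make_variant(snp_id=f"rs{i}", pos=1000 * (i + 1), ea=ea, oa=oa, eaf=eaf))
            vy.append(make_variant(snp_id=f"rs{i}", pos=1000 * (i + 1), ea=ea, oa=oa,
                                   eaf=eaf, beta=beta))
            vy_flipped.append(make_variant(snp_id=f"rs{i}", pos=1000 * (i + 1), ea=oa, oa=ea,
                                           eaf=1 - eaf, beta=-beta))
        exp = make_dataset(vx, trait_id="exp")
        out = make_dataset(vy, trait_id="out", trait_type="outcome")
        out_flipped = make_dataset(vy_flipped, trait_id="out", trait_type="outcome")
        h1 = harmonize(exp, out)
        h2 = harmonize(exp, out_flipped)
        pd.testing.assert_frame_equal(h1.rows, h2.rows)


class TestHarmonizedSet:
    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError, match="positive standard errors"):
            HarmonizedSet.from_arrays([0.1, 0.2], [0.01, 0.0], [0.05, 0.1], [0.01, 0.01])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            HarmonizedSet.from_arrays([0.1, 0.2], [0.01, 0.01], [0.05, 0.1],
                                      [0.01, 0.01], snp_ids=["a", "a"])
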
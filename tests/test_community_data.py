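"""Count-table I/O, taxonomy filtering, rare-ASV filter, rarefaction."""

import numpy as np
import pandas as pd
import pytest

from tubertrace import (
    CountTable,
    TaxonomyAssignment,
    filter_rare_asvs,
    rarefy,
    read_count_table,
    read_taxonomy,
    remove_offtarget_taxa,
    to_relative_abundance,
    write_count_table,
)
from tubertrace.community_data import (
    TableFormatError,
    TaxonomyError,
    parse_lineage,
    read_metadata,
    write_taxonomy,
)


class TestIO:
    def test_tsv_round_trip(self, random_table, tmp_path):
        p = tmp_path / "counts.tsv"
        write_count_table(random_table, p)
        back = read_count_table(p)
        pd.testing.assert_frame_equal(back.data, random_table.data)

    def test_tsv_asvs_by_samples_orientation(self, small_table, tmp_path):
        p = tmp_path / "t.tsv"
        write_count_table(small_table, p, orientation="asvs_by_samples")
        back = read_count_table(p, orientation="asvs_by_samples")
        pd.testing.assert_frame_equal(back.data, small_table.data)

    def test_biom_json_round_trip(self, random_table, tmp_path):
        p = tmp_path / "counts.biom.json"
        write_count_table(random_table, p, format="biom_json")
        back = read_count_table(p, format="biom_json")
        pd.testing.assert_frame_equal(
            back.data.loc[random_table.sample_ids, random_table.asv_ids],
            random_table.data,
        )

    def test_small_tsv_shape(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample\tA\tB\tC\ns1\t1\t2\t3\ns2\t0\t0\t1\n")
        t = read_count_table(p)
        assert t.n_samples == 2 and t.n_asvs == 3
        assert t.data.loc["s1", "B"] == 2

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample\tA\ns1\t-1\n")
        with pytest.raises(TableFormatError, match="negative count.*s1"):
            read_count_table(p)

    def test_non_integer_count_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample\tA\ns1\t1.5\n")
        with pytest.raises(TableFormatError, match="non-integer"):
            read_count_table(p)

    def test_duplicate_sample_ids_rejected(self):
        df = pd.DataFrame([[1], [2]], index=["s1", "s1"], columns=["a"])
        with pytest.raises(TableFormatError, match="duplicate sample"):
            CountTable(df)

    def test_taxonomy_round_trip(self, tmp_path):
        tax = {
            "a1": TaxonomyAssignment("a1", ("Bacteria", "Proteobacteria")),
            "a2": TaxonomyAssignment("a2", ("Fungi", "Ascomycota")),
        }
        p = tmp_path / "tax.tsv"
        write_taxonomy(tax, p)
        back = read_taxonomy(p)
        assert back == tax

    def test_metadata_unknown_sample_type_rejected(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("sample_id\tsample_type\ns1\tleaf\n")
        with pytest.raises(TableFormatError, match="sample_type"):
            read_metadata(p)


class TestTaxonomyFlags:
    @pytest.mark.parametrize(
        "lineage, flag, value",
        [
            ("Bacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;Mitochondria",
             "is_mitochondria", True),
            ("Bacteria;Cyanobacteria;Oxyphotobacteria;Chloroplast",
             "is_chloroplast", True),
            ("Eukaryota;Viridiplantae;Streptophyta", "is_viridiplantae", True),
            ("Eukaryota;Protista", "is_protista", True),
            ("Bacteria;Firmicutes", "is_bacteria", True),
            ("Fungi;Ascomycota", "is_fungi", True),
            ("Eukaryota;Fungi", "is_fungi", False),  # top rank only
            ("bacteria;firmicutes", "is_bacteria", True),  # case-insensitive
        ],
    )
    def test_flag_rules(self, lineage, flag, value):
        rec = TaxonomyAssignment("x", parse_lineage(lineage))
        assert getattr(rec, flag) is value

    def test_16s_drops_chloroplast(self):
        df = pd.DataFrame([[3, 4]], index=["s1"], columns=["a1", "a2"])
        tax = {
            "a1": TaxonomyAssignment("a1", parse_lineage("Bacteria;Cyanobacteria;Chloroplast")),
            "a2": TaxonomyAssignment("a2", parse_lineage("Bacteria;Firmicutes")),
        }
        out = remove_offtarget_taxa(CountTable(df), tax, "16S")
        assert out.asv_ids == ["a2"]
        assert out.sample_ids == ["s1"]

    def test_its_all_fungi_unchanged(self):
        df = pd.DataFrame([[3, 4]], index=["s1"], columns=["f1", "f2"])
        tax = {a: TaxonomyAssignment(a, ("Fungi", "Ascomycota")) for a in ["f1", "f2"]}
        out = remove_offtarget_taxa(CountTable(df), tax, "ITS")
        assert out.asv_ids == ["f1", "f2"]

    def test_mixed_table_matches_per_asv_oracle(self, rng):
        lineages = [
            "Bacteria;Firmicutes", "Bacteria;Proteobacteria;Mitochondria",
            "Bacteria;Cyanobacteria;Chloroplast", "Archaea;Euryarchaeota",
            "Fungi;Basidiomycota", "Eukaryota;Viridiplantae",
        ]
        asvs = [f"a{i}" for i in range(len(lineages))]
        tax = {a: TaxonomyAssignment(a, parse_lineage(s)) for a, s in zip(asvs, lineages)}
        df = pd.DataFrame(rng.integers(0, 9, (4, len(asvs))),
                          index=[f"s{i}" for i in range(4)], columns=asvs)
        out = remove_offtarget_taxa(CountTable(df), tax, "16S")
        expected = [
            a for a in asvs
            if tax[a].is_bacteria and not tax[a].is_mitochondria and not tax[a].is_chloroplast
        ]
        assert out.asv_ids == expected

    def test_missing_taxonomy_is_error(self, small_table):
        with pytest.raises(TaxonomyError, match="a2"):
            remove_offtarget_taxa(
                small_table,
                {"a1": TaxonomyAssignment("a1", ("Bacteria",))},
                "16S",
            )


class TestRareFilter:
    def _table(self, cols):
        """Build a table from {asv: list of per-sample counts}."""
        df = pd.DataFrame(cols, index=[f"s{i}" for i in range(len(next(iter(cols.values()))))])
        return CountTable(df)

    def test_boundary_semantics(self):
        # 29 reads over 5 samples: below the 30-read floor -> removed
        # 30 reads over exactly 3 samples: both boundaries inclusive -> kept
        # 1000 reads in 2 samples: below the 3-sample floor -> removed
        t = self._table({
            "low_total": [6, 6, 6, 6, 5],
            "boundary": [10, 10, 10, 0, 0],
            "low_prev": [500, 500, 0, 0, 0],
        })
        out = filter_rare_asvs(t)
        assert out.asv_ids == ["boundary"]

    def test_sample_reorder_equivariance(self, random_table, rng):
        perm = list(rng.permutation(random_table.sample_ids))
        direct = filter_rare_asvs(random_table, 5, 2)
        shuffled = filter_rare_asvs(random_table.subset_samples(perm), 5, 2)
        assert direct.asv_ids == shuffled.asv_ids


class TestRarefy:
    def test_conservation_and_bounds(self, random_table):
        out, dropped = rarefy(random_table, 10, rng_seed=1, prune_empty_asvs=False)
        assert (out.data.sum(axis=1) == 10).all()
        orig = random_table.data.loc[out.sample_ids]
        assert (out.data.to_numpy() <= orig.to_numpy()).all()
        # dropped samples are exactly those under depth
        under = random_table.sample_totals() < 10
        assert set(dropped) == set(under.index[under])

    def test_sample_at_exact_depth_unchanged(self):
        df = pd.DataFrame([[3, 4, 3]], index=["s1"], columns=["a", "b", "c"])
        out, _ = rarefy(CountTable(df), 10, rng_seed=0)
        pd.testing.assert_frame_equal(out.data, df.astype(np.int64))

    def test_seed_reproducibility(self, random_table):
        a, _ = rarefy(random_table, 8, rng_seed=42)
        b, _ = rarefy(random_table, 8, rng_seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)
        c, _ = rarefy(random_table, 8, rng_seed=43)
        assert not a.data.equals(c.data)

    def test_expected_counts_hypergeometric(self):
        # mean rarefied count over many draws ~ depth * count/total,
        # within 3 Monte-Carlo standard errors
        counts = np.array([50, 30, 20])
        df = pd.DataFrame([counts], index=["s"], columns=["a", "b", "c"])
        t = CountTable(df)
        depth, reps = 40, 1000
        draws = np.zeros((reps, 3))
        for i in range(reps):
            out, _ = rarefy(t, depth, rng_seed=i, prune_empty_asvs=False)
            draws[i] = out.data.to_numpy()[0]
        expected = depth * counts / counts.sum()
        se = draws.std(axis=0, ddof=1) / np.sqrt(reps)
        assert (np.abs(draws.mean(axis=0) - expected) <= 3 * se + 1e-9).all()

    def test_nonpositive_depth_is_error(self, small_table):
        with pytest.raises(ValueError, match="depth"):
            rarefy(small_table, 0, rng_seed=0)


class TestRelativeAbundance:
    def test_simple_row(self):
        df = pd.DataFrame([[2, 2, 0]], index=["s"], columns=["a", "b", "c"])
        rel = to_relative_abundance(CountTable(df))
        assert rel.data.loc["s"].tolist() == [0.5, 0.5, 0.0]

    def test_rows_sum_to_one(self, random_table):
        rel = to_relative_abundance(random_table)
        assert np.allclose(rel.data.sum(axis=1), 1.0)

    def test_zero_total_sample_is_error(self):
        df = pd.DataFrame([[0, 0]], index=["empty"], columns=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            to_relative_abundance(CountTable(df))
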
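import numpy as np
import pytest

from pmltcr.repertoire_io import (
    ClonotypeRecord,
    RowParseError,
    SampleMetadata,
    SchemaError,
    build_cohort,
    filter_short_cdr3,
    read_clonotype_table,
    read_metadata,
    write_airr,
    write_metadata,
)

AIRR_HEADER = "repertoire_id\tjunction_aa\tjunction\tlocus\tv_call\tj_call\tduplicate_count\n"


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadAirr:
    def test_parses_rows(self, tmp_path):
        p = write(
            tmp_path,
            "t.tsv",
            AIRR_HEADER
            + "S1\tCASSLGF\ttgc\tTRB\tTRBV5-1\tTRBJ2-7\t3\n"
            + "S1\tCAVRDNF\t\tTRA\t\t\t1\n"
            + "S2\tCASSQET\t\t\t\t\t2\n",
        )
        recs = read_clonotype_table(p, dialect="airr")
        assert len(recs) == 3
        assert recs[0] == ClonotypeRecord("S1", "CASSLGF", 3, chain="TRB", cdr3_nt="tgc",
                                          v_call="TRBV5-1", j_call="TRBJ2-7")
        assert recs[2].chain == "unknown"  # empty locus

    def test_header_only_gives_empty_list(self, tmp_path):
        assert read_clonotype_table(write(tmp_path, "e.tsv", AIRR_HEADER)) == []

    def test_missing_column_names_it(self, tmp_path):
        p = write(tmp_path, "m.tsv", "repertoire_id\tjunction_aa\nS1\tCASSF\n")
        with pytest.raises(SchemaError, match="duplicate_count"):
            read_clonotype_table(p)

    def test_unparseable_count_reports_line(self, tmp_path):
        p = write(tmp_path, "u.tsv", AIRR_HEADER + "S1\tCASSLGF\t\tTRB\t\t\tmany\n")
        with pytest.raises(RowParseError, match="line 2"):
            read_clonotype_table(p)

    def test_nonpositive_counts_dropped(self, tmp_path):
        p = write(
            tmp_path, "z.tsv",
            AIRR_HEADER + "S1\tCASSLGF\t\tTRB\t\t\t0\nS1\tCAVRDNF\t\tTRA\t\t\t2\n",
        )
        recs = read_clonotype_table(p)
        assert [r.cdr3_aa for r in recs] == ["CAVRDNF"]

    def test_stop_codon_and_ambiguous_cdr3_dropped(self, tmp_path):
        p = write(
            tmp_path, "s.tsv",
            AIRR_HEADER + "S1\tCAS*LGF\t\tTRB\t\t\t2\nS1\tCAXRDNF\t\tTRA\t\t\t2\n"
            + "S1\tCASSQET\t\tTRB\t\t\t2\n",
        )
        assert [r.cdr3_aa for r in read_clonotype_table(p)] == ["CASSQET"]

    def test_duplicate_rows_preserved_at_read(self, tmp_path):
        p = write(
            tmp_path, "d.tsv",
            AIRR_HEADER + "S1\tCASSLGF\t\tTRB\t\t\t2\nS1\tCASSLGF\t\tTRB\t\t\t3\n",
        )
        recs = read_clonotype_table(p)
        assert len(recs) == 2  # aggregation is deferred to build_cohort


class TestReadTrust:
    def test_parses_with_comments_and_fractional_counts(self, tmp_path):
        p = write(
            tmp_path, "t.tsv",
            "#comment line\nsample\tcount\tCDR3aa\tCDR3nt\tVgene\tJgene\tchain\n"
            + "S1\t2.5\tCASSLGF\ttgc\tTRBV5\tTRBJ2\tTRB\n"
            + "S1\t1.2\tCAVRDNF\t\tTRAV1\tTRAJ3\tTRA\n",
        )
        recs = read_clonotype_table(p, dialect="trust")
        assert recs[0].read_count == 3  # 2.5 rounds half-up
        assert recs[1].read_count == 1
        assert recs[0].v_call == "TRBV5"

    def test_missing_column(self, tmp_path):
        p = write(tmp_path, "m.tsv", "sample\tcount\nS1\t2\n")
        with pytest.raises(SchemaError, match="CDR3aa"):
            read_clonotype_table(p, dialect="trust")


class TestFilterShortCdr3:
    def test_drops_below_six_aa(self):
        recs = [
            ClonotypeRecord("S1", "CASSF", 1, chain="TRB"),   # 5 aa
            ClonotypeRecord("S1", "CASSLF", 1, chain="TRB"),  # 6 aa
        ]
        assert [r.cdr3_aa for r in filter_short_cdr3(recs)] == ["CASSLF"]

    def test_min_one_is_identity(self, tiny_records):
        assert filter_short_cdr3(tiny_records, min_aa=1) == tiny_records

    def test_all_short_gives_empty(self):
        recs = [ClonotypeRecord("S1", "CAS", 1)]
        assert filter_short_cdr3(recs, min_aa=6) == []

    def test_idempotent(self, tiny_records):
        once = filter_short_cdr3(tiny_records)
        assert filter_short_cdr3(once) == once

    def test_commutes_with_cohort_aggregation(self, tiny_records, tiny_metadata):
        filtered_first = build_cohort(filter_short_cdr3(tiny_records, 7), tiny_metadata)
        built_first = build_cohort(tiny_records, tiny_metadata)
        keys_a = set(filtered_first.universe)
        keys_b = {k for k in built_first.universe if len(k[1]) >= 7}
        assert keys_a == keys_b


class TestBuildCohort:
    def test_duplicate_rows_summed(self, tiny_metadata):
        recs = [
            ClonotypeRecord("S1", "CASSLGF", 2, chain="TRB"),
            ClonotypeRecord("S1", "CASSLGF", 3, chain="TRB"),
        ]
        cohort = build_cohort(recs, tiny_metadata)
        assert len(cohort.records) == 1
        assert cohort.records["read_count"].iloc[0] == 5

    def test_universe_counts_distinct_keys(self, tiny_cohort):
        assert len(tiny_cohort.universe) == 3

    def test_totals_match_independent_sums(self, tiny_records, tiny_cohort):
        totals = tiny_cohort.sample_totals.set_index("sample_id")
        for sid in ("S1", "S2", "S3"):
            expected = sum(r.read_count for r in tiny_records if r.sample_id == sid)
            assert totals.loc[sid, "total_reads"] == expected

    def test_orphan_sample_listed(self, tiny_records, tiny_metadata):
        orphan = ClonotypeRecord("S9", "CASSQET", 1, chain="TRB")
        with pytest.raises(ValueError, match="S9"):
            build_cohort(tiny_records + [orphan], tiny_metadata)

    def test_universe_invariant_under_row_permutation(self, tiny_records, tiny_metadata):
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = list(tiny_records)
            rng.shuffle(shuffled)
            assert build_cohort(shuffled, tiny_metadata).universe == build_cohort(
                tiny_records, tiny_metadata
            ).universe

    def test_pool_chains_merges_across_loci(self, tiny_metadata):
        recs = [
            ClonotypeRecord("S1", "CASSLGF", 2, chain="TRB"),
            ClonotypeRecord("S1", "CASSLGF", 3, chain="TRA"),
        ]
        pooled = build_cohort(recs, tiny_metadata, pool_chains=True)
        assert len(pooled.universe) == 1
        assert pooled.records["read_count"].sum() == 5
        separate = build_cohort(recs, tiny_metadata, pool_chains=False)
        assert len(separate.universe) == 2


class TestWriteAirr:
    def test_round_trip_preserves_record_multiset(self, tiny_cohort, tiny_metadata, tmp_path):
        p = tmp_path / "out.tsv"
        write_airr(tiny_cohort, p)
        back = build_cohort(read_clonotype_table(p), tiny_metadata)
        assert back.records.equals(tiny_cohort.records)

    def test_empty_cohort_writes_header_only(self, tiny_metadata, tmp_path):
        p = tmp_path / "empty.tsv"
        write_airr(build_cohort([], tiny_metadata), p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("repertoire_id\t")

    def test_unknown_chain_emits_empty_locus(self, tiny_metadata, tmp_path):
        cohort = build_cohort([ClonotypeRecord("S1", "CASSLGF", 1)], tiny_metadata)
        p = tmp_path / "u.tsv"
        write_airr(cohort, p)
        row = p.read_text().splitlines()[1].split("\t")
        assert row[3] == ""  # locus column

    def test_metadata_round_trip(self, tiny_cohort, tmp_path):
        p = tmp_path / "meta.tsv"
        write_metadata(tiny_cohort, p)
        metas = read_metadata(p)
        assert [m.sample_id for m in metas] == ["S1", "S2", "S3"]
        assert metas[0].outcome == "regressive"
        assert metas[2].subtype == "other"


class TestRecordValidation:
    def test_rejects_nonpositive_count(self):
        with pytest.raises(ValueError):
            ClonotypeRecord("S1", "CASSLGF", 0)

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            ClonotypeRecord("S1", "CASS1GF", 1)

    def test_rejects_bad_chain(self):
        with pytest.raises(ValueError):
            ClonotypeRecord("S1", "CASSLGF", 1, chain="IGH")

    def test_metadata_rejects_duplicate_lesion_sample(self):
        metas = [
            SampleMetadata("A", "P1", "L1", 1),
            SampleMetadata("B", "P1", "L1", 1),
        ]
        with pytest.raises(ValueError, match="share"):
            build_cohort([], metas)
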
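"""Mutation table I/O, quality filters, annotation and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoedit.mutation_io import (
    MutationTable,
    SchemaError,
    annotate_consequence,
    annotate_context,
    apply_quality_filters,
    read_mutation_table,
    set_neoantigen_flags,
    summarize_samples,
    write_mutation_table,
)


def _write_maf(path, rows, header=None):
    header = header or (
        "Tumor_Sample_Barcode\tTranscript_ID\tCDS_Position\tReference_Allele\t"
        "Tumor_Seq_Allele2\tVAF\tt_alt_count\tt_depth\tFILTER"
    )
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


def test_read_toy_maf(tmp_path):
    maf = tmp_path / "toy.maf"
    _write_maf(
        maf,
        [
            "S1\tT1\t5\tA\tG\t0.4\t10\t40\tPASS",
            "S1\tT1\t8\tC\tT\t0.2\t5\t30\tPASS",
            "S2\tT1\t5\tA\tC\t0.3\t9\t35\tPASS",
        ],
    )
    table = read_mutation_table(maf)
    assert len(table) == 3
    assert list(table.df["sample"]) == ["S1", "S1", "S2"]
    assert table.provenance[0]["skipped_non_snv"] == 0


def test_non_snv_rows_skipped(tmp_path):
    maf = tmp_path / "toy.maf"
    _write_maf(
        maf,
        [
            "S1\tT1\t5\tAT\tG\t0.4\t10\t40\tPASS",  # dinucleotide ref
            "S1\tT1\t8\tC\tT\t0.2\t5\t30\tPASS",
        ],
    )
    table = read_mutation_table(maf)
    assert len(table) == 1
    assert table.provenance[0]["skipped_non_snv"] == 1


def test_missing_mandatory_column(tmp_path):
    maf = tmp_path / "toy.maf"
    maf.write_text("Tumor_Sample_Barcode\tReference_Allele\nS1\tA\n")
    with pytest.raises(SchemaError, match="Transcript_ID"):
        read_mutation_table(maf)


def test_write_read_round_trip(tmp_path, baseline_cohort):
    out = tmp_path / "cohort.tsv"
    head = MutationTable(baseline_cohort.df.head(50).copy())
    write_mutation_table(head, out)
    back = read_mutation_table(
        out,
        column_map={
            "sample": "sample", "transcript": "transcript", "cds_pos": "cds_pos",
            "ref": "ref", "alt": "alt", "vaf": "vaf", "alt_count": "alt_count",
            "depth": "depth", "filter": "filter", "ccf": "ccf",
            "is_neoantigen": "is_neoantigen", "affinity": "affinity",
        },
    )
    for col in ["sample", "transcript", "cds_pos", "ref", "alt"]:
        assert list(back.df[col]) == list(head.df[col])
    np.testing.assert_allclose(back.df["ccf"], head.df["ccf"])


@pytest.mark.parametrize(
    "alt,vaf,depth,kept",
    [
        (3, 0.01, 16, True),   # boundary: all thresholds inclusive except depth
        (2, 0.5, 40, False),   # alt below minimum
        (3, 0.009, 40, False), # VAF below minimum
        (10, 0.5, 15, False),  # depth threshold is strict
    ],
)
def test_quality_filter_boundaries(make_mutations, alt, vaf, depth, kept):
    table = make_mutations(
        [dict(sample="S1", transcript="T1", cds_pos=5, ref="A", alt="G",
              vaf=vaf, alt_count=alt, depth=depth, filter="PASS")]
    )
    out = apply_quality_filters(table)
    assert (len(out) == 1) is kept


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_quality_filter_matches_predicate_scan(seed):
    """Random 100-record table: kept set equals an independent predicate scan."""
    rng = np.random.default_rng(seed)
    n = 100
    df = pd.DataFrame(
        {
            "sample": "S",
            "transcript": "T",
            "cds_pos": np.arange(n),
            "ref": "A",
            "alt": "G",
            "vaf": rng.uniform(0, 0.05, n),
            "alt_count": rng.integers(0, 6, n),
            "depth": rng.integers(10, 20, n),
            "filter": rng.choice(["PASS", "germline"], n),
        }
    )
    table = MutationTable(df.copy())
    out = apply_quality_filters(table, min_alt=3, min_vaf=0.01, min_depth=15, pass_only=True)
    expected = [
        i
        for i in range(n)
        if df.loc[i, "alt_count"] >= 3
        and df.loc[i, "vaf"] >= 0.01
        and df.loc[i, "depth"] > 15
        and df.loc[i, "filter"] == "PASS"
    ]
    assert list(out.df["cds_pos"]) == [df.loc[i, "cds_pos"] for i in expected]
    # idempotence: filtering again changes nothing
    again = apply_quality_filters(out, min_alt=3, min_vaf=0.01, min_depth=15, pass_only=True)
    assert len(again) == len(out)


def test_context_annotation_read_off(make_mutations, small_region_set):
    cds = small_region_set["T1"].cds
    p = cds.index("AAA") + 1  # middle base of an AAA trinucleotide
    table = make_mutations(
        [dict(sample="S1", transcript="T1", cds_pos=p, ref="A", alt="G")]
    )
    out = annotate_context(table, small_region_set)
    assert out.df.loc[0, "context"] == "A[A>G]A"
    assert out.df.loc[0, "context96"] == "T[T>C]T"


def test_context_edge_positions_missing(make_mutations, small_region_set):
    cds = small_region_set["T1"].cds
    table = make_mutations(
        [
            dict(sample="S1", transcript="T1", cds_pos=0, ref=cds[0], alt="C"),
            dict(sample="S1", transcript="T1", cds_pos=len(cds) - 1, ref=cds[-1], alt="C"),
        ]
    )
    out = annotate_context(table, small_region_set)
    assert out.df["context"].isna().all()


def test_context_ref_mismatch_raises(make_mutations, small_region_set):
    cds = small_region_set["T1"].cds
    wrong = "C" if cds[5] != "C" else "G"
    table = make_mutations(
        [dict(sample="S1", transcript="T1", cds_pos=5, ref=wrong, alt="T")]
    )
    from immunoedit.mutation_io import AnnotationError

    with pytest.raises(AnnotationError):
        annotate_context(table, small_region_set)


def test_consequence_against_codon_table(make_mutations, small_region_set):
    """Leu->Leu synonymous; Trp->stop nonsynonymous; outside CDS -> other."""
    cds = small_region_set["T1"].cds
    # CTG codon at positions 9-11 (ATG GCT AAA CTG ...); TGG codon at 30-32
    assert cds[9:12] == "CTG" and cds[30:33] == "TGG"
    table = make_mutations(
        [
            dict(sample="S1", transcript="T1", cds_pos=11, ref="G", alt="A"),  # CTG->CTA
            dict(sample="S1", transcript="T1", cds_pos=31, ref="G", alt="A"),  # TGG->TAG
            dict(sample="S1", transcript="T1", cds_pos=999, ref="A", alt="G"),
        ]
    )
    out = annotate_consequence(table, small_region_set)
    assert list(out.df["consequence"]) == ["synonymous", "nonsynonymous", "other"]


def test_gct_codon_substitution_split(make_mutations):
    """All 9 substitutions of codon GCT: 3 synonymous (third position), 6 not."""
    from immunoedit.regions import CodingRegion, CodingRegionSet

    regions = CodingRegionSet([CodingRegion("G", "c", "+", ((0, 9),), "ATGGCTTAA"[:9])])
    rows = []
    for p, ref in [(3, "G"), (4, "C"), (5, "T")]:
        for alt in "ACGT":
            if alt != ref:
                rows.append(dict(sample="S1", transcript="G", cds_pos=p, ref=ref, alt=alt))
    out = annotate_consequence(make_mutations(rows), regions)
    counts = out.df["consequence"].value_counts()
    assert counts["synonymous"] == 3
    assert counts["nonsynonymous"] == 6


def test_neoantigen_flag_precedence(make_mutations):
    table = make_mutations(
        [
            dict(sample="S", transcript="T", cds_pos=1, ref="A", alt="G",
                 consequence="nonsynonymous", affinity=100.0, is_neoantigen=False),
            dict(sample="S", transcript="T", cds_pos=2, ref="A", alt="G",
                 consequence="nonsynonymous", affinity=100.0),
            dict(sample="S", transcript="T", cds_pos=3, ref="A", alt="G",
                 consequence="synonymous", affinity=100.0),
            dict(sample="S", transcript="T", cds_pos=4, ref="A", alt="G",
                 consequence="nonsynonymous", affinity=600.0),
        ]
    )
    out = set_neoantigen_flags(table)
    assert list(out.df["is_neoantigen"]) == [False, True, False, False]


def test_sample_summaries(make_mutations):
    rows = []
    for i in range(1001):
        rows.append(dict(sample="HM", transcript="T", cds_pos=i, ref="A", alt="G",
                         consequence="nonsynonymous", is_neoantigen=i < 5))
    rows.append(dict(sample="LO", transcript="T", cds_pos=0, ref="A", alt="G",
                     consequence="synonymous", is_neoantigen=False))
    table = make_mutations(rows)
    out = summarize_samples(table, exome_size_mb=38.0, hypermutation_threshold=1000)
    hm = out.set_index("sample").loc["HM"]
    assert hm["hypermutated"]          # 1,001 > 1,000
    assert hm["nobs"] == 1001 and hm["bobs"] == 5
    lo = out.set_index("sample").loc["LO"]
    assert not lo["hypermutated"]
    assert lo["sobs"] == 1 and lo["bobs"] <= lo["nobs"] + lo["sobs"]


def test_tmb_group_boundaries(make_mutations):
    rows = [dict(sample="M", transcript="T", cds_pos=i, ref="A", alt="G",
                 consequence="other") for i in range(50)]
    out = summarize_samples(make_mutations(rows), exome_size_mb=10.0)
    assert out.loc[0, "tmb"] == 5.0
    assert out.loc[0, "tmb_group"] == "TMB-medium"  # 5 <= TMB < 20
    with pytest.raises(ValueError):
        summarize_samples(make_mutations(rows), exome_size_mb=0)


def test_summary_counts_match_brute_tally(baseline_cohort):
    out = summarize_samples(baseline_cohort)
    df = baseline_cohort.df
    for _, row in out.head(5).iterrows():
        g = df[df["sample"] == row["sample"]]
        assert row["nobs"] == (g["consequence"] == "nonsynonymous").sum()
        assert row["sobs"] == (g["consequence"] == "synonymous").sum()
        assert row["bobs"] == g["is_neoantigen"].fillna(False).astype(bool).sum()
        assert row["bobs"] <= row["nobs"] <= row["n_total"]
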
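"""Annotation cascade, collapsing and CPM quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from piriscope import annotate as ann
from piriscope.io import FastqParseError, write_fastq
from piriscope.types import CASCADE_ORDER, ReferenceBundle


def _tiny_bundle():
    """Handcrafted bundle with a sequence shared by miRNA and piRNA DBs."""
    shared = "ACGTACGTACGTACGTACGTAC"
    pir_only = "TTTTGGGGCCCCAAAATTTTGG"
    genomic_only = "GGCCGGCCGGCCGGCCGGCCGG"
    genome = {"chr1": "TTAA" + shared + "CCGG" + pir_only + "AT" + genomic_only + "AA"}
    dbs = {name: {} for name in CASCADE_ORDER}
    dbs["miRNA"]["miR-1"] = shared
    dbs["piRNA"]["piR-1"] = shared
    dbs["piRNA"]["piR-2"] = pir_only
    return ReferenceBundle(
        genome=genome, db_list=[(n, dbs[n]) for n in CASCADE_ORDER], transcripts=[]
    ), shared, pir_only, genomic_only


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------

def test_collapse_matches_dictionary_oracle(tmp_path):
    rng = np.random.default_rng(42)
    seqs = ["".join(rng.choice(list("ACGT"), size=rng.integers(15, 50)))
            for _ in range(100)]
    path = tmp_path / "lib.fastq"
    write_fastq(path, ((f"r{i}", s) for i, s in enumerate(seqs)))

    table = ann.collapse_reads(path, (18, 45), sample="lib")
    oracle: dict[str, int] = {}
    dropped = 0
    for s in seqs:
        if 18 <= len(s) <= 45:
            oracle[s] = oracle.get(s, 0) + 1
        else:
            dropped += 1
    assert table["count_lib"].to_dict() == oracle
    assert table.attrs["dropped"] == dropped
    assert table.attrs["total_retained"] == sum(oracle.values())


def test_identical_reads_merge_and_short_reads_drop(tmp_path):
    path = tmp_path / "r.fastq"
    write_fastq(path, [("a", "A" * 26), ("b", "A" * 26), ("c", "A" * 26),
                       ("d", "C" * 15)])
    table = ann.collapse_reads(path, (18, 45))
    assert table.iloc[0, 0] == 3 and len(table) == 1
    assert table.attrs["dropped"] == 1


def test_malformed_fastq_reports_line_number(tmp_path):
    path = tmp_path / "bad.fastq"
    path.write_text("@r1\nACGTACGTACGTACGTACGT\nOOPS\nIIIIIIIIIIIIIIIIIIII\n")
    with pytest.raises(FastqParseError, match="line 3"):
        ann.collapse_reads(path)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.text(alphabet="ACGT", min_size=10, max_size=50), max_size=60))
def test_collapse_conserves_reads(seqs):
    table = ann.collapse_sequences(seqs, (18, 45))
    n_in_window = sum(1 for s in seqs if 18 <= len(s) <= 45)
    assert table.attrs["total_retained"] + table.attrs["dropped"] == len(seqs)
    assert table.attrs["total_retained"] == n_in_window


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def test_earlier_cascade_level_shadows_pirna():
    bundle, shared, pir_only, genomic_only = _tiny_bundle()
    out = ann.cascade_annotate([shared, pir_only, genomic_only, "T" * 25], bundle)
    assert out.loc[shared, "category"] == "miRNA"
    assert out.loc[shared, "db_hit_id"] == "miR-1"
    assert out.loc[pir_only, "category"] == "piRNA"
    assert out.loc[genomic_only, "category"] == "unannotated_genomic"
    assert out.loc["T" * 25, "category"] == "unmatched"
    assert not out.loc["T" * 25, "genome_matched"]


def test_empty_bundle_is_a_configuration_error():
    empty = ReferenceBundle(genome={}, db_list=[], transcripts=[])
    with pytest.raises(ValueError, match="bundle"):
        ann.cascade_annotate(["ACGT" * 6], empty)


def _cascade_oracle(seq, bundle, k=0):
    """Exhaustive scan over every DB, applying the priority order at the
    end; independent of the implementation's first-hit-wins loop."""
    from piriscope.annotate import _hamming_contains

    hits = {}
    for name, db in bundle.db_list:
        ids = sorted(
            i for i, entry in db.items()
            if (seq in entry if k == 0 else _hamming_contains(entry, seq, k))
        )
        if ids:
            hits[name] = ids[0]
    for name in bundle.cascade_order:
        if name in hits:
            return name, hits[name]
    genome = any(
        (seq in c if k == 0 else _hamming_contains(c, seq, k))
        for c in bundle.genome.values()
    )
    return ("unannotated_genomic" if genome else "unmatched"), ""


def test_cascade_equals_exhaustive_scan_oracle(study):
    bundle, molecules, _ = study
    rng = np.random.default_rng(0)
    seqs = [m.sequence for m in molecules[::3]]
    seqs += ["".join(rng.choice(list("ACGT"), size=24)) for _ in range(40)]
    out = ann.cascade_annotate(seqs, bundle)
    for seq in seqs:
        cat, hit = _cascade_oracle(seq, bundle)
        assert out.loc[seq, "category"] == cat
        assert out.loc[seq, "db_hit_id"] == hit


def test_cascade_invariant_to_db_internal_order(study):
    bundle, molecules, _ = study
    seqs = [m.sequence for m in molecules[::5]]
    out1 = ann.cascade_annotate(seqs, bundle)
    shuffled = ReferenceBundle(
        genome=bundle.genome,
        db_list=[(n, dict(reversed(list(db.items())))) for n, db in bundle.db_list],
        transcripts=bundle.transcripts,
    )
    out2 = ann.cascade_annotate(seqs, shuffled)
    pd.testing.assert_series_equal(out1["category"], out2["category"])


def test_mismatch_tolerance_is_monotone(study):
    bundle, molecules, _ = study
    seqs = [m.sequence for m in molecules[:15]]
    # one-substitution variants of real piRNAs
    variants = []
    for s in seqs[:5]:
        alt = "A" if s[10] != "A" else "C"
        variants.append(s[:10] + alt + s[11:])
    out0 = ann.cascade_annotate(seqs + variants, bundle, mismatches=0)
    out1 = ann.cascade_annotate(seqs + variants, bundle, mismatches=1)
    annotated0 = (out0["category"] != "unmatched").sum()
    annotated1 = (out1["category"] != "unmatched").sum()
    assert annotated1 >= annotated0
    # a 1-mismatch variant is recovered only at k=1
    assert (out1.loc[variants, "category"] != "unmatched").all()


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------

def test_cpm_formula_and_conservation():
    table = pd.DataFrame(
        {"count_s": [1, 249, 750_000, 249_750]},
        index=pd.Index(["A" * 20, "C" * 20, "G" * 20, "T" * 20], name="sequence"),
    )
    out = ann.compute_cpm(table)
    total = table["count_s"].sum()
    expected = table["count_s"] * 1e6 / total
    assert np.allclose(out["cpm_s"], expected)
    assert abs(out["cpm_s"].sum() - 1e6) < 1e-6 * 1e6


def test_single_sequence_library_gets_full_million():
    table = pd.DataFrame({"count_s": [123]}, index=pd.Index(["ACGT" * 5]))
    assert ann.compute_cpm(table)["cpm_s"].iloc[0] == pytest.approx(1e6)


def test_zero_total_sample_is_an_error():
    table = pd.DataFrame({"count_s": [0, 0]}, index=pd.Index(["AAAA", "CCCC"]))
    with pytest.raises(ValueError, match="zero retained"):
        ann.compute_cpm(table)


def test_expression_filter_is_strictly_greater():
    table = pd.DataFrame(
        {"count_s": [1, 2, 0], "cpm_s": [0.1, 0.2, 0.0]},
        index=pd.Index(["AA", "CC", "GG"], name="sequence"),
    )
    out = ann.filter_expressed(table, 0.1)
    assert list(out.index) == ["CC"]  # cpm exactly at threshold is removed
    assert out.attrs["filtered_out"] == 2
    out0 = ann.filter_expressed(table, 0.0)
    assert list(out0.index) == ["AA", "CC"]  # only zero-cpm rows removed


def test_category_composition_fractions(annotations):
    comp = ann.category_composition(annotations)
    assert np.allclose(comp.sum(axis=0), 1.0, atol=1e-9)
    # hand-check one category against raw ratios
    counts = annotations.groupby("category")["count_NT"].sum()
    assert comp.loc["piRNA", "NT"] == pytest.approx(
        counts["piRNA"] / counts.sum()
    )


def test_single_category_composition_is_unity():
    table = pd.DataFrame(
        {"category": ["piRNA", "piRNA"], "count_x": [3, 7]},
        index=pd.Index(["AAAA", "CCCC"], name="sequence"),
    )
    comp = ann.category_composition(table)
    assert comp.loc["piRNA", "x"] == 1.0
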
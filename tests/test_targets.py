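"""Long-read extraction, transcript mapping and complementarity pairing."""

import numpy as np
import pandas as pd
import pytest

import piriscope as ps
from piriscope import targets as tgt
from piriscope.io import write_fastq
from piriscope.simulate import reverse_complement
from piriscope.types import TranscriptRecord


def _transcript(seq, utr5=10, cds=20, tid="T1"):
    n = len(seq)
    return TranscriptRecord(tid, seq, (0, utr5), (utr5, utr5 + cds),
                            (utr5 + cds, n))


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def test_long_read_window_boundaries_exact(tmp_path):
    reads = [("a", "A" * 45), ("b", "C" * 46), ("c", "G" * 75), ("d", "T" * 76)]
    path = tmp_path / "lib.fastq"
    write_fastq(path, reads)
    table = tgt.extract_long_reads(path, sample="lib")
    assert set(table.index) == {"C" * 46, "G" * 75}


def test_empty_library_gives_empty_table(tmp_path):
    path = tmp_path / "empty.fastq"
    path.write_text("")
    table = tgt.extract_long_reads(path, sample="x")
    assert len(table) == 0


def test_window_filter_equals_length_oracle(tmp_path):
    rng = np.random.default_rng(1)
    reads = [("r%d" % i, "".join(rng.choice(list("ACGT"), size=L)))
             for i, L in enumerate(rng.integers(30, 90, size=80))]
    path = tmp_path / "mix.fastq"
    write_fastq(path, reads)
    table = tgt.extract_long_reads(path, sample="mix")
    oracle = {s for _, s in reads if 46 <= len(s) <= 75}
    assert set(table.index) == oracle


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

def test_mapping_counts_and_fractional_assignment():
    t1 = _transcript("A" * 30 + "CCGGTTAACCGGTTAACCGGTTAACCGGTTAACCGGTTAACCGGTTAA", tid="T1")
    shared = t1.sequence[25:75]
    t2 = _transcript("G" * 10 + shared + "C" * 20, tid="T2")
    unique = t1.sequence[0:48]
    reads = pd.DataFrame(
        {"count_s": [2, 4]},
        index=pd.Index([unique, shared], name="sequence"),
    )
    m = tgt.map_to_transcripts(reads, [t1, t2])
    assert m.loc["T1", "count_s"] == pytest.approx(2 + 4 * 0.5)
    assert m.loc["T2", "count_s"] == pytest.approx(4 * 0.5)
    m_int = tgt.map_to_transcripts(reads, [t1, t2], fractional=False)
    assert m_int.loc["T1", "count_s"] == 6


def test_mapping_equals_bruteforce_scan_oracle(study, rip_design):
    bundle, _, _ = study
    counts, _ = rip_design
    long_tab = tgt.extract_long_reads_table(counts).head(200)
    reads = long_tab.rename(columns={c: f"count_{c}" for c in long_tab.columns})
    matrix = tgt.map_to_transcripts(reads, bundle.transcripts)
    oracle = pd.DataFrame(0.0, index=matrix.index, columns=matrix.columns)
    for seq in reads.index:
        hits = [t.transcript_id for t in bundle.transcripts if seq in t.sequence]
        for tid in hits:
            oracle.loc[tid] += reads.loc[seq].to_numpy() / len(hits)
    pd.testing.assert_frame_equal(matrix, oracle)


def test_empty_transcript_set_rejected():
    reads = pd.DataFrame({"count_s": [1]}, index=pd.Index(["A" * 50]))
    with pytest.raises(ValueError, match="empty"):
        tgt.map_to_transcripts(reads, [])


# ---------------------------------------------------------------------------
# complementarity scanning
# ---------------------------------------------------------------------------

def _scan_oracle(pirna, transcript, seed_start=2, seed_end=11,
                 min_comp=0.8, wobble=True):
    """Independent scanner in the reverse-complement representation: the
    site matches where the transcript window agrees with revcomp(piRNA),
    with wobble equivalences expressed on the revcomp string."""
    rc = reverse_complement(pirna)
    L = len(pirna)
    out = []
    for start in range(len(transcript.sequence) - L + 1):
        window = transcript.sequence[start:start + L]
        mism = 0
        seed_ok = True
        for j, (w, r) in enumerate(zip(window, rc)):
            pirna_pos = L - j  # 1-based position of the piRNA base facing j
            paired = w == r
            # piRNA G : transcript T <=> revcomp base C facing T;
            # piRNA T : transcript G <=> revcomp base A facing G
            wob = (r == "C" and w == "T") or (r == "A" and w == "G")
            in_seed = seed_start <= pirna_pos <= seed_end
            if paired:
                continue
            if in_seed:
                seed_ok = False
                break
            if wobble and wob:
                continue
            mism += 1
        if seed_ok and (L - mism) / L >= min_comp:
            out.append((start, mism))
    return out


def test_exact_reverse_complement_in_utr3_yields_one_clean_site():
    rng = np.random.default_rng(5)
    pirna = "".join(rng.choice(list("ACGT"), size=26))
    backbone = "".join(rng.choice(list("ACGT"), size=100))
    seq = backbone[:80] + reverse_complement(pirna) + backbone[80:]
    t = _transcript(seq, utr5=20, cds=40)
    sites = tgt.scan_target_sites(pirna, t)
    exact = [s for s in sites if s.mismatches == 0]
    assert len(exact) == 1
    s = exact[0]
    assert s.start == 80 and s.region == "utr3" and s.seed_perfect


def test_shuffled_pirna_finds_no_sites():
    rng = np.random.default_rng(6)
    pirna = "".join(rng.choice(list("ACGT"), size=28))
    transcript = _transcript("".join(rng.choice(list("ACGT"), size=400)))
    shuffled = "".join(rng.permutation(list(pirna)))
    assert tgt.scan_target_sites(shuffled, transcript) == []


def test_scanner_equals_exhaustive_offset_oracle():
    rng = np.random.default_rng(9)
    pirnas = ["".join(rng.choice(list("ACGT"), size=L))
              for L in (20, 24, 27, 31, 35)]
    transcripts = []
    for i in range(3):
        seq = "".join(rng.choice(list("ACGT"), size=250))
        # plant a perfect site and a near-perfect (2 non-seed mismatches) one
        rc = reverse_complement(pirnas[i])
        seq = seq[:50] + rc + seq[50 + len(rc):]
        noisy = list(reverse_complement(pirnas[(i + 1) % 5]))
        noisy[0] = "A" if noisy[0] != "A" else "C"
        noisy[1] = "A" if noisy[1] != "A" else "C"
        seq = seq[:150] + "".join(noisy) + seq[150 + len(noisy):]
        transcripts.append(_transcript(seq, utr5=60, cds=80, tid=f"T{i}"))
    for pirna in pirnas:
        for t in transcripts:
            got = [(s.start, s.mismatches) for s in tgt.scan_target_sites(pirna, t)]
            assert got == _scan_oracle(pirna, t), (pirna, t.transcript_id)


def test_relaxing_complementarity_never_loses_sites():
    rng = np.random.default_rng(10)
    pirna = "".join(rng.choice(list("ACGT"), size=26))
    seq = "".join(rng.choice(list("ACGT"), size=150))
    seq += reverse_complement(pirna) + "".join(rng.choice(list("ACGT"), size=50))
    t = _transcript(seq)
    previous: set = set()
    for threshold in (1.0, 0.9, 0.8, 0.7):
        now = {s.start for s in tgt.scan_target_sites(
            pirna, t, min_complementarity=threshold)}
        assert previous <= now
        previous = now


def test_short_or_long_pirna_rejected():
    t = _transcript("ACGT" * 30)
    with pytest.raises(ValueError, match="20-35"):
        tgt.scan_target_sites("ACGT", t)


# ---------------------------------------------------------------------------
# enrichment + pairing
# ---------------------------------------------------------------------------

def _fragment_design(transcript_ids, enriched_ids, reps=3):
    classes = {f"{cls}_rep{r + 1}": cls for cls in ("input", "IP1", "IP2", "NoAb")
               for r in range(reps)}
    rows = {}
    for tid in transcript_ids:
        row = {}
        for col, cls in classes.items():
            if tid in enriched_ids:
                row[col] = 200 if cls in ("IP1", "IP2") else 0
            else:
                row[col] = 50
        rows[tid] = row
    m = pd.DataFrame(rows).T
    m.index.name = "transcript_id"
    m.columns = [f"count_{c}" for c in m.columns]
    return m, classes


def test_ip_only_fragments_are_enriched_uniform_are_not():
    matrix, classes = _fragment_design(["T1", "T2", "T3"], {"T1"})
    res = tgt.test_transcript_enrichment(matrix, classes)
    assert res.loc["T1", "bound"]
    assert not res.loc["T2", "bound"] and not res.loc["T3", "bound"]


def test_pairing_requires_both_memberships_and_sites(study):
    bundle, molecules, truth = study
    ttruth = truth.attrs["transcripts"]
    targets = ttruth[ttruth["role"] == "target"]
    bound = list(targets["pirna_sequence"].unique())
    enriched = list(targets["transcript_id"]) + ["ENST_SYN00019"]  # idle decoy
    pairs, sites, summary = tgt.pair_pirna_targets(
        bound, enriched, bundle.transcripts
    )
    got = set(zip(pairs["pirna_sequence"], pairs["transcript_id"]))
    planted = set(zip(targets["pirna_sequence"], targets["transcript_id"]))
    assert planted <= got
    # output is a subset of the Cartesian product of the two input sets
    assert got <= set(zip(
        np.repeat(bound, len(enriched)), list(enriched) * len(bound)
    ))
    assert sum(summary.values()) == len(sites)
    # region labels agree with an independent interval lookup
    by_id = {t.transcript_id: t for t in bundle.transcripts}
    for _, s in sites.iterrows():
        t = by_id[s["transcript_id"]]
        spans = {"utr5": t.utr5, "cds": t.cds, "utr3": t.utr3}
        lo, hi = spans[s["region"]]
        assert lo <= s["start"] < hi


def test_no_sites_gives_empty_pair_table(study):
    bundle, _, _ = study
    pairs, sites, summary = tgt.pair_pirna_targets(
        ["A" * 26], [bundle.transcripts[0].transcript_id], bundle.transcripts
    )
    assert len(pairs) == 0 and len(sites) == 0
    assert summary == {"utr5": 0, "cds": 0, "utr3": 0}
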
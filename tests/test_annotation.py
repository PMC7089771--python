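"""Annotation parsing, isoform selection, and stop-codon landmarks."""

import numpy as np
import pytest

from riboscr.annotation import (
    STOP_CODONS,
    TranscriptModel,
    find_landmarks,
    parse_annotation,
    reverse_complement,
    select_transcripts,
)

from conftest import make_transcript


def _write_toy_gtf(tmp_path, chrom_seq, rows, chrom="chrT"):
    fasta = tmp_path / "g.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{chrom}\n{chrom_seq}\n")
    gtf = tmp_path / "g.gtf"
    with open(gtf, "w") as fh:
        for feat, start, end, strand, attrs in rows:
            fh.write(f"{chrom}\ttest\t{feat}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n")
    return str(gtf), str(fasta)


def test_parse_single_exon_plus_strand(tmp_path):
    """Identity case: 120-nt single-exon gene, CDS at transcript 30..90."""
    rng = np.random.default_rng(0)
    # CDS occupies 30..90 incl stop: sense codons then TAA at 87..90
    seq = "".join(rng.choice(list("ACG"), size=120))  # no T -> no stray stops
    seq = seq[:30] + "ATG" + seq[33:87] + "TAA" + seq[90:]
    attrs = 'gene_id "G1"; transcript_id "T1"; gene_type "protein_coding"; transcript_type "protein_coding";'
    rows = [
        ("gene", 1, 120, "+", attrs),
        ("transcript", 1, 120, "+", attrs),
        ("exon", 1, 120, "+", attrs),
        ("CDS", 31, 87, "+", attrs),  # GENCODE: excludes the stop codon
        ("stop_codon", 88, 90, "+", attrs),
    ]
    gtf, fasta = _write_toy_gtf(tmp_path, seq, rows)
    models, pseudo = parse_annotation(gtf, fasta)
    assert len(models) == 1 and not pseudo
    t = models[0]
    assert (t.cds_start, t.cds_end) == (30, 90)
    assert t.seq == seq
    assert t.stop_codon == "TAA"


def test_parse_extends_cds_when_stop_codon_feature_absent(tmp_path):
    """Without a stop_codon feature the CDS is extended 3 nt after a sequence check."""
    seq = "A" * 30 + "ATG" + "GCC" * 18 + "TAA" + "C" * 30
    attrs = 'gene_id "G1"; transcript_id "T1"; transcript_type "protein_coding";'
    n = len(seq)
    rows = [
        ("gene", 1, n, "+", attrs),
        ("transcript", 1, n, "+", attrs),
        ("exon", 1, n, "+", attrs),
        ("CDS", 31, 30 + 3 + 18 * 3, "+", attrs),
    ]
    gtf, fasta = _write_toy_gtf(tmp_path, seq, rows)
    models, _ = parse_annotation(gtf, fasta)
    assert len(models) == 1
    assert models[0].cds_end - models[0].cds_start == 3 * 20
    assert models[0].stop_codon == "TAA"


def test_parse_minus_strand_two_exons(tmp_path):
    """Minus-strand splicing: transcript equals revcomp of concatenated exons."""
    # hand-built 57-nt transcript: 12 nt UTR5 + 27 nt CDS (incl TGA) + 18 nt UTR3
    tx = "A" * 12 + "ATG" + "GCCGCAGGT" * 2 + "CAT" + "TGA" + "C" * 18
    assert len(tx) == 57
    genomic_tx = reverse_complement(tx)  # the genome's plus-strand copy
    intron = "G" * 10
    # chrom: 5 nt pad | genomic_tx[0:35] | intron | genomic_tx[35:57] | 5 nt pad
    chrom_seq = "T" * 5 + genomic_tx[:35] + intron + genomic_tx[35:] + "T" * 5

    # genomic coordinate (0-based) of genomic_tx index i, then of transcript pos p
    def g(i):
        return 5 + i if i < 35 else 15 + i

    def span(a, b):  # transcript [a, b) -> 1-based genomic inclusive interval(s)
        coords = sorted(g(56 - p) for p in range(a, b))
        out, lo, prev = [], coords[0], coords[0]
        for c in coords[1:]:
            if c != prev + 1:
                out.append((lo + 1, prev + 1))
                lo = c
            prev = c
        out.append((lo + 1, prev + 1))
        return out

    attrs = 'gene_id "G1"; transcript_id "T1"; transcript_type "protein_coding";'
    rows = [("gene", 6, 72, "-", attrs), ("transcript", 6, 72, "-", attrs),
            ("exon", 6, 40, "-", attrs), ("exon", 51, 72, "-", attrs)]
    rows += [("CDS", a, b, "-", attrs) for a, b in span(12, 36)]  # excludes stop
    rows += [("stop_codon", a, b, "-", attrs) for a, b in span(36, 39)]
    gtf, fasta = _write_toy_gtf(tmp_path, chrom_seq, rows)
    models, _ = parse_annotation(gtf, fasta)
    assert len(models) == 1
    t = models[0]
    assert t.seq == tx
    assert (t.cds_start, t.cds_end) == (12, 39)
    lm = find_landmarks(t)
    assert lm.stop_codon == "TGA"
    assert lm.plus4 == "C"


def test_parse_drops_transcripts_without_utrs(tmp_path):
    seq = "ATG" + "GCC" * 10 + "TAA" + "C" * 20  # no 5'UTR
    n = len(seq)
    attrs = 'gene_id "G1"; transcript_id "T1"; transcript_type "protein_coding";'
    rows = [
        ("gene", 1, n, "+", attrs),
        ("transcript", 1, n, "+", attrs),
        ("exon", 1, n, "+", attrs),
        ("CDS", 1, 33, "+", attrs),
        ("stop_codon", 34, 36, "+", attrs),
    ]
    gtf, fasta = _write_toy_gtf(tmp_path, seq, rows)
    models, _ = parse_annotation(gtf, fasta)
    assert models == []


def test_parse_missing_chrom_is_hard_error(tmp_path):
    fasta = tmp_path / "g.fa"
    fasta.write_text(">other\nACGT\n")
    gtf = tmp_path / "g.gtf"
    attrs = 'gene_id "G1"; transcript_id "T1"; transcript_type "protein_coding";'
    gtf.write_text(
        f"chrT\ttest\tgene\t1\t40\t.\t+\t.\t{attrs}\n"
        f"chrT\ttest\ttranscript\t1\t40\t.\t+\t.\t{attrs}\n"
        f"chrT\ttest\texon\t1\t40\t.\t+\t.\t{attrs}\n"
        f"chrT\ttest\tCDS\t5\t34\t.\t+\t.\t{attrs}\n"
    )
    with pytest.raises(ValueError, match="T1"):
        parse_annotation(str(gtf), str(fasta))


# ---------------------------------------------------------------------------
# selection


def _isoform(tid, gene, utr5, cds_codons, utr3, appris="none", ccds=False, offset=0):
    t = make_transcript(utr5, cds_codons, utr3, transcript_id=tid)
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        chrom="chr1",
        strand="+",
        exons=[(offset, offset + t.length)],
        seq=t.seq,
        cds_start=t.cds_start,
        cds_end=t.cds_end,
        appris_tag=appris,
        is_ccds=ccds,
    )


def test_single_isoform_gene_selects_itself():
    t = _isoform("T1", "G1", 30, 20, 60)
    assert select_transcripts([t])["G1"].transcript_id == "T1"


def test_selection_cascade_prefers_appris_primary():
    """Among isoforms sharing the 3'-most stop: APPRIS primary wins over CCDS
    and untagged, even with a longer 3'UTR (brute-force rule order)."""
    # same CDS end (aligned stop in genomic coordinates): same utr5+cds layout
    a = _isoform("A", "G1", 30, 20, 120, appris="primary")
    b = _isoform("B", "G1", 30, 20, 60, ccds=True)
    c = _isoform("C", "G1", 30, 20, 60)
    assert select_transcripts([a, b, c])["G1"].transcript_id == "A"


def test_selection_cascade_rule_order():
    """Rules fire in order: CCDS beats longest-CDS, which beats shortest UTRs."""
    # all isoforms share genomic stop position 90 (utr5 + 3*codons == 90)
    ccds_short = _isoform("S", "G1", 30, 20, 60, ccds=True)
    long_cds = _isoform("L", "G1", 24, 22, 54)  # longer CDS but not CCDS
    assert select_transcripts([ccds_short, long_cds])["G1"].transcript_id == "S"
    # without CCDS the longer CDS wins
    long_cds2 = _isoform("L", "G1", 24, 22, 54)
    short_cds = _isoform("S", "G1", 30, 20, 60)
    assert select_transcripts([long_cds2, short_cds])["G1"].transcript_id == "L"


def test_selection_three_prime_most_stop_first():
    """An untagged isoform with a more 3' stop beats an APPRIS primary one."""
    near = _isoform("P", "G1", 30, 20, 60, appris="primary", offset=0)
    far = _isoform("F", "G1", 30, 24, 60, offset=0)  # stop further 3' on +
    assert select_transcripts([near, far])["G1"].transcript_id == "F"


def test_selection_tie_break_is_lexicographic_and_order_independent():
    import itertools

    isos = [_isoform(tid, "G1", 30, 20, 60) for tid in ("TB", "TA", "TC")]
    for perm in itertools.permutations(isos):
        assert select_transcripts(list(perm))["G1"].transcript_id == "TA"


def test_selection_drops_neighbor_overlap():
    """A selected transcript overlapping the nearest same-strand gene is dropped."""
    t1 = _isoform("T1", "G1", 30, 20, 60, offset=0)
    t2 = _isoform("T2", "G2", 30, 20, 60, offset=100)  # overlaps T1 (len 153)
    t3 = _isoform("T3", "G3", 30, 20, 60, offset=5000)
    out = select_transcripts([t1, t2, t3])
    assert "G1" not in out and "G2" not in out
    assert "G3" in out


def test_selection_drops_utr_pseudogene_overlap():
    t1 = _isoform("T1", "G1", 30, 20, 60, offset=0)  # 3'UTR at genomic 93..153
    out = select_transcripts([t1], pseudogene_spans=[("chr1", (100, 110))])
    assert out == {}
    # a pseudogene overlapping only the CDS does not disqualify
    out = select_transcripts([t1], pseudogene_spans=[("chr1", (40, 50))])
    assert "G1" in out


# ---------------------------------------------------------------------------
# landmarks


def test_landmark_examples():
    t = make_transcript(utr5=30, cds_codons=20, utr3="AAATAAGG")
    lm = find_landmarks(t)
    assert lm.ntc_pos == t.cds_end - 3
    assert lm.tc3_pos == t.cds_end + 3  # TAA in frame after AAA
    assert lm.plus4 == "A"
    none = find_landmarks(make_transcript(utr3="C" * 30))
    assert none.tc3_pos is None


def test_landmark_scan_matches_brute_force():
    """tc3_pos equals a brute-force scan of all in-frame triplets (1,000 UTRs)."""
    rng = np.random.default_rng(7)
    for _ in range(1000):
        utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 60))))
        t = make_transcript(utr5=12, cds_codons=10, utr3=utr3)
        lm = find_landmarks(t)
        expected = None
        for p in range(t.cds_end, t.length - 2, 3):
            if t.seq[p : p + 3] in STOP_CODONS:
                expected = p
                break
        assert lm.tc3_pos == expected
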
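"""Transcript annotation: parsing, single-isoform selection, stop-codon landmarks.

Quantifying stop-codon readthrough from ribosome footprints requires that the
region downstream of a stop codon belongs unambiguously to the 3'UTR of a
single transcript isoform.  This module parses a GENCODE-dialect GTF plus a
genome FASTA into :class:`TranscriptModel` objects, applies a deterministic
single-isoform selection cascade per gene (3'-most stop codon, then APPRIS,
CCDS, CDS length, UTR lengths), and locates the stop-codon landmarks used
throughout the pipeline: the normal termination codon (NTC), the +4
nucleotide, and the first in-frame stop codon in the 3'UTR (3'TC).

All transcript coordinates are 0-based half-open in transcript orientation;
``cds_end`` is one past the last nucleotide of the stop codon (i.e. the CDS
*includes* the stop codon).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """One transcript isoform with spliced sequence and CDS bounds.

    ``exons`` are genomic 0-based half-open intervals sorted by genomic
    start regardless of strand; ``seq`` is in transcript (5'->3')
    orientation.  ``cds_start``/``cds_end`` are transcript coordinates and
    include the stop codon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    seq: str
    cds_start: int
    cds_end: int
    appris_tag: str = "none"  # {primary, alternative, none}
    is_ccds: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.validate()

    def validate(self) -> None:
        n = len(self.seq)
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if sum(b - a for a, b in self.exons) != n:
            raise ValueError(
                f"{self.transcript_id}: exon lengths do not sum to sequence length"
            )
        if not (0 <= self.cds_start < self.cds_end <= n):
            raise ValueError(f"{self.transcript_id}: CDS bounds outside transcript")
        cds_len = self.cds_end - self.cds_start
        if cds_len < 6 or cds_len % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {cds_len} not a multiple of 3 >= 6"
            )
        if self.stop_codon not in STOP_CODONS:
            raise ValueError(
                f"{self.transcript_id}: CDS does not end in a stop codon "
                f"({self.seq[self.cds_end - 3:self.cds_end]!r})"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def stop_codon(self) -> str:
        return self.seq[self.cds_end - 3 : self.cds_end].upper()

    @property
    def utr5_len(self) -> int:
        return self.cds_start

    @property
    def utr3_len(self) -> int:
        return len(self.seq) - self.cds_end

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    # genomic extent of the stop codon, for strand-aware 3'-most comparison
    @property
    def stop_genomic_edge(self) -> int:
        if self.strand == "+":
            return self.to_genomic(self.cds_end - 1) + 1  # genomic end (exclusive)
        return self.to_genomic(self.cds_end - 1)  # genomic start (smallest coord)

    @property
    def genomic_span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def to_genomic(self, pos: int) -> int:
        """Map a transcript coordinate to its genomic coordinate."""
        if not 0 <= pos < self.length:
            raise IndexError(f"transcript position {pos} outside {self.transcript_id}")
        if self.strand == "+":
            off = pos
            for a, b in self.exons:
                if off < b - a:
                    return a + off
                off -= b - a
        else:
            off = pos
            for a, b in reversed(self.exons):
                if off < b - a:
                    return b - 1 - off
                off -= b - a
        raise AssertionError("unreachable")

    def to_transcript(self, gpos: int) -> Optional[int]:
        """Map a genomic coordinate to a transcript coordinate, or None if intronic."""
        off = 0
        if self.strand == "+":
            for a, b in self.exons:
                if a <= gpos < b:
                    return off + (gpos - a)
                off += b - a
        else:
            for a, b in reversed(self.exons):
                if a <= gpos < b:
                    return off + (b - 1 - gpos)
                off += b - a
        return None

    def utr_genomic_intervals(self) -> list[tuple[int, int]]:
        """Genomic intervals covered by the 5' and 3' UTRs (exon-level)."""
        out = []
        for lo, hi in ((0, self.cds_start), (self.cds_end, self.length)):
            for pos in range(lo, hi):
                g = self.to_genomic(pos)
                if out and out[-1][1] == g:
                    out[-1] = (out[-1][0], g + 1)
                elif out and out[-1][0] == g + 1:
                    out[-1] = (g, out[-1][1])
                else:
                    out.append((g, g + 1))
        return _merge_intervals(out)


@dataclass
class StopLandmarks:
    """Stop-codon landmarks of one transcript.

    ``ntc_pos`` is the transcript coordinate of the first nucleotide of the
    normal termination codon; ``tc3_pos`` is the first in-frame 3'UTR stop
    codon start, or None when the 3'UTR has no in-frame stop.
    """

    ntc_pos: int
    stop_codon: str
    plus4: Optional[str]
    tc3_pos: Optional[int]
    utr3_len: int


def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(x) for x in out]


def find_landmarks(t: TranscriptModel) -> StopLandmarks:
    """Locate the NTC, the +4 nucleotide and the first in-frame 3'TC.

    The 3'UTR is scanned from ``cds_end`` in steps of 3 (the CDS reading
    frame); the first stop triplet entirely within the transcript is the
    3'TC.
    """
    seq = t.seq.upper()
    ntc_pos = t.cds_end - 3
    plus4 = seq[t.cds_end] if t.cds_end < t.length else None
    tc3_pos = None
    for pos in range(t.cds_end, t.length - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            tc3_pos = pos
            break
    return StopLandmarks(
        ntc_pos=ntc_pos,
        stop_codon=t.stop_codon,
        plus4=plus4,
        tc3_pos=tc3_pos,
        utr3_len=t.utr3_len,
    )


# ---------------------------------------------------------------------------
# GTF parsing


def _classify_appris(tags: Iterable[str]) -> str:
    tags = list(tags)
    if any(tag.startswith("appris_principal") for tag in tags):
        return "primary"
    if any(tag.startswith("appris_alternative") for tag in tags):
        return "alternative"
    return "none"


def parse_annotation(
    gtf_path: str,
    fasta_path: str,
    require_utrs: bool = True,
) -> tuple[list[TranscriptModel], list[tuple[str, tuple[int, int]]]]:
    """Parse a GENCODE-dialect GTF + genome FASTA into TranscriptModels.

    Returns ``(transcripts, pseudogene_spans)`` where pseudogene spans are
    ``(chrom, (start, end))`` genomic intervals of genes whose biotype
    contains "pseudogene" (used by the selection overlap filter).

    Only protein-coding transcripts with a complete CDS and, when
    ``require_utrs``, both UTRs are returned.  GENCODE CDS features exclude
    the stop codon; the internal convention includes it, so the CDS is
    extended by the ``stop_codon`` feature when present, else by 3 nt with a
    sequence check.  Transcripts whose resulting CDS length is not a
    positive multiple of 3, or that do not end in a stop codon, are dropped
    with a logged reason.  A chromosome missing from the FASTA is a hard
    error naming the transcript.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    fasta = Fasta(fasta_path, rebuild=False)

    pseudogene_spans: list[tuple[str, tuple[int, int]]] = []
    for gene in db.features_of_type("gene"):
        biotype = (gene.attributes.get("gene_type") or gene.attributes.get("gene_biotype") or [""])[0]
        if "pseudogene" in biotype:
            pseudogene_spans.append((gene.seqid, (gene.start - 1, gene.end)))

    out: list[TranscriptModel] = []
    for tx in db.features_of_type("transcript"):
        biotype = (
            tx.attributes.get("transcript_type")
            or tx.attributes.get("transcript_biotype")
            or [""]
        )[0]
        if biotype != "protein_coding":
            continue
        tid = tx.attributes["transcript_id"][0]
        gid = tx.attributes["gene_id"][0]
        tags = tx.attributes.get("tag", [])
        if any(tag in ("cds_start_NF", "cds_end_NF", "mRNA_start_NF", "mRNA_end_NF") for tag in tags):
            logger.info("dropping %s: incomplete CDS/mRNA annotation", tid)
            continue

        exons = sorted(
            (f.start - 1, f.end) for f in db.children(tx, featuretype="exon")
        )
        cds_ivs = sorted(
            (f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")
        )
        stop_ivs = sorted(
            (f.start - 1, f.end) for f in db.children(tx, featuretype="stop_codon")
        )
        if not exons or not cds_ivs:
            continue
        if tx.seqid not in fasta:
            raise ValueError(
                f"chromosome {tx.seqid!r} (transcript {tid}) missing from FASTA"
            )

        genome_seq = "".join(str(fasta[tx.seqid][a:b]) for a, b in exons).upper()
        seq = genome_seq if tx.strand == "+" else reverse_complement(genome_seq)

        model = _assemble_transcript(
            tid, gid, tx.seqid, tx.strand, exons, seq, cds_ivs, stop_ivs, tags
        )
        if model is None:
            continue
        if require_utrs and (model.utr5_len == 0 or model.utr3_len == 0):
            logger.info("dropping %s: missing UTR", tid)
            continue
        out.append(model)
    return out, pseudogene_spans


def _assemble_transcript(
    tid, gid, chrom, strand, exons, seq, cds_ivs, stop_ivs, tags
) -> Optional[TranscriptModel]:
    # genomic -> transcript mapping via a throwaway model with a dummy CDS
    def g2t(gpos: int) -> Optional[int]:
        off = 0
        ordered = exons if strand == "+" else list(reversed(exons))
        for a, b in ordered:
            if a <= gpos < b:
                return off + (gpos - a if strand == "+" else b - 1 - gpos)
            off += b - a
        return None

    cds_gpos = []
    for a, b in cds_ivs + stop_ivs:
        cds_gpos.extend((a, b - 1))
    tpos = [g2t(g) for g in cds_gpos]
    if any(p is None for p in tpos):
        logger.info("dropping %s: CDS outside exons", tid)
        return None
    cds_start, cds_last = min(tpos), max(tpos)
    cds_end = cds_last + 1
    if not stop_ivs:
        # GENCODE CDS excludes the stop codon: extend by 3 with a sequence check
        if cds_end + 3 <= len(seq) and seq[cds_end : cds_end + 3] in STOP_CODONS:
            cds_end += 3
    if seq[cds_end - 3 : cds_end] not in STOP_CODONS:
        logger.info("dropping %s: CDS does not end in a stop codon", tid)
        return None
    if (cds_end - cds_start) % 3 != 0 or cds_end - cds_start < 6:
        logger.info("dropping %s: CDS length not a multiple of 3", tid)
        return None
    is_ccds = "CCDS" in tags or any(t.startswith("ccds") for t in tags)
    try:
        return TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=exons,
            seq=seq,
            cds_start=cds_start,
            cds_end=cds_end,
            appris_tag=_classify_appris(tags),
            is_ccds=is_ccds,
        )
    except ValueError as exc:
        logger.info("dropping %s: %s", tid, exc)
        return None


# ---------------------------------------------------------------------------
# single-isoform selection


_APPRIS_RANK = {"primary": 0, "alternative": 1, "none": 2}


def _select_within_gene(txs: list[TranscriptModel]) -> TranscriptModel:
    """Apply the per-gene selection cascade; input is one gene's isoforms."""
    # (1) 3'-most stop codon in genomic orientation (strand-aware)
    if txs[0].strand == "+":
        best = max(t.stop_genomic_edge for t in txs)
    else:
        best = min(t.stop_genomic_edge for t in txs)
    txs = [t for t in txs if t.stop_genomic_edge == best]
    # (2) APPRIS primary, else alternative
    best_rank = min(_APPRIS_RANK[t.appris_tag] for t in txs)
    txs = [t for t in txs if _APPRIS_RANK[t.appris_tag] == best_rank]
    # (3) CCDS membership
    if any(t.is_ccds for t in txs):
        txs = [t for t in txs if t.is_ccds]
    # (4) longest CDS, (5) shortest 3'UTR, (6) shortest 5'UTR,
    # final deterministic tie-break: lexicographically smallest transcript_id
    txs.sort(key=lambda t: (-t.cds_len, t.utr3_len, t.utr5_len, t.transcript_id))
    return txs[0]


def select_transcripts(
    transcripts: Iterable[TranscriptModel],
    pseudogene_spans: Sequence[tuple[str, tuple[int, int]]] = (),
) -> dict[str, TranscriptModel]:
    """Select one transcript per gene and apply the neighbor/pseudogene filters.

    Per gene the cascade is: 3'-most stop codon (genomic, strand-aware);
    APPRIS primary then alternative; CCDS; longest CDS; shortest 3'UTR;
    shortest 5'UTR; lexicographically smallest transcript_id.  A selected
    transcript is then discarded when any of its exons overlaps any exon of
    any transcript of the nearest same-strand neighboring gene (upstream or
    downstream), or when its UTR intervals overlap an annotated pseudogene.
    Returns a mapping gene_id -> selected TranscriptModel.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    selected = {gid: _select_within_gene(sorted(txs, key=lambda t: t.transcript_id))
                for gid, txs in by_gene.items()}

    # gene spans (over all isoforms) per chrom+strand for neighbor lookup
    gene_meta: dict[str, tuple[str, str, int, int]] = {}
    for gid, txs in by_gene.items():
        starts = [t.genomic_span[0] for t in txs]
        ends = [t.genomic_span[1] for t in txs]
        gene_meta[gid] = (txs[0].chrom, txs[0].strand, min(starts), max(ends))

    groups: dict[tuple[str, str], list[str]] = {}
    for gid, (chrom, strand, s, e) in gene_meta.items():
        groups.setdefault((chrom, strand), []).append(gid)

    pseudo_trees: dict[str, IntervalTree] = {}
    for chrom, (a, b) in pseudogene_spans:
        pseudo_trees.setdefault(chrom, IntervalTree()).addi(a, b)

    kept: dict[str, TranscriptModel] = {}
    for (chrom, strand), gids in groups.items():
        gids = sorted(gids, key=lambda g: gene_meta[g][2])
        for i, gid in enumerate(gids):
            t = selected[gid]
            neighbors = _nearest_neighbors(gids, i, gene_meta)
            if any(
                _exon_overlap(t, other)
                for ng in neighbors
                for other in by_gene[ng]
            ):
                logger.info("dropping %s: overlaps nearest-neighbor gene", t.transcript_id)
                continue
            tree = pseudo_trees.get(chrom)
            if tree is not None and any(
                tree.overlap(a, b) for a, b in t.utr_genomic_intervals()
            ):
                logger.info("dropping %s: UTR overlaps pseudogene", t.transcript_id)
                continue
            kept[gid] = t
    return kept


def _nearest_neighbors(gids, i, gene_meta) -> list[str]:
    """Nearest up- and downstream gene (by genomic distance) on the same strand."""
    out = []
    _, _, s, e = gene_meta[gids[i]]
    if i > 0:
        best = min(range(i), key=lambda j: abs(s - gene_meta[gids[j]][3]))
        out.append(gids[best])
    if i + 1 < len(gids):
        best = min(range(i + 1, len(gids)), key=lambda j: abs(gene_meta[gids[j]][2] - e))
        out.append(gids[best])
    return out


def _exon_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    for x0, x1 in a.exons:
        for y0, y1 in b.exons:
            if x0 < y1 and y0 < x1:
                return True
    return False


def selected_transcript_table(selected: dict[str, TranscriptModel]):
    """Tabulate the selected transcripts with their stop-codon landmarks."""
    import pandas as pd

    rows = []
    for gid in sorted(selected):
        t = selected[gid]
        lm = find_landmarks(t)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": gid,
                "chrom": t.chrom,
                "strand": t.strand,
                "cds_start": t.cds_start,
                "cds_end": t.cds_end,
                "utr3_len": lm.utr3_len,
                "stop_codon": lm.stop_codon,
                "plus4": lm.plus4 if lm.plus4 is not None else "",
                "tc3_pos": lm.tc3_pos if lm.tc3_pos is not None else -1,
            }
        )
    return pd.DataFrame(rows)
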
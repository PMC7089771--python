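"""Footprint ingestion: 5'-end assignment, A-site offset calibration, density tracks.

Ribosome-protected fragments (RPFs) are assigned to transcripts by their 5'
ends and shifted to the nucleotide at the *center* of the A-site codon using
a read-length-specific offset.  Offsets are calibrated per library from reads
over the start codon: an initiating ribosome holds the start codon in its P
site, so its A-site codon is the second codon, whose center nucleotide sits
at ``cds_start + 4``.  The canonical full-length offsets this recovers are
{28:16, 29:16, 30:16, 31:17, 32:17, 33:17, 34:17, 35:17}.

Density tracks store one raw count per read at the A-site center; the A-site
codon start is ``center - 1`` and all downstream window arithmetic is defined
on codon starts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .annotation import TranscriptModel

logger = logging.getLogger(__name__)

#: canonical 5'-end -> A-site-center offsets for full-length footprints
FULL_LENGTH_OFFSETS: dict[int, int] = {
    28: 16, 29: 16, 30: 16, 31: 17, 32: 17, 33: 17, 34: 17, 35: 17,
}
#: offsets for short (empty-A-site) footprints; ingestible, excluded from
#: analyses by default
SHORT_READ_OFFSETS: dict[int, int] = {20: 16, 21: 16, 22: 17, 23: 17}

FULL_LENGTH_RANGE = (28, 35)
MIN_READ_LEN, MAX_READ_LEN = 15, 40


@dataclass
class FootprintReads:
    """Column-oriented container of 5'-end-assigned footprint reads."""

    transcript_ids: list[str]
    tx_index: np.ndarray  # int index into transcript_ids, one per read
    five_prime: np.ndarray  # transcript coordinate of the 5' end
    length: np.ndarray  # read length in nt

    def __len__(self) -> int:
        return len(self.tx_index)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "FootprintReads":
        ids: list[str] = []
        index: dict[str, int] = {}
        tx, fp, ln = [], [], []
        for tid, five, length in records:
            if tid not in index:
                index[tid] = len(ids)
                ids.append(tid)
            tx.append(index[tid])
            fp.append(five)
            ln.append(length)
        return cls(
            transcript_ids=ids,
            tx_index=np.asarray(tx, dtype=np.int64),
            five_prime=np.asarray(fp, dtype=np.int64),
            length=np.asarray(ln, dtype=np.int64),
        )


@dataclass
class DensityTrack:
    """Per-nucleotide A-site-assigned counts along one transcript."""

    transcript_id: str
    raw: np.ndarray  # integer counts, length == transcript length
    rpm: np.ndarray  # depth-normalized counts
    total_reads: int

    def __post_init__(self) -> None:
        if int(self.raw.sum()) != self.total_reads:
            raise ValueError(
                f"{self.transcript_id}: raw counts ({int(self.raw.sum())}) "
                f"!= total_reads ({self.total_reads})"
            )


# ---------------------------------------------------------------------------
# alignment reading / projection


def project_to_transcript(
    chrom: str,
    genomic_five_prime: int,
    read_strand: str,
    t: TranscriptModel,
) -> Optional[int]:
    """Map a genome-space read 5' end to a transcript coordinate.

    Returns None when the chromosome or strand disagrees or the 5' end is
    not exonic.  The genomic 5' end of a reverse-strand alignment is its
    rightmost aligned base.
    """
    if chrom != t.chrom or read_strand != t.strand:
        return None
    return t.to_transcript(genomic_five_prime)


def read_transcript_sam(
    path: str,
    min_mapq: int = 0,
) -> FootprintReads:
    """Read transcript-space alignments (references are transcript ids).

    Secondary and supplementary alignments are never represented; reads
    outside 15-40 nt are dropped with a counter.
    """
    import pysam

    tx, fp, ln = [], [], []
    ids: list[str] = []
    index: dict[str, int] = {}
    skipped = Counter()
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped["secondary_or_unmapped"] += 1
                continue
            if rec.is_reverse:
                skipped["reverse_strand"] += 1
                continue
            if rec.mapping_quality < min_mapq:
                skipped["low_mapq"] += 1
                continue
            length = rec.query_length or rec.infer_query_length() or 0
            if not MIN_READ_LEN <= length <= MAX_READ_LEN:
                skipped["length_out_of_range"] += 1
                continue
            tid = rec.reference_name
            if tid not in index:
                index[tid] = len(ids)
                ids.append(tid)
            tx.append(index[tid])
            fp.append(rec.reference_start)
            ln.append(length)
    if skipped:
        logger.info("read_transcript_sam skipped: %s", dict(skipped))
    return FootprintReads(
        transcript_ids=ids,
        tx_index=np.asarray(tx, dtype=np.int64),
        five_prime=np.asarray(fp, dtype=np.int64),
        length=np.asarray(ln, dtype=np.int64),
    )


def read_genome_sam(
    path: str,
    models: Mapping[str, TranscriptModel],
    min_mapq: int = 0,
) -> FootprintReads:
    """Read genome-space alignments and project 5' ends through exon chains.

    Each read is assigned to the first selected transcript whose exons
    contain its genomic 5' end on the matching strand (selected transcripts
    from non-overlapping genes make this effectively unique).
    """
    import pysam

    trees: dict[str, list[TranscriptModel]] = {}
    for t in models.values():
        trees.setdefault(t.chrom, []).append(t)

    records = []
    skipped = Counter()
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped["secondary_or_unmapped"] += 1
                continue
            if rec.mapping_quality < min_mapq:
                skipped["low_mapq"] += 1
                continue
            length = rec.query_length or rec.infer_query_length() or 0
            if not MIN_READ_LEN <= length <= MAX_READ_LEN:
                skipped["length_out_of_range"] += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            g5 = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
            hit = None
            for t in trees.get(rec.reference_name, ()):
                pos = project_to_transcript(rec.reference_name, g5, strand, t)
                if pos is not None:
                    hit = (t.transcript_id, pos, length)
                    break
            if hit is None:
                skipped["unassigned"] += 1
                continue
            records.append(hit)
    if skipped:
        logger.info("read_genome_sam skipped: %s", dict(skipped))
    return FootprintReads.from_records(records)


# ---------------------------------------------------------------------------
# offset calibration


def calibrate_offsets(
    reads: FootprintReads,
    models: Mapping[str, TranscriptModel],
    lengths: Sequence[int] = tuple(range(28, 36)),
    min_calibration_reads: int = 200,
    upstream_window: int = 40,
    default_table: Optional[Mapping[int, int]] = FULL_LENGTH_OFFSETS,
    offset_bounds: tuple[int, int] = (10, 20),
) -> dict[int, int]:
    """Calibrate per-length 5'->A-site-center offsets from start-codon reads.

    For reads whose 5' end lies within ``upstream_window`` nt upstream of the
    start codon, the candidate shift is ``cds_start + 4 - five_prime`` (the
    shift that places the start codon in the P site).  The offset for each
    length is the mode of candidate shifts within ``offset_bounds``; ties go
    to the smaller shift with a warning.  Lengths with fewer than
    ``min_calibration_reads`` candidates fall back to ``default_table``; if
    no default is allowed and no length calibrates, a ValueError is raised.
    """
    cds_start = np.full(len(reads.transcript_ids), -1, dtype=np.int64)
    for i, tid in enumerate(reads.transcript_ids):
        if tid in models:
            cds_start[i] = models[tid].cds_start
    starts = cds_start[reads.tx_index]
    in_window = (starts >= 0) & (reads.five_prime < starts) & (
        reads.five_prime >= starts - upstream_window
    )
    shifts = starts + 4 - reads.five_prime
    lo, hi = offset_bounds
    usable = in_window & (shifts >= lo) & (shifts <= hi)

    table: dict[int, int] = {}
    n_calibrated = 0
    for L in lengths:
        sel = usable & (reads.length == L)
        vals, counts = np.unique(shifts[sel], return_counts=True)
        if counts.sum() >= min_calibration_reads:
            best = counts.max()
            candidates = vals[counts == best]
            if len(candidates) > 1:
                logger.warning(
                    "offset tie for length %d (%s); choosing smaller shift",
                    L, candidates.tolist(),
                )
            table[L] = int(candidates.min())
            n_calibrated += 1
        elif default_table is not None and L in default_table:
            logger.info(
                "length %d: %d calibration reads < %d, using default offset %d",
                L, int(counts.sum()), min_calibration_reads, default_table[L],
            )
            table[L] = int(default_table[L])
        else:
            logger.warning("length %d: cannot calibrate and no default", L)
    if not table or (n_calibrated == 0 and default_table is None):
        raise ValueError("no read length could be calibrated and no default table")
    return table


# ---------------------------------------------------------------------------
# density tracks


def build_tracks(
    reads: FootprintReads,
    models: Mapping[str, TranscriptModel],
    offsets: Mapping[int, int],
    length_range: tuple[int, int] = FULL_LENGTH_RANGE,
    normalization: str = "per_length",
) -> tuple[dict[str, DensityTrack], dict[str, int]]:
    """Shift reads to A-site centers and accumulate per-transcript densities.

    Each read of length L in ``length_range`` contributes one raw count at
    ``five_prime + offsets[L]``.  Reads outside the length range, on unknown
    transcripts, or whose shifted A-site falls off the transcript are
    dropped (not clipped) with counters.  ``normalization`` is
    ``"per_length"`` (reads-per-million computed within each read length,
    then summed) or ``"global"`` (one RPM factor over all assigned reads).

    Returns ``(tracks, counters)``.
    """
    if normalization not in ("per_length", "global"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    lo, hi = length_range
    counters: Counter = Counter()

    known = np.array([tid in models for tid in reads.transcript_ids])
    tx_len = np.array(
        [models[tid].length if tid in models else 0 for tid in reads.transcript_ids],
        dtype=np.int64,
    )
    off = np.full(MAX_READ_LEN + 1, -1, dtype=np.int64)
    for L, o in offsets.items():
        if L <= MAX_READ_LEN:
            off[L] = o

    in_range = (reads.length >= lo) & (reads.length <= hi)
    counters["length_out_of_range"] = int((~in_range).sum())
    ok = in_range & known[reads.tx_index]
    counters["unknown_transcript"] = int((in_range & ~known[reads.tx_index]).sum())
    has_offset = off[reads.length] >= 0
    counters["no_offset"] = int((ok & ~has_offset).sum())
    ok &= has_offset

    pos = reads.five_prime + off[reads.length]
    on_tx = (pos >= 0) & (pos < tx_len[reads.tx_index])
    counters["off_transcript"] = int((ok & ~on_tx).sum())
    ok &= on_tx

    tx = reads.tx_index[ok]
    pos = pos[ok]
    lens = reads.length[ok]
    counters["assigned"] = int(ok.sum())

    # flatten (transcript, position) into one global coordinate space
    offsets_per_tx = np.concatenate(([0], np.cumsum(tx_len)))
    flat = offsets_per_tx[tx] + pos

    total = len(tx)
    raw_flat = np.bincount(flat, minlength=offsets_per_tx[-1]).astype(np.int64)
    if normalization == "global" or total == 0:
        denom = max(total, 1) / 1e6
        rpm_flat = raw_flat / denom
    else:
        rpm_flat = np.zeros(offsets_per_tx[-1], dtype=np.float64)
        for L in np.unique(lens):
            sel = lens == L
            n_l = int(sel.sum())
            rpm_flat += np.bincount(
                flat[sel], minlength=offsets_per_tx[-1]
            ) / (n_l / 1e6)

    tracks: dict[str, DensityTrack] = {}
    for i, tid in enumerate(reads.transcript_ids):
        if not known[i]:
            continue
        a, b = offsets_per_tx[i], offsets_per_tx[i + 1]
        raw = raw_flat[a:b]
        tracks[tid] = DensityTrack(
            transcript_id=tid,
            raw=raw,
            rpm=rpm_flat[a:b].copy(),
            total_reads=int(raw.sum()),
        )
    # transcripts with zero assigned reads still get (empty) tracks
    for tid, m in models.items():
        if tid not in tracks:
            tracks[tid] = DensityTrack(
                transcript_id=tid,
                raw=np.zeros(m.length, dtype=np.int64),
                rpm=np.zeros(m.length, dtype=np.float64),
                total_reads=0,
            )
    return tracks, dict(counters)


def tracks_to_table(tracks: Mapping[str, DensityTrack]):
    """Long-format (transcript_id, position, raw, rpm) table of nonzero positions."""
    import pandas as pd

    frames = []
    for tid in sorted(tracks):
        tr = tracks[tid]
        nz = np.nonzero(tr.raw)[0]
        if len(nz) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": tid,
                    "position": nz,
                    "raw": tr.raw[nz],
                    "rpm": tr.rpm[nz],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["transcript_id", "position", "raw", "rpm"])
    return pd.concat(frames, ignore_index=True)


def tracks_from_table(df, models: Mapping[str, TranscriptModel]) -> dict[str, DensityTrack]:
    """Inverse of :func:`tracks_to_table` (requires models for lengths)."""
    tracks = {}
    grouped = dict(tuple(df.groupby("transcript_id"))) if len(df) else {}
    for tid, m in models.items():
        raw = np.zeros(m.length, dtype=np.int64)
        rpm = np.zeros(m.length, dtype=np.float64)
        g = grouped.get(tid)
        if g is not None:
            raw[g["position"].to_numpy()] = g["raw"].to_numpy()
            rpm[g["position"].to_numpy()] = g["rpm"].to_numpy()
        tracks[tid] = DensityTrack(tid, raw, rpm, int(raw.sum()))
    return tracks
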
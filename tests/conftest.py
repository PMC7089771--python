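"""Shared fixtures: hand-built transcripts and a small simulated library."""

from __future__ import annotations

import numpy as np
import pytest

from riboscr.annotation import TranscriptModel
from riboscr.ingest import DensityTrack, build_tracks
from riboscr.readthrough import rrts_table
from riboscr.simulate import SimulationSpec, simulate_footprints, simulate_transcriptome

SENSE = "GCT"  # alanine filler codon


def make_transcript(
    utr5: int = 30,
    cds_codons: int = 40,
    utr3: str | int = 120,
    transcript_id: str = "T1",
    stop: str = "TAA",
    filler: str = SENSE,
) -> TranscriptModel:
    """Deterministic toy transcript: poly-A 5'UTR, filler-codon CDS, given 3'UTR.

    ``utr3`` may be an explicit sequence or a length (then poly-C, which
    contains no stop codons).
    """
    utr3_seq = "C" * utr3 if isinstance(utr3, int) else utr3
    seq = "A" * utr5 + "ATG" + filler * (cds_codons - 2) + stop + utr3_seq
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=f"G_{transcript_id}",
        chrom=transcript_id,
        strand="+",
        exons=[(0, len(seq))],
        seq=seq,
        cds_start=utr5,
        cds_end=utr5 + 3 * cds_codons,
    )


def uniform_track(model: TranscriptModel, value: int = 1) -> DensityTrack:
    raw = np.full(model.length, value, dtype=np.int64)
    return DensityTrack(model.transcript_id, raw, raw.astype(float), int(raw.sum()))


def track_from_counts(model: TranscriptModel, counts: dict[int, int]) -> DensityTrack:
    raw = np.zeros(model.length, dtype=np.int64)
    for pos, c in counts.items():
        raw[pos] = c
    return DensityTrack(model.transcript_id, raw, raw.astype(float), int(raw.sum()))


@pytest.fixture(scope="session")
def sim():
    """One simulated library run through ingestion: (spec, transcriptome, tracks, rrts)."""
    spec = SimulationSpec(
        n_transcripts=150,
        n_reads=400_000,
        readthrough=0.2,
        tc3_distance=60,
        tc3_clear_codons=5,
        expression_sigma=0.5,
    )
    txome = simulate_transcriptome(spec, seed=101)
    reads, info = simulate_footprints(spec, txome, seed=102)
    tracks, counters = build_tracks(reads, txome.models, spec.offsets)
    table = rrts_table(tracks, txome.models)
    return {
        "spec": spec,
        "txome": txome,
        "reads": reads,
        "info": info,
        "tracks": tracks,
        "counters": counters,
        "rrts": table,
    }
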
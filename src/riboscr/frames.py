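"""Reading-frame composition, frame-resolved 3'TC metagenes, codon occupancy.

Footprints decoded by elongating ribosomes show strong 3-nt periodicity:
their A-site codon starts fall in the annotated reading frame (frame 0).
This module measures the fraction of A-site density per frame in the CDS
and 3'UTR, builds frame-resolved profiles around the first 3'UTR stop codon
of each frame (ribosomes translating a frame terminate at that frame's
stops, not at the others'), and computes per-codon occupancy (pause)
scores.

A density-track position holds the A-site codon *center*; the codon start
is position - 1, and the frame of a count is ``(start - cds_start) mod 3``
mapped to {0, +1, -1}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import STOP_CODONS, StopLandmarks, TranscriptModel
from .ingest import DensityTrack
from .metagene import cds_mean_density

FRAME_LABELS = {0: 0, 1: 1, 2: -1}  # residue class -> reported frame
TC3_WINDOW = 12  # nt either side of the 3' stop codon (Fig-3E-style profile)


@dataclass
class FrameSummary:
    region: str  # {CDS, UTR3}
    fractions: dict[int, float]  # frame label -> fraction of density


def frame_fractions(
    tracks: Mapping[str, DensityTrack],
    models: Mapping[str, TranscriptModel],
    region: str = "CDS",
    use: str = "rpm",
) -> FrameSummary:
    """Fraction of A-site density in frames {0, +1, -1} within a region.

    Densities are CDS-mean normalized per transcript before summing, so the
    result is invariant to per-transcript expression scaling.
    """
    sums = np.zeros(3)
    for tid, model in models.items():
        if tid not in tracks:
            continue
        denom = cds_mean_density(tracks[tid], model, use=use)
        if denom <= 0:
            continue
        vals = getattr(tracks[tid], use) / denom
        # codon starts: position p holds the A-site center, codon start p-1
        starts = np.arange(model.length) - 1
        if region == "CDS":
            mask = (starts >= model.cds_start) & (starts < model.cds_end)
        elif region == "UTR3":
            mask = starts >= model.cds_end
        else:
            raise ValueError(f"unknown region {region!r}")
        cls = np.mod(starts - model.cds_start, 3)
        for c in range(3):
            sums[c] += vals[mask & (cls == c)].sum()
    total = sums.sum()
    if total <= 0:
        raise ValueError(f"no density in region {region}")
    return FrameSummary(
        region=region,
        fractions={FRAME_LABELS[c]: float(sums[c] / total) for c in range(3)},
    )


def tc3_frame_metagene(
    tracks: Mapping[str, DensityTrack],
    models: Mapping[str, TranscriptModel],
    landmarks: Optional[Mapping[str, StopLandmarks]] = None,
    use: str = "rpm",
) -> pd.DataFrame:
    """Summed depth-normalized density around the first 3'UTR stop of each frame.

    For each frame f in {0, +1, -1} independently, the first stop triplet in
    the 3'UTR whose start lies in frame f is the anchor; density is summed
    per position over [-12, +12] relative to the anchor's first nucleotide.
    Transcripts with additional stop triplets (in any frame) starting
    within the window are discarded — termination at a nearby stop in
    another frame would otherwise distort the profile — as are transcripts
    where the window does not fit.

    Returns a long DataFrame (frame, position, density, n_transcripts).
    """
    rows = []
    for cls in range(3):
        label = FRAME_LABELS[cls]
        profile = np.zeros(2 * TC3_WINDOW + 1)
        n = 0
        for tid, model in models.items():
            if tid not in tracks:
                continue
            seq = model.seq.upper()
            # first 3'UTR stop whose start is in residue class `cls`
            first = model.cds_end + ((cls - (model.cds_end - model.cds_start)) % 3)
            anchor = None
            for p in range(first, model.length - 2, 3):
                if seq[p : p + 3] in STOP_CODONS:
                    anchor = p
                    break
            if anchor is None:
                continue
            if anchor - TC3_WINDOW < 0 or anchor + TC3_WINDOW >= model.length:
                continue
            extra = any(
                seq[p : p + 3] in STOP_CODONS
                for p in range(max(0, anchor - TC3_WINDOW - 2), anchor + TC3_WINDOW + 1)
                if p != anchor  # any stop triplet overlapping the window
            )
            if extra:
                continue
            vals = getattr(tracks[tid], use)
            profile += vals[anchor - TC3_WINDOW : anchor + TC3_WINDOW + 1]
            n += 1
        for i, pos in enumerate(range(-TC3_WINDOW, TC3_WINDOW + 1)):
            rows.append(
                {"frame": label, "position": pos, "density": profile[i], "n_transcripts": n}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# codon occupancy

OCC_CDS_TRIM = 15  # nt trimmed from each CDS end for the mean density
OCC_EDGE_CODONS = 2  # codons skipped at each end of the mRNA


def codon_occupancy(
    tracks: Mapping[str, DensityTrack],
    models: Mapping[str, TranscriptModel],
    use: str = "raw",
) -> pd.DataFrame:
    """Mean occupancy (pause score) of each of the 61 sense codons.

    For every occurrence of a codon (outside the first/last two codons of
    the CDS) the density over its 3-nt window, anchored at the A-site codon
    start, is divided by the transcript's CDS mean density computed with the
    first and last 15 nt excluded; the occupancy is the mean of these ratios
    over all occurrences.  Codons with zero occurrences are reported with
    n=0 and NaN occupancy.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for tid, model in models.items():
        if tid not in tracks:
            continue
        vals = getattr(tracks[tid], use)
        lo = model.cds_start + OCC_CDS_TRIM
        hi = model.cds_end - OCC_CDS_TRIM
        if hi <= lo:
            continue
        mean_density = float(vals[lo:hi].mean())
        if mean_density <= 0:
            continue
        seq = model.seq.upper()
        n_codons = (model.cds_end - model.cds_start) // 3
        for i in range(OCC_EDGE_CODONS, n_codons - OCC_EDGE_CODONS):
            q = model.cds_start + 3 * i
            codon = seq[q : q + 3]
            if codon in STOP_CODONS or "N" in codon:
                continue
            window = float(vals[q : q + 3].sum()) / 3.0
            sums[codon] = sums.get(codon, 0.0) + window / mean_density
            counts[codon] = counts.get(codon, 0) + 1

    rows = []
    for c1 in "ACGT":
        for c2 in "ACGT":
            for c3 in "ACGT":
                codon = c1 + c2 + c3
                if codon in STOP_CODONS:
                    continue
                n = counts.get(codon, 0)
                rows.append(
                    {
                        "codon": codon,
                        "amino_acid": str(Seq(codon).translate()),
                        "occupancy": sums[codon] / n if n else float("nan"),
                        "n_occurrences": n,
                    }
                )
    return pd.DataFrame(rows)
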
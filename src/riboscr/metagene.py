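"""Average-gene (metagene) profiles and the 3'UTR/CDS density ratio.

Profiles are anchored at the start or stop codon; position 0 of a
stop-anchored profile is the first nucleotide of the stop codon (the stop
occupies positions 0..2).  Each transcript's track is first normalized by
its own mean CDS density so every transcript contributes on the same scale;
profiles are then averaged transcript-weighted (each transcript counts
once).  Transcripts that cannot hold the full window, or with zero CDS
density, are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotation import TranscriptModel
from .ingest import DensityTrack

STOP_WINDOW = (-150, 100)
START_WINDOW = (-100, 150)
#: stop-anchored sub-windows of the 3'UTR/CDS ratio (inclusive bounds)
UTR_WINDOW = (5, 100)
CDS_WINDOW = (-147, -16)


@dataclass
class MetageneProfile:
    anchor: str  # {start, stop}
    window: tuple[int, int]
    mean_norm_density: np.ndarray
    n_transcripts: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] + 1)

    def value_at(self, lo: int, hi: int) -> float:
        """Mean profile value over inclusive position range [lo, hi]."""
        a = lo - self.window[0]
        b = hi - self.window[0] + 1
        return float(self.mean_norm_density[a:b].mean())


def cds_mean_density(track: DensityTrack, model: TranscriptModel, use: str = "rpm") -> float:
    vals = getattr(track, use)[model.cds_start : model.cds_end]
    return float(vals.mean())


def normalized_profile(
    track: DensityTrack,
    model: TranscriptModel,
    anchor: str = "stop",
    window: Optional[tuple[int, int]] = None,
    use: str = "rpm",
) -> Optional[np.ndarray]:
    """Per-position CDS-normalized densities in ``window`` around the anchor.

    Returns None when the window does not fit entirely inside the transcript
    or the mean CDS density is zero.
    """
    if window is None:
        window = STOP_WINDOW if anchor == "stop" else START_WINDOW
    if anchor == "stop":
        anchor_pos = model.cds_end - 3  # first nt of the stop codon
    elif anchor == "start":
        anchor_pos = model.cds_start
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    lo, hi = window
    if anchor_pos + lo < 0 or anchor_pos + hi >= model.length:
        return None
    denom = cds_mean_density(track, model, use=use)
    if denom <= 0:
        return None
    vals = getattr(track, use)[anchor_pos + lo : anchor_pos + hi + 1]
    return vals / denom


def average_profiles(
    profiles: Sequence[np.ndarray],
    anchor: str = "stop",
    window: Optional[tuple[int, int]] = None,
) -> MetageneProfile:
    """Unweighted per-position mean across transcripts."""
    if window is None:
        window = STOP_WINDOW if anchor == "stop" else START_WINDOW
    if not profiles:
        raise ValueError("no profiles to average")
    return MetageneProfile(
        anchor=anchor,
        window=window,
        mean_norm_density=np.mean(np.stack(profiles), axis=0),
        n_transcripts=len(profiles),
    )


def metagene(
    tracks: Mapping[str, DensityTrack],
    models: Mapping[str, TranscriptModel],
    anchor: str = "stop",
    window: Optional[tuple[int, int]] = None,
    use: str = "rpm",
) -> MetageneProfile:
    """Build and average stop- or start-anchored profiles over all transcripts."""
    profiles = []
    for tid, model in models.items():
        if tid not in tracks:
            continue
        p = normalized_profile(tracks[tid], model, anchor=anchor, window=window, use=use)
        if p is not None:
            profiles.append(p)
    return average_profiles(profiles, anchor=anchor, window=window)


def utr_cds_ratio(
    tracks: Mapping[str, DensityTrack],
    models: Mapping[str, TranscriptModel],
    use: str = "rpm",
    per_transcript: bool = False,
) -> float:
    """3'UTR density as a percentage of CDS density around the stop codon.

    The 3'UTR window is +5..+100 and the CDS window -147..-16 relative to
    the stop codon's first nucleotide, excluding stop-proximal positions.
    By default the ratio is computed on the averaged profile; with
    ``per_transcript`` it is the mean of per-transcript ratios (transcripts
    with zero CDS-window density skipped).
    """
    if per_transcript:
        ratios = []
        for tid, model in models.items():
            if tid not in tracks:
                continue
            p = normalized_profile(tracks[tid], model, anchor="stop", use=use)
            if p is None:
                continue
            prof = MetageneProfile("stop", STOP_WINDOW, p, 1)
            cds = prof.value_at(*CDS_WINDOW)
            if cds > 0:
                ratios.append(100.0 * prof.value_at(*UTR_WINDOW) / cds)
        if not ratios:
            raise ValueError("no transcripts with nonzero CDS window density")
        return float(np.mean(ratios))
    prof = metagene(tracks, models, anchor="stop", use=use)
    cds = prof.value_at(*CDS_WINDOW)
    if cds <= 0:
        raise ValueError("zero CDS window density in averaged profile")
    return 100.0 * prof.value_at(*UTR_WINDOW) / cds


def profile_table(profile: MetageneProfile):
    import pandas as pd

    return pd.DataFrame(
        {
            "position": profile.positions,
            "mean_norm_density": profile.mean_norm_density,
            "n_transcripts": profile.n_transcripts,
        }
    )
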
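"""The RRTS readthrough statistic and stop-codon comparisons.

The Ribosome ReadThrough Score (RRTS) of a transcript is the footprint
density (counts/nt) in the 3'UTR between the normal termination codon (NTC)
and the first in-frame 3'UTR stop codon (3'TC), divided by the footprint
density in the CDS.  Stated filters: transcripts with fewer than 128 mapped
reads, without an in-frame 3'TC, with fewer than 5 codons between NTC and
3'TC, or with zero CDS-window density are excluded (each with a recorded
reason).  The CDS window drops the first 18 and last 15 nt of the CDS to
avoid the initiation and termination peaks; the extension window drops the
6 nt immediately after the NTC.

Also provided: group comparisons of RRTS by stop-codon identity
(Mann-Whitney U), the log2 transform with the 2^-15 floor for zeros, and
the NTC-vs-3'TC relative-readthrough contrast on 30-nt flanks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import STOP_CODONS, StopLandmarks, TranscriptModel, find_landmarks
from .ingest import DensityTrack
from .metagene import cds_mean_density

MIN_TOTAL_READS = 128
MIN_CODONS_BETWEEN = 5
CDS_TRIM_START = 18
CDS_TRIM_END = 15
EXT_SKIP = 6
ZERO_FLOOR = 2.0 ** -15


@dataclass
class RRTSRecord:
    transcript_id: str
    cds_density: float
    ext_density: float
    rrts: float
    total_reads: int
    status: str  # "included" or "excluded:<reason>"

    @property
    def included(self) -> bool:
        return self.status == "included"


def compute_rrts(
    track: DensityTrack,
    model: TranscriptModel,
    landmarks: Optional[StopLandmarks] = None,
    min_reads: int = MIN_TOTAL_READS,
    min_codons: int = MIN_CODONS_BETWEEN,
) -> RRTSRecord:
    """RRTS for one transcript, or an excluded record with a single reason.

    Exclusion reasons, checked in order: ``low_reads`` (total assigned reads
    < 128), ``no_3tc``, ``short_extension`` (< 5 codons strictly between NTC
    and 3'TC, i.e. ``tc3_pos - cds_end < 15``), ``zero_cds``.
    """
    if landmarks is None:
        landmarks = find_landmarks(model)
    tid = model.transcript_id
    total = track.total_reads

    def excluded(reason: str) -> RRTSRecord:
        return RRTSRecord(tid, math.nan, math.nan, math.nan, total, f"excluded:{reason}")

    if total < min_reads:
        return excluded("low_reads")
    if landmarks.tc3_pos is None:
        return excluded("no_3tc")
    if landmarks.tc3_pos - model.cds_end < 3 * min_codons:
        return excluded("short_extension")

    cds_lo = model.cds_start + CDS_TRIM_START
    cds_hi = model.cds_end - CDS_TRIM_END
    if cds_hi <= cds_lo:
        return excluded("zero_cds")
    cds_density = float(track.raw[cds_lo:cds_hi].mean())
    if cds_density <= 0:
        return excluded("zero_cds")

    ext_lo = model.cds_end + EXT_SKIP
    ext_hi = landmarks.tc3_pos
    ext_density = float(track.raw[ext_lo:ext_hi].mean())
    return RRTSRecord(tid, cds_density, ext_density, ext_density / cds_density, total, "included")


def rrts_table(
    tracks: Mapping[str, DensityTrack],
    models: Mapping[str, TranscriptModel],
    landmarks: Optional[Mapping[str, StopLandmarks]] = None,
    min_reads: int = MIN_TOTAL_READS,
    min_codons: int = MIN_CODONS_BETWEEN,
) -> pd.DataFrame:
    """RRTS records for all transcripts as a DataFrame (one row each)."""
    rows = []
    for tid, model in models.items():
        if tid not in tracks:
            continue
        lm = landmarks[tid] if landmarks is not None else find_landmarks(model)
        r = compute_rrts(tracks[tid], model, lm, min_reads=min_reads, min_codons=min_codons)
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "cds_density": r.cds_density,
                "ext_density": r.ext_density,
                "rrts": r.rrts,
                "total_reads": r.total_reads,
                "status": r.status,
                "stop_codon": lm.stop_codon,
                "plus4": lm.plus4 or "",
            }
        )
    return pd.DataFrame(rows)


def log_transform_rrts(values: Sequence[float]) -> np.ndarray:
    """log2 RRTS for plotting; zeros are floored at 2^-15 (=> -15)."""
    v = np.asarray(values, dtype=float)
    return np.log2(np.where(v <= 0, ZERO_FLOOR, v))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Mann-Whitney U (statistic for x) with exact p for small untied groups.

    Exact enumeration is used when both groups have <= ``exact_max_n``
    observations and there are no ties; otherwise the normal approximation
    with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_rrts_by_stop(
    table: pd.DataFrame,
    grouping: str = "stop3",
    one_sided_plus4: str = "",
    min_group_size: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group RRTS by stop-codon identity and run pairwise Mann-Whitney U tests.

    ``grouping`` is ``"stop3"`` (UAA/UAG/UGA), ``"stop4"`` (stop codon +
    the +4 nucleotide, the 4-nt stop signal) or ``"plus4"`` (+4 nucleotide
    alone).  Tests are two-sided except when ``one_sided_plus4`` names a +4
    nucleotide (e.g. ``"C"``): comparisons of that group against others are
    then one-sided in the direction 'greater'.

    Returns ``(group_summaries, pairwise_tests)``.
    """
    inc = table[table["status"] == "included"].copy()
    if grouping == "stop3":
        inc["group"] = inc["stop_codon"]
    elif grouping == "stop4":
        inc["group"] = inc["stop_codon"] + inc["plus4"]
    elif grouping == "plus4":
        inc["group"] = inc["plus4"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    summaries = []
    groups: dict[str, np.ndarray] = {}
    for g, sub in inc.groupby("group"):
        vals = sub["rrts"].to_numpy()
        if len(vals) < min_group_size:
            continue
        groups[g] = vals
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        summaries.append(
            {"group": g, "n": len(vals), "median": med, "q1": q1, "q3": q3,
             "mean": float(vals.mean())}
        )
    names = sorted(groups)
    tests = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if one_sided_plus4 and (a.endswith(one_sided_plus4) or b.endswith(one_sided_plus4)):
                # test the +4-matched group as the 'greater' side
                if a.endswith(one_sided_plus4):
                    u, p = mann_whitney_u(groups[a], groups[b], alternative="greater")
                else:
                    u, p = mann_whitney_u(groups[b], groups[a], alternative="greater")
                alt = "greater"
            else:
                u, p = mann_whitney_u(groups[a], groups[b], alternative="two-sided")
                alt = "two-sided"
            tests.append({"group_a": a, "group_b": b, "U": u, "p": p, "alternative": alt})
    return pd.DataFrame(summaries), pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# NTC vs 3'TC relative readthrough

#: inclusive flank windows relative to the stop codon's first nucleotide:
#: 30 nt either side of the codon, minus the codon immediately adjacent
UP_FLANK = (-30, -4)
DOWN_FLANK = (6, 32)
FLANK = 30


@dataclass
class RelativeReadthroughRecord:
    transcript_id: str
    anchor: str  # {NTC, TC3}
    up_density: float
    down_density: float
    ratio: float


def _flank_ratio(norm: np.ndarray, stop_pos: int, length: int) -> Optional[tuple[float, float, float]]:
    lo_u, hi_u = stop_pos + UP_FLANK[0], stop_pos + UP_FLANK[1] + 1
    lo_d, hi_d = stop_pos + DOWN_FLANK[0], stop_pos + DOWN_FLANK[1] + 1
    if lo_u < 0 or hi_d > length:
        return None
    up = float(norm[lo_u:hi_u].mean())
    down = float(norm[lo_d:hi_d].mean())
    if up <= 0:
        return None
    return up, down, down / up


def relative_readthrough(
    tracks: Mapping[str, DensityTrack],
    models: Mapping[str, TranscriptModel],
    landmarks: Optional[Mapping[str, StopLandmarks]] = None,
    use: str = "rpm",
) -> pd.DataFrame:
    """Downstream/upstream density ratios around the NTC and the first 3'TC.

    Densities are CDS-mean normalized.  Flanks span 30 nt on either side of
    each stop codon excluding the codon immediately before and after it.
    Transcripts are excluded when they (1) lack an in-frame 3'TC, (2) have
    the first 3'TC within the first 30 nt of the 3'UTR, (3) have fewer than
    30 nt downstream of the 3'TC, or (4) have additional in-frame 3'TCs in
    the 30-nt window downstream of the first one.
    """
    rows = []
    for tid, model in models.items():
        if tid not in tracks:
            continue
        lm = landmarks[tid] if landmarks is not None else find_landmarks(model)
        if lm.tc3_pos is None:
            continue  # (1)
        if lm.tc3_pos - model.cds_end < FLANK:
            continue  # (2)
        if model.length - (lm.tc3_pos + 3) < FLANK:
            continue  # (3)
        seq = model.seq.upper()
        extra = any(
            seq[p : p + 3] in STOP_CODONS
            for p in range(lm.tc3_pos + 3, lm.tc3_pos + 3 + FLANK - 2, 3)
        )
        if extra:
            continue  # (4)
        denom = cds_mean_density(tracks[tid], model, use=use)
        if denom <= 0:
            continue
        norm = getattr(tracks[tid], use) / denom
        for anchor, pos in (("NTC", lm.ntc_pos), ("TC3", lm.tc3_pos)):
            res = _flank_ratio(norm, pos, model.length)
            if res is None:
                continue
            up, down, ratio = res
            rows.append(
                {"transcript_id": tid, "anchor": anchor, "up_density": up,
                 "down_density": down, "ratio": ratio}
            )
    return pd.DataFrame(rows)


def relative_readthrough_summary(
    replicate_tables: Sequence[pd.DataFrame],
) -> dict:
    """Per-anchor mean ratios per replicate, plus a paired t-test.

    The paired t-test compares the per-replicate mean TC3 ratio against the
    per-replicate mean NTC ratio; with fewer than 2 replicates the ratios
    are reported and the test skipped.
    """
    ntc_means, tc3_means = [], []
    for df in replicate_tables:
        ntc_means.append(float(df.loc[df["anchor"] == "NTC", "ratio"].mean()))
        tc3_means.append(float(df.loc[df["anchor"] == "TC3", "ratio"].mean()))
    out = {
        "ntc_mean_per_replicate": ntc_means,
        "tc3_mean_per_replicate": tc3_means,
        "ntc_mean": float(np.mean(ntc_means)),
        "tc3_mean": float(np.mean(tc3_means)),
    }
    if len(replicate_tables) >= 2:
        t, p = stats.ttest_rel(tc3_means, ntc_means)
        out["paired_t"] = float(t)
        out["paired_p"] = float(p)
    return out
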
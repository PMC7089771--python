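"""Stop-codon sequence-context statistics.

The sequence under a terminating ribosome's footprint — 15 nt upstream of
the stop codon through 12 nt downstream — modulates readthrough.  This
module pairs each transcript's 30-nt stop-codon context with its RRTS
weight and provides:

* position-weighted one-sided two-sample t-tests (does nucleotide n at
  position i increase or decrease RRTS relative to all other nucleotides
  there?), Benjamini-Hochberg adjusted over all tested cells;
* a ridge regression of RRTS on the one-hot context encoding: 27 positions
  x 4 nucleotides plus 3 stop-codon indicators = 111 binary features,
  default penalty alpha = 10^3;
* per-position nucleotide-frequency matrices around the NTC and the first
  in-frame 3'TC.

Positions are labelled -15..-1 (upstream), the stop codon as one 3-level
factor, and +4..+15 (downstream; +4 is the first nucleotide after the
stop).  RRTS values of zero are retained by default — absence of
readthrough is signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import STOP_CODONS, StopLandmarks, TranscriptModel, find_landmarks

UPSTREAM = 15
DOWNSTREAM = 12
CONTEXT_LEN = UPSTREAM + 3 + DOWNSTREAM  # 30

#: position labels of the 27 non-stop context positions, in context order
POSITION_LABELS: list[int] = list(range(-UPSTREAM, 0)) + list(range(4, 4 + DOWNSTREAM))
NUCLEOTIDES = "ACGT"
RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}


def _context_offset(label: int) -> int:
    """Context-string offset of a position label."""
    return label + UPSTREAM if label < 0 else UPSTREAM + 3 + (label - 4)


@dataclass
class ContextRecord:
    transcript_id: str
    context: str  # 30 nt, DNA alphabet
    stop_codon: str
    weight: float  # RRTS

    def __post_init__(self) -> None:
        if len(self.context) != CONTEXT_LEN:
            raise ValueError(f"{self.transcript_id}: context must be {CONTEXT_LEN} nt")
        if self.context[UPSTREAM : UPSTREAM + 3] != self.stop_codon:
            raise ValueError(f"{self.transcript_id}: context/stop codon mismatch")


def extract_contexts(
    models: Mapping[str, TranscriptModel],
    rrts: pd.DataFrame,
    landmarks: Optional[Mapping[str, StopLandmarks]] = None,
) -> list[ContextRecord]:
    """One context record per *included* RRTS transcript.

    Transcripts with 3'UTRs shorter than 12 nt (or fewer than 15 nt of CDS
    upstream of the stop codon) are discarded.  Zero RRTS weights are
    retained.
    """
    weights = rrts.loc[rrts["status"] == "included"].set_index("transcript_id")["rrts"]
    out = []
    for tid, w in weights.items():
        model = models.get(tid)
        if model is None:
            continue
        lm = landmarks[tid] if landmarks is not None else find_landmarks(model)
        if lm.utr3_len < DOWNSTREAM or lm.ntc_pos < UPSTREAM:
            continue
        ctx = model.seq.upper()[lm.ntc_pos - UPSTREAM : lm.ntc_pos + 3 + DOWNSTREAM]
        out.append(ContextRecord(tid, ctx, lm.stop_codon, float(w)))
    return out


# ---------------------------------------------------------------------------
# position-weighted t-tests


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Pooled-variance two-sample t statistic, dof; nan t on zero variance."""
    na, nb = len(a), len(b)
    dof = na + nb - 2
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # constant groups: numpy's variance can return rounding dust here,
        # so detect the degenerate case by exact range instead
        return (0.0, 0.0, dof) if a[0] == b[0] else (float("nan"), float("nan"), dof)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / dof
    if sp2 <= 0:
        # no variance anywhere: equal means carry no evidence (t=0);
        # unequal means with zero variance are a degenerate (untested) cell
        if a.mean() == b.mean():
            return 0.0, 0.0, dof
        return float("nan"), float("nan"), dof
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return float(t), sp2, dof


def weighted_position_tests(
    records: Sequence[ContextRecord],
    equal_var: bool = True,
    bh_level_cols: bool = True,
) -> pd.DataFrame:
    """Positional one-sided t-tests of RRTS weights, BH-adjusted jointly.

    For each of the 27 non-stop positions and each nucleotide, transcripts
    carrying that nucleotide there are compared against all others by a
    pooled-variance (Student) two-sample t-test — Welch with
    ``equal_var=False`` — one-sided in the direction of the observed mean
    difference.  The stop codon is tested analogously as three
    codon-vs-rest cells.  BH adjustment spans all tested cells in one
    family.  Cells with fewer than 2 records on either side or zero pooled
    variance are reported untested (NaN p).
    """
    weights = np.array([r.weight for r in records], dtype=float)
    rows = []

    def test_cell(position, symbol, mask):
        a, b = weights[mask], weights[~mask]
        if len(a) < 2 or len(b) < 2:
            return dict(position=position, nucleotide=symbol, t_stat=np.nan,
                        p_raw=np.nan, direction="", n_with=len(a), tested=False)
        if equal_var:
            t, _, dof = _pooled_t(a, b)
            if np.isnan(t):
                return dict(position=position, nucleotide=symbol, t_stat=np.nan,
                            p_raw=np.nan, direction="", n_with=len(a), tested=False)
            p_one = float(stats.t.sf(abs(t), dof))
        else:
            t, p_two = stats.ttest_ind(a, b, equal_var=False)
            if np.isnan(t):
                return dict(position=position, nucleotide=symbol, t_stat=np.nan,
                            p_raw=np.nan, direction="", n_with=len(a), tested=False)
            t, p_one = float(t), float(p_two) / 2
        return dict(
            position=position,
            nucleotide=symbol,
            t_stat=t,
            p_raw=p_one,
            direction="increases" if t >= 0 else "decreases",
            n_with=len(a),
            tested=True,
        )

    for label in POSITION_LABELS:
        off = _context_offset(label)
        chars = np.array([r.context[off] for r in records])
        for nt in NUCLEOTIDES:
            rows.append(test_cell(label, RNA[nt], chars == nt))
    stops = np.array([r.stop_codon for r in records])
    for codon in STOP_CODONS:
        rows.append(test_cell("stop", codon.replace("T", "U"), stops == codon))

    df = pd.DataFrame(rows)
    tested = df["tested"].to_numpy()
    padj = np.full(len(df), np.nan)
    if tested.any():
        padj[tested] = bh_adjust(df.loc[tested, "p_raw"].to_numpy())
    df["p_adj"] = padj
    return df.drop(columns=["tested"])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# ridge regression on one-hot contexts


@dataclass
class RidgeContextModel:
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    alpha: float

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names, "coefficient": self.coefficients}
        )

    def predict(self, records: Sequence[ContextRecord]) -> np.ndarray:
        X, _ = design_matrix(records)
        return X @ self.coefficients + self.intercept


def design_matrix(records: Sequence[ContextRecord]) -> tuple[np.ndarray, list[str]]:
    """One-hot design: 27 positions x 4 nucleotides + 3 stop indicators = 111."""
    names = [
        f"{label}:{RNA[nt]}" for label in POSITION_LABELS for nt in NUCLEOTIDES
    ] + [f"stop:{c.replace('T', 'U')}" for c in STOP_CODONS]
    X = np.zeros((len(records), len(names)))
    for i, r in enumerate(records):
        for j, label in enumerate(POSITION_LABELS):
            ch = r.context[_context_offset(label)]
            k = NUCLEOTIDES.find(ch)
            if k >= 0:
                X[i, 4 * j + k] = 1.0
        X[i, 4 * len(POSITION_LABELS) + STOP_CODONS.index(r.stop_codon)] = 1.0
    return X, names


def fit_context_ridge(
    records: Sequence[ContextRecord],
    alpha: float = 1e3,
    min_records: int = 200,
) -> RidgeContextModel:
    """Ridge regression of RRTS on the 111-feature one-hot context encoding.

    The intercept is fitted unpenalized and the binary features are not
    standardized.  ``alpha`` defaults to 10^3.
    """
    if len(records) < min_records:
        raise ValueError(
            f"need at least {min_records} context records, got {len(records)}"
        )
    from sklearn.linear_model import Ridge

    X, names = design_matrix(records)
    y = np.array([r.weight for r in records], dtype=float)
    model = Ridge(alpha=alpha, fit_intercept=True)
    model.fit(X, y)
    return RidgeContextModel(
        feature_names=names,
        coefficients=model.coef_.copy(),
        intercept=float(model.intercept_),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# nucleotide frequencies

NTC_FREQ_WINDOW = (40, 60)  # nt upstream / downstream of the NTC
TC3_FREQ_WINDOW = (12, 12)


def nucleotide_frequencies(
    models: Mapping[str, TranscriptModel],
    landmarks: Optional[Mapping[str, StopLandmarks]] = None,
    anchor: str = "NTC",
) -> pd.DataFrame:
    """Per-position nucleotide frequencies around the NTC or first 3'TC.

    NTC mode spans 40 nt upstream to 60 nt downstream (transcripts with
    3'UTRs shorter than 60 nt discarded); TC3 mode spans 12 nt either side
    of the first in-frame 3'TC (transcripts with <12 nt downstream of it,
    or with other in-frame 3'TCs in the window, discarded).  The stop codon
    is collapsed to a single row whose columns are the three stop codons;
    every row sums to 1.
    """
    if anchor == "NTC":
        up, down = NTC_FREQ_WINDOW
    elif anchor == "TC3":
        up, down = TC3_FREQ_WINDOW
    else:
        raise ValueError(f"unknown anchor {anchor!r}")

    labels = list(range(-up, 0)) + ["stop"] + list(range(4, 4 + down))
    cols = [RNA[n] for n in NUCLEOTIDES] + [c.replace("T", "U") for c in STOP_CODONS]
    windows: list[str] = []  # up nt + 3-nt stop + down nt per eligible transcript
    for tid, model in models.items():
        lm = landmarks[tid] if landmarks is not None else find_landmarks(model)
        seq = model.seq.upper()
        if anchor == "NTC":
            pos = lm.ntc_pos
            if lm.utr3_len < down or pos < up:
                continue
        else:
            pos = lm.tc3_pos
            if pos is None or pos < up or model.length - (pos + 3) < down:
                continue
            other = any(
                seq[p : p + 3] in STOP_CODONS
                for p in range(model.cds_end, model.length - 2, 3)
                if p != pos and pos - up <= p <= pos + down
            )
            if other:
                continue
        windows.append(seq[pos - up : pos + 3 + down])
    if not windows:
        raise ValueError("no eligible transcripts for nucleotide frequencies")

    chars = np.frombuffer("".join(windows).encode(), dtype="S1").reshape(
        len(windows), up + 3 + down
    )
    counts = pd.DataFrame(0.0, index=pd.Index(labels, name="position"), columns=cols)
    for j, label in enumerate(labels):
        if label == "stop":
            stops = [w[up : up + 3].replace("T", "U") for w in windows]
            vals, n = np.unique(stops, return_counts=True)
            for v, c in zip(vals, n):
                counts.loc["stop", str(v)] += int(c)
        else:
            col = j if j < up else up + 3 + (j - up - 1)
            vals, n = np.unique(chars[:, col], return_counts=True)
            for v, c in zip(vals, n):
                ch = v.decode()
                if ch in NUCLEOTIDES:
                    counts.loc[label, RNA[ch]] += int(c)
    freq = counts.div(counts.sum(axis=1), axis=0)
    freq.attrs["n_transcripts"] = len(windows)
    return freq
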
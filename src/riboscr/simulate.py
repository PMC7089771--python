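"""Synthetic ribosome-profiling data with fully known ground truth.

The generator emits a toy transcriptome (complete 5'UTR/CDS/3'UTR per
transcript, valid stop codons, optionally a forced in-frame 3'UTR stop at a
controlled distance) and footprint reads drawn from an explicit generative
model of translation:

* transcript chosen proportional to expression (log-normal) times its total
  ribosome load;
* the ribosome's A-site walks the CDS codon by codon with per-codon dwell
  multipliers, an initiation peak at the second codon and a pause at the
  stop codon;
* at the normal termination codon the ribosome continues into the 3'UTR
  with probability pi (optionally modulated by the stop-codon sequence
  context), and past each in-frame 3'UTR stop with probability
  ``tc3_readthrough``;
* the observed A-site is jittered off-frame by +-1 nt with probability
  1 - frame_fidelity (split evenly), modelling imperfect footprint ends;
* read length is drawn from a 28-35 nt distribution and the 5' end placed
  at ``A-site center - offset[length]`` using a known truth offset table.

Every random choice flows from a single integer seed, so identical
(spec, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import STOP_CODONS, TranscriptModel, reverse_complement
from .ingest import FULL_LENGTH_OFFSETS, FootprintReads

#: default read-length distribution over full-length footprints
DEFAULT_LENGTH_PROBS: dict[int, float] = {
    28: 0.08, 29: 0.14, 30: 0.20, 31: 0.20,
    32: 0.14, 33: 0.10, 34: 0.08, 35: 0.06,
}

#: approximate human stop-codon usage
DEFAULT_STOP_PROBS: dict[str, float] = {"TAA": 0.28, "TAG": 0.24, "TGA": 0.48}

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass
class SimulationSpec:
    """Parameters of the generative model (defaults emulate a G418-treated
    library: substantial NTC readthrough, partial termination at 3'UTR
    stops, a strong stop-codon pause)."""

    n_transcripts: int = 500
    utr5_len: tuple[int, int] = (60, 200)  # uniform inclusive range
    cds_codons: tuple[int, int] = (120, 400)
    utr3_len: tuple[int, int] = (150, 400)
    base_probs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    stop_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STOP_PROBS))
    expression_sigma: float = 1.0  # log-normal(0, sigma) expression
    n_reads: int = 1_000_000
    length_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_PROBS))
    offsets: dict[int, int] = field(default_factory=lambda: dict(FULL_LENGTH_OFFSETS))
    frame_fidelity: float = 0.95
    stop_pause: float = 5.0
    init_peak: float = 2.0
    codon_dwell: dict[str, float] = field(default_factory=dict)
    readthrough: float = 0.2  # base NTC readthrough probability pi
    tc3_readthrough: float = 0.46  # probability of reading through a 3'UTR stop
    #: multiplicative context effects on pi, keyed "pos:nt" (RNA letters;
    #: e.g. "4:C" doubles pi when C is at +4) or "stop:UGA"
    context_multipliers: dict[str, float] = field(default_factory=dict)
    tc3_distance: Optional[int] = None  # force the first 3'TC this many nt after the NTC
    tc3_clear_codons: int = 0  # non-stop in-frame codons guaranteed after the forced 3'TC
    plus4_probs: Optional[dict[str, float]] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclass
class Transcriptome:
    models: dict[str, TranscriptModel]
    truth: pd.DataFrame  # per-transcript ground truth

    def order(self) -> list[str]:
        return list(self.truth["transcript_id"])


def _sample_seq(rng: np.random.Generator, n: int, probs: dict[str, float]) -> str:
    letters = np.array(list("ACGT"))
    p = np.array([probs[x] for x in "ACGT"], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(letters, size=n, p=p)) if n else ""


def _sense_codon_probs(base_probs: dict[str, float]) -> np.ndarray:
    p = np.array(
        [np.prod([base_probs[c] for c in codon]) for codon in SENSE_CODONS]
    )
    return p / p.sum()


def _sample_codons(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    idx = rng.choice(len(SENSE_CODONS), size=n, p=probs)
    return "".join(SENSE_CODONS[i] for i in idx)


def _context_pi(spec: SimulationSpec, seq: str, cds_end: int) -> float:
    """Per-transcript readthrough probability with context multipliers applied."""
    pi = spec.readthrough
    for key, mult in spec.context_multipliers.items():
        pos_s, sym = key.split(":")
        if pos_s == "stop":
            if seq[cds_end - 3 : cds_end].replace("T", "U") == sym:
                pi *= mult
        else:
            label = int(pos_s)
            idx = cds_end - 3 + label if label < 0 else cds_end + (label - 4)
            if 0 <= idx < len(seq) and seq[idx].replace("T", "U") == sym:
                pi *= mult
    return min(pi, 0.95)


def simulate_transcriptome(spec: SimulationSpec, seed: int) -> Transcriptome:
    """Generate the toy transcriptome and its truth table.

    Raises ValueError when the forced 3'TC layout cannot fit into the
    3'UTR length range.
    """
    rng = np.random.default_rng(seed)
    codon_p = _sense_codon_probs(spec.base_probs)
    stop_names = list(spec.stop_probs)
    stop_p = np.array([spec.stop_probs[s] for s in stop_names], dtype=float)
    stop_p = stop_p / stop_p.sum()

    if spec.tc3_distance is not None:
        if spec.tc3_distance % 3 or spec.tc3_distance < 3:
            raise ValueError("tc3_distance must be a positive multiple of 3")
        need = spec.tc3_distance + 3 + 3 * spec.tc3_clear_codons
        if need > spec.utr3_len[0]:
            raise ValueError(
                f"3'UTR minimum length {spec.utr3_len[0]} cannot hold a 3'TC at "
                f"+{spec.tc3_distance} with {spec.tc3_clear_codons} clear codons"
            )

    models: dict[str, TranscriptModel] = {}
    rows = []
    width = len(str(spec.n_transcripts))
    expression = rng.lognormal(mean=0.0, sigma=spec.expression_sigma, size=spec.n_transcripts)
    for i in range(spec.n_transcripts):
        tid = f"TX{i:0{width}d}"
        u5 = int(rng.integers(spec.utr5_len[0], spec.utr5_len[1] + 1))
        ncod = int(rng.integers(spec.cds_codons[0], spec.cds_codons[1] + 1))
        u3 = int(rng.integers(spec.utr3_len[0], spec.utr3_len[1] + 1))
        stop = stop_names[int(rng.choice(len(stop_names), p=stop_p))]
        cds = "ATG" + _sample_codons(rng, ncod - 2, codon_p) + stop
        utr3 = _build_utr3(rng, spec, u3, codon_p, stop_names, stop_p)
        seq = _sample_seq(rng, u5, spec.base_probs) + cds + utr3
        cds_start, cds_end = u5, u5 + 3 * ncod
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=f"G{i:0{width}d}",
            chrom=tid,
            strand="+",
            exons=[(0, len(seq))],
            seq=seq,
            cds_start=cds_start,
            cds_end=cds_end,
        )
        models[tid] = model
        pi = _context_pi(spec, seq, cds_end)
        from .annotation import find_landmarks

        lm = find_landmarks(model)
        rows.append(
            {
                "transcript_id": tid,
                "expression": expression[i],
                "pi": pi,
                "stop_codon": stop,
                "plus4": lm.plus4,
                "tc3_pos": -1 if lm.tc3_pos is None else lm.tc3_pos,
                "utr5_len": u5,
                "cds_len": 3 * ncod,
                "utr3_len": u3,
            }
        )
    return Transcriptome(models=models, truth=pd.DataFrame(rows))


def _build_utr3(rng, spec, u3, codon_p, stop_names, stop_p) -> str:
    plus4 = None
    if spec.plus4_probs is not None:
        names = list(spec.plus4_probs)
        p = np.array([spec.plus4_probs[n] for n in names], dtype=float)
        plus4 = names[int(rng.choice(len(names), p=p / p.sum()))]
    if spec.tc3_distance is None:
        utr3 = _sample_seq(rng, u3, spec.base_probs)
        if plus4 is not None and u3:
            utr3 = plus4 + utr3[1:]
        return utr3
    # forced 3'TC: non-stop in-frame codons up to the forced stop, the stop,
    # a guaranteed stop-free stretch, then unconstrained sequence
    n_pre = spec.tc3_distance // 3
    pre = _sample_codons(rng, n_pre, codon_p)
    if plus4 is not None and n_pre:
        cand = plus4 + pre[1:3]
        while cand in STOP_CODONS:
            cand = plus4 + _sample_codons(rng, 1, codon_p)[1:3]
        pre = cand + pre[3:]
    tc3 = stop_names[int(rng.choice(len(stop_names), p=stop_p))]
    clear = _sample_codons(rng, spec.tc3_clear_codons, codon_p)
    rest = _sample_seq(rng, u3 - len(pre) - 3 - len(clear), spec.base_probs)
    return pre + tc3 + clear + rest


# ---------------------------------------------------------------------------
# footprint simulation


def _position_weights(spec: SimulationSpec, model: TranscriptModel, pi: float):
    """A-site codon-start positions and dwell-times-flux weights for one transcript."""
    seq = model.seq.upper()
    qs, ws = [], []
    ncod = (model.cds_end - model.cds_start) // 3
    for k in range(1, ncod):
        q = model.cds_start + 3 * k
        codon = seq[q : q + 3]
        if k == ncod - 1:
            w = spec.stop_pause
        else:
            w = spec.codon_dwell.get(codon, 1.0)
            if k == 1:
                w *= spec.init_peak
        qs.append(q)
        ws.append(w)
    flux = pi
    q = model.cds_end
    while q + 3 <= model.length and flux > 1e-9:
        codon = seq[q : q + 3]
        if codon in STOP_CODONS:
            qs.append(q)
            ws.append(flux * spec.stop_pause)
            flux *= spec.tc3_readthrough
        else:
            qs.append(q)
            ws.append(flux * spec.codon_dwell.get(codon, 1.0))
        q += 3
    return np.asarray(qs, dtype=np.int64), np.asarray(ws, dtype=np.float64)


def simulate_footprints(
    spec: SimulationSpec,
    transcriptome: Transcriptome,
    seed: int,
) -> tuple[FootprintReads, dict]:
    """Draw footprint reads from the generative model.

    Returns ``(reads, info)``; ``info`` counts requested, emitted, and
    rejected (off-transcript 5' end) reads.
    """
    rng = np.random.default_rng(seed)
    order = transcriptome.order()
    expr = transcriptome.truth.set_index("transcript_id")["expression"]
    pi = transcriptome.truth.set_index("transcript_id")["pi"]

    all_q, all_w, all_tx = [], [], []
    tx_len = np.zeros(len(order), dtype=np.int64)
    for i, tid in enumerate(order):
        model = transcriptome.models[tid]
        tx_len[i] = model.length
        q, w = _position_weights(spec, model, float(pi[tid]))
        all_q.append(q)
        all_w.append(w * float(expr[tid]))
        all_tx.append(np.full(len(q), i, dtype=np.int64))
    q = np.concatenate(all_q)
    w = np.concatenate(all_w)
    tx = np.concatenate(all_tx)
    p = w / w.sum()

    counts = rng.multinomial(spec.n_reads, p)
    reads_q = np.repeat(q, counts)
    reads_tx = np.repeat(tx, counts)
    n = len(reads_q)

    # off-frame jitter of the observed A-site (+-1 nt, evenly split)
    f = spec.frame_fidelity
    jitter = rng.choice([-1, 0, 1], size=n, p=[(1 - f) / 2, f, (1 - f) / 2])
    center = reads_q + 1 + jitter

    lengths = np.array(sorted(spec.length_probs), dtype=np.int64)
    lp = np.array([spec.length_probs[int(L)] for L in lengths], dtype=float)
    lp = lp / lp.sum()
    read_len = lengths[rng.choice(len(lengths), size=n, p=lp)]
    off = np.array([spec.offsets[int(L)] for L in lengths], dtype=np.int64)
    offset_of = dict(zip(lengths.tolist(), off.tolist()))
    five = center - np.array([offset_of[int(L)] for L in read_len], dtype=np.int64)

    ok = (five >= 0) & (five + read_len <= tx_len[reads_tx])
    info = {
        "n_requested": int(spec.n_reads),
        "n_emitted": int(ok.sum()),
        "n_rejected_off_transcript": int((~ok).sum()),
    }
    reads = FootprintReads(
        transcript_ids=order,
        tx_index=reads_tx[ok],
        five_prime=five[ok],
        length=read_len[ok],
    )
    return reads, info


# ---------------------------------------------------------------------------
# serialization: FASTA, GTF, SAM, truth table


def write_fasta(transcriptome: Transcriptome, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for tid in transcriptome.order():
            seq = transcriptome.models[tid].seq
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gtf_attrs(gene_id: str, tid: str, extra: str = "") -> str:
    return (
        f'gene_id "{gene_id}"; transcript_id "{tid}"; '
        f'gene_type "protein_coding"; transcript_type "protein_coding";{extra}'
    )


def write_gtf(transcriptome: Transcriptome, path: str) -> None:
    """Transcript-space GTF: each transcript is a single-exon plus-strand
    gene on its own contig (contig name == transcript id)."""
    with open(path, "w") as fh:
        for tid in transcriptome.order():
            m = transcriptome.models[tid]
            attrs = _gtf_attrs(m.gene_id, tid)
            rows = [
                ("gene", 1, m.length),
                ("transcript", 1, m.length),
                ("exon", 1, m.length),
                ("CDS", m.cds_start + 1, m.cds_end - 3),  # GENCODE: CDS excludes stop
                ("stop_codon", m.cds_end - 2, m.cds_end),
            ]
            for feat, a, b in rows:
                fh.write(
                    f"{tid}\tsim\t{feat}\t{a}\t{b}\t.\t+\t.\t{attrs}\n"
                )


def write_sam(reads: FootprintReads, transcriptome: Transcriptome, path: str) -> None:
    """Emit reads as primary transcript-space SAM alignments (deterministic bytes)."""
    models = transcriptome.models
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for tid in reads.transcript_ids:
            fh.write(f"@SQ\tSN:{tid}\tLN:{models[tid].length}\n")
        for i in range(len(reads)):
            tid = reads.transcript_ids[int(reads.tx_index[i])]
            fp = int(reads.five_prime[i])
            L = int(reads.length[i])
            seq = models[tid].seq[fp : fp + L]
            fh.write(
                f"read{i}\t0\t{tid}\t{fp + 1}\t255\t{L}M\t*\t0\t0\t{seq}\t*\n"
            )


def write_truth(transcriptome: Transcriptome, path: str) -> None:
    transcriptome.truth.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# genome embedding (exercises the genome-space projection path)


def embed_in_genome(
    transcriptome: Transcriptome,
    seed: int,
    chrom: str = "chrS1",
    spacer: int = 300,
    minus_fraction: float = 0.5,
    intron_prob: float = 0.5,
    intron_len: tuple[int, int] = (60, 200),
) -> tuple[dict[str, str], dict[str, TranscriptModel]]:
    """Place the transcripts on a toy chromosome with optional introns.

    Returns ``(genome, models)`` where ``genome`` maps chromosome name to
    sequence and ``models`` are genome-space TranscriptModels (possibly
    minus-strand and multi-exon) equivalent to the transcript-space ones.
    """
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    cursor = 0
    models: dict[str, TranscriptModel] = {}
    for tid in transcriptome.order():
        m = transcriptome.models[tid]
        gap = _sample_seq(rng, spacer, {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
        pieces.append(gap)
        cursor += spacer
        strand = "-" if rng.random() < minus_fraction else "+"
        gseq_tx = m.seq if strand == "+" else reverse_complement(m.seq)

        if rng.random() < intron_prob and m.length > 20:
            brk = int(rng.integers(10, m.length - 10))  # transcript coordinate
            ilen = int(rng.integers(intron_len[0], intron_len[1] + 1))
            intron = _sample_seq(rng, ilen, {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
            gbrk = brk if strand == "+" else m.length - brk
            genomic = gseq_tx[:gbrk] + intron + gseq_tx[gbrk:]
            exons = [
                (cursor, cursor + gbrk),
                (cursor + gbrk + ilen, cursor + m.length + ilen),
            ]
        else:
            genomic = gseq_tx
            exons = [(cursor, cursor + m.length)]
        pieces.append(genomic)
        cursor += len(genomic)

        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=m.gene_id,
            chrom=chrom,
            strand=strand,
            exons=exons,
            seq=m.seq,
            cds_start=m.cds_start,
            cds_end=m.cds_end,
        )
    genome = {chrom: "".join(pieces)}
    return genome, models


def _tx_interval_to_genomic(m: TranscriptModel, lo: int, hi: int) -> list[tuple[int, int]]:
    """Genomic intervals (0-based half-open) of transcript range [lo, hi)."""
    out: list[tuple[int, int]] = []
    for pos in range(lo, hi):
        g = m.to_genomic(pos)
        if out and out[-1][1] == g:
            out[-1] = (out[-1][0], g + 1)
        elif out and out[-1][0] == g + 1:
            out[-1] = (g, out[-1][1])
        else:
            out.append((g, g + 1))
    return sorted(out)


def write_genome_annotation(
    genome: dict[str, str],
    models: dict[str, TranscriptModel],
    fasta_path: str,
    gtf_path: str,
) -> None:
    """Write the embedded toy genome as FASTA + GENCODE-dialect GTF."""
    with open(fasta_path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(gtf_path, "w") as fh:
        for tid, m in models.items():
            attrs = _gtf_attrs(m.gene_id, tid)
            span = m.genomic_span
            fh.write(
                f"{m.chrom}\tsim\tgene\t{span[0] + 1}\t{span[1]}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{m.chrom}\tsim\ttranscript\t{span[0] + 1}\t{span[1]}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for a, b in m.exons:
                fh.write(
                    f"{m.chrom}\tsim\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            for a, b in _tx_interval_to_genomic(m, m.cds_start, m.cds_end - 3):
                fh.write(
                    f"{m.chrom}\tsim\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            for a, b in _tx_interval_to_genomic(m, m.cds_end - 3, m.cds_end):
                fh.write(
                    f"{m.chrom}\tsim\tstop_codon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}\n"
                )
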
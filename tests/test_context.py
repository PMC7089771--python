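"""Stop-codon context statistics: extraction, t-tests, BH, ridge, frequencies."""

import numpy as np
import pandas as pd
import pytest

from riboscr.context import (
    POSITION_LABELS,
    ContextRecord,
    bh_adjust,
    design_matrix,
    extract_contexts,
    fit_context_ridge,
    nucleotide_frequencies,
    weighted_position_tests,
)

from conftest import make_transcript


def _rrts_frame(entries):
    return pd.DataFrame(
        [{"transcript_id": tid, "rrts": w, "status": status} for tid, w, status in entries]
    )


def _random_records(rng, n, weights=None):
    recs = []
    for i in range(n):
        up = "".join(rng.choice(list("ACGT"), size=15))
        down = "".join(rng.choice(list("ACGT"), size=12))
        stop = rng.choice(["TAA", "TAG", "TGA"])
        w = float(weights[i]) if weights is not None else float(rng.exponential(0.1))
        recs.append(ContextRecord(f"t{i}", up + stop + down, stop, w))
    return recs


# ---------------------------------------------------------------------------
# extraction


def test_extract_context_equals_hand_slice():
    utr3 = "GATTACAGGG" + "TAA" + "C" * 30
    t = make_transcript(utr5=30, cds_codons=30, utr3=utr3, stop="TGA")
    table = _rrts_frame([("T1", 0.25, "included")])
    recs = extract_contexts({"T1": t}, table)
    assert len(recs) == 1
    r = recs[0]
    assert r.context == t.seq[t.cds_end - 18 : t.cds_end + 12]
    assert r.stop_codon == "TGA"
    assert r.context[15:18] == "TGA"
    assert r.context[18:28] == "GATTACAGGG"
    assert r.weight == 0.25


def test_extract_drops_short_utr_and_keeps_zero_weights():
    short = make_transcript(utr5=30, cds_codons=30, utr3=10, transcript_id="S")
    ok = make_transcript(utr5=30, cds_codons=30, utr3=40, transcript_id="K")
    table = _rrts_frame([("S", 0.1, "included"), ("K", 0.0, "included"),
                         ("X", 0.5, "excluded:low_reads")])
    recs = extract_contexts({"S": short, "K": ok}, table)
    assert [r.transcript_id for r in recs] == ["K"]
    assert recs[0].weight == 0.0


# ---------------------------------------------------------------------------
# weighted position tests


def test_identical_weights_give_t_zero_p_half():
    rng = np.random.default_rng(3)
    recs = _random_records(rng, 50, weights=np.full(50, 0.2))
    df = weighted_position_tests(recs)
    tested = df.dropna(subset=["p_raw"])
    assert len(tested) > 0
    np.testing.assert_allclose(tested["t_stat"], 0.0)
    np.testing.assert_allclose(tested["p_raw"], 0.5)


def test_zero_variance_with_different_means_is_untested():
    recs = [
        ContextRecord("a", "A" * 15 + "TAA" + "A" * 12, "TAA", 2.0),
        ContextRecord("b", "A" * 15 + "TAA" + "A" * 12, "TAA", 2.0),
        ContextRecord("c", "C" * 15 + "TAA" + "C" * 12, "TAA", 1.0),
        ContextRecord("d", "C" * 15 + "TAA" + "C" * 12, "TAA", 1.0),
    ]
    df = weighted_position_tests(recs)
    cell = df[(df.position == -1) & (df.nucleotide == "A")]
    assert np.isnan(cell["p_raw"].iloc[0])


def test_detects_planted_effect_and_direction():
    rng = np.random.default_rng(11)
    recs = _random_records(rng, 600)
    boosted = [
        ContextRecord(r.transcript_id, r.context, r.stop_codon,
                      r.weight * (3.0 if r.context[18] == "C" else 1.0))
        for r in recs
    ]
    df = weighted_position_tests(boosted)
    cell = df[(df.position == 4) & (df.nucleotide == "C")].iloc[0]
    assert cell["direction"] == "increases"
    assert cell["p_adj"] < 0.01


def test_tests_invariant_to_weight_rescaling():
    rng = np.random.default_rng(13)
    recs = _random_records(rng, 200)
    scaled = [ContextRecord(r.transcript_id, r.context, r.stop_codon, r.weight * 37.0)
              for r in recs]
    a = weighted_position_tests(recs)
    b = weighted_position_tests(scaled)
    np.testing.assert_allclose(a["t_stat"], b["t_stat"], rtol=1e-9)


# ---------------------------------------------------------------------------
# BH


def _bh_brute_force(p):
    """Step-up BH from the definition: p_(i) * m / i, cumulative-min from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def test_bh_examples():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)
    np.testing.assert_allclose(bh_adjust([0.37]), [0.37])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_bh_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(19)
    for _ in range(50):
        p = rng.uniform(size=int(rng.integers(1, 30)))
        np.testing.assert_allclose(bh_adjust(p), _bh_brute_force(p), atol=1e-12)


def test_bh_preserves_order_monotonicity():
    rng = np.random.default_rng(20)
    p = rng.uniform(size=40)
    adj = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)
    assert np.all(adj >= p)


# ---------------------------------------------------------------------------
# ridge


def _ridge_closed_form(X, y, alpha):
    """(Xc'Xc + aI)^-1 Xc'y with unpenalized intercept via centering."""
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    beta = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(X.shape[1]), Xc.T @ yc)
    return beta, ym - xm @ beta


def test_design_matrix_shape_and_row_sums():
    rng = np.random.default_rng(23)
    recs = _random_records(rng, 20)
    X, names = design_matrix(recs)
    assert X.shape == (20, 111)
    assert len(names) == 111
    # each record: one indicator per non-stop position plus one stop indicator
    np.testing.assert_allclose(X.sum(axis=1), len(POSITION_LABELS) + 1)


def test_ridge_matches_closed_form():
    rng = np.random.default_rng(29)
    recs = _random_records(rng, 300)
    model = fit_context_ridge(recs, alpha=1e3, min_records=100)
    X, _ = design_matrix(recs)
    y = np.array([r.weight for r in recs])
    beta, intercept = _ridge_closed_form(X, y, 1e3)
    np.testing.assert_allclose(model.coefficients, beta, atol=1e-8)
    assert model.intercept == pytest.approx(intercept, abs=1e-8)


def test_ridge_penalty_limit_shrinks_to_mean():
    rng = np.random.default_rng(31)
    recs = _random_records(rng, 250)
    model = fit_context_ridge(recs, alpha=1e12, min_records=100)
    np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-6)
    y = np.array([r.weight for r in recs])
    assert model.intercept == pytest.approx(y.mean(), abs=1e-6)


def test_ridge_recovers_effect_signs():
    rng = np.random.default_rng(37)
    recs = _random_records(rng, 1500)
    adjusted = []
    for r in recs:
        w = 0.1
        if r.stop_codon == "TGA":
            w += 0.05
        if r.context[18] == "G":  # +4 G decreases readthrough
            w -= 0.03
        adjusted.append(ContextRecord(r.transcript_id, r.context, r.stop_codon,
                                      w + rng.normal(0, 0.01)))
    model = fit_context_ridge(adjusted, alpha=1e3)
    coef = dict(zip(model.feature_names, model.coefficients))
    assert coef["stop:UGA"] > 0
    assert coef["4:G"] < 0


def test_ridge_requires_minimum_records():
    rng = np.random.default_rng(41)
    with pytest.raises(ValueError):
        fit_context_ridge(_random_records(rng, 50), min_records=200)


# ---------------------------------------------------------------------------
# nucleotide frequencies


def test_frequencies_all_A_transcriptome():
    models = {}
    for i in range(3):
        tid = f"T{i}"
        models[tid] = make_transcript(utr5=50, cds_codons=40, utr3="A" * 70,
                                      transcript_id=tid, filler="AAG", stop="TAA")
    freq = nucleotide_frequencies(models, anchor="NTC")
    np.testing.assert_allclose(freq.sum(axis=1), 1.0)
    assert freq.loc["stop", "UAA"] == 1.0
    non_stop = freq.drop(index="stop")
    # every sampled position is A or G (filler AAG upstream, poly-A downstream)
    assert (non_stop["A"] + non_stop["G"]).min() == pytest.approx(1.0)
    assert (non_stop.loc[[p for p in non_stop.index if p > 0], "A"] == 1.0).all()


def test_frequencies_plus4_counting():
    a = make_transcript(utr5=50, cds_codons=40, utr3="A" + "C" * 69, transcript_id="A")
    g = make_transcript(utr5=50, cds_codons=40, utr3="G" + "C" * 69, transcript_id="G")
    freq = nucleotide_frequencies({"A": a, "G": g}, anchor="NTC")
    row = freq.loc[4]
    assert row["A"] == 0.5 and row["G"] == 0.5 and row["C"] == 0.0


def test_frequencies_tc3_window_filters():
    # eligible transcript: 3'TC at +45 with a clean +-12 window
    ok = make_transcript(utr5=50, cds_codons=40, utr3="C" * 45 + "TAA" + "C" * 45,
                         transcript_id="OK")
    # second in-frame stop 6 nt after the 3'TC: window dirty -> dropped
    dirty = make_transcript(utr5=50, cds_codons=40,
                            utr3="C" * 45 + "TAA" + "CCC" + "TGA" + "C" * 39,
                            transcript_id="D")
    freq = nucleotide_frequencies({"OK": ok, "D": dirty}, anchor="TC3")
    assert freq.attrs["n_transcripts"] == 1
    np.testing.assert_allclose(freq.sum(axis=1), 1.0)


def test_frequencies_recover_generator_composition():
    """+4 distribution (G .4, A .3, C .2, U .1) recovered within +-0.01 at n=10,000."""
    from riboscr.simulate import SimulationSpec, simulate_transcriptome

    spec = SimulationSpec(
        n_transcripts=10_000, utr5_len=(50, 60), cds_codons=(30, 40),
        utr3_len=(70, 90), plus4_probs={"G": 0.4, "A": 0.3, "C": 0.2, "T": 0.1},
    )
    txome = simulate_transcriptome(spec, 43)
    freq = nucleotide_frequencies(txome.models, anchor="NTC")
    row = freq.loc[4]
    for nt, expect in (("G", 0.4), ("A", 0.3), ("C", 0.2), ("U", 0.1)):
        assert row[nt] == pytest.approx(expect, abs=0.01)
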
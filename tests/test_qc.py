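"""Drift correction, CV and dilution-linearity gates."""

import numpy as np
import pandas as pd
import pytest

import sphingoquant as sq
from sphingoquant.qc import (
    compute_cv,
    correct_drift,
    dilution_linearity,
    filter_species,
    qc_metrics,
)


def _sequence(n_study=8, batches=1, qc_every=4):
    rows = []
    for b in range(1, batches + 1):
        order = 0
        rows.append({"injection_id": f"QC{b}_0", "role": "pooled_qc", "batch": b, "order": order})
        for i in range(n_study):
            order += 1
            rows.append({"injection_id": f"S{b}_{i}", "role": "study", "batch": b, "order": order})
            if (i + 1) % qc_every == 0:
                order += 1
                rows.append(
                    {"injection_id": f"QC{b}_{(i + 1) // qc_every}", "role": "pooled_qc",
                     "batch": b, "order": order}
                )
    return pd.DataFrame(rows)


def test_drift_free_input_unchanged():
    seq = _sequence()
    areas = pd.DataFrame(
        {"sp1": 100.0, "sp2": 50.0}, index=seq["injection_id"]
    )
    out = correct_drift(areas, seq)
    np.testing.assert_allclose(out.to_numpy(), areas.to_numpy(), rtol=1e-12)


def test_monotone_drift_reduces_qc_cv():
    cfg = sq.GeneratorConfig(seed=21, n_per_group=30, noise_cv=0.0, drift_amplitude=0.8,
                             n_batches=1)
    table, _ = sq.generate_cohort(cfg)
    peaks, seq, lib, _ = sq.generate_injection_run(table, cfg)
    ann, _ = sq.match_peaks(peaks, lib)
    conc = sq.quantify_injections(ann)
    sub = seq[seq["role"].isin(["study", "pooled_qc"])]
    raw = conc.loc[sub["injection_id"]]
    corrected = correct_drift(raw, sub)
    qc_ids = sub.loc[sub["role"] == "pooled_qc", "injection_id"]
    pre = np.array([compute_cv(raw.loc[qc_ids, s]) for s in table.species])
    post = np.array([compute_cv(corrected.loc[qc_ids, s]) for s in table.species])
    assert np.nanmean(post) < np.nanmean(pre)
    assert (post <= pre + 1e-9).mean() > 0.95


def test_two_batch_offset_alignment():
    seq = _sequence(n_study=4, batches=2, qc_every=2)
    base = pd.Series(1.0, index=seq["injection_id"])
    base[seq.set_index("injection_id")["batch"] == 2] = 1.5  # flat 1.5x batch offset
    areas = pd.DataFrame({"sp": base * 100.0})
    out = correct_drift(areas, seq)
    qc = seq[seq["role"] == "pooled_qc"].set_index("injection_id")
    med1 = out.loc[qc.index[qc["batch"] == 1], "sp"].median()
    med2 = out.loc[qc.index[qc["batch"] == 2], "sp"].median()
    assert med1 == pytest.approx(med2, rel=1e-12)


def test_single_qc_batch_warns_and_scales(caplog):
    seq = pd.DataFrame(
        [
            {"injection_id": "QC0", "role": "pooled_qc", "batch": 1, "order": 0},
            {"injection_id": "S0", "role": "study", "batch": 1, "order": 1},
        ]
    )
    areas = pd.DataFrame({"sp": [200.0, 100.0]}, index=["QC0", "S0"])
    with caplog.at_level("WARNING"):
        out = correct_drift(areas, seq)
    assert "median-only" in caplog.text
    # flat scaling by the lone QC, re-anchored to the grand QC median
    assert out.loc["S0", "sp"] == pytest.approx(100.0)


def test_cv_formula_and_boundary():
    assert compute_cv([5.0, 5.0, 5.0]) == pytest.approx(0.0)
    assert compute_cv([8.0, 10.0, 12.0]) == pytest.approx(20.0)  # sd 2, mean 10
    assert np.isnan(compute_cv([4.0]))
    assert np.isnan(compute_cv([1.0, -3.0]))  # non-positive mean


def test_dilution_linearity_perfect_and_flat():
    df = np.array([1, 2, 5, 10, 20, 50, 100], dtype=float)
    assert dilution_linearity(1000.0 / df, df) == pytest.approx(1.0)
    assert dilution_linearity(np.full(df.size, 7.0), df) == pytest.approx(0.0, abs=1e-12)


def test_dilution_linearity_drops_missing_high_df_points():
    df = np.array([1, 2, 5, 10, 20, 50], dtype=float)
    areas = 1000.0 / df
    areas[-2:] = 0.0  # below detection
    assert dilution_linearity(areas, df) == pytest.approx(1.0)
    assert np.isnan(dilution_linearity([100.0, 50.0, 0.0, 0.0, 0.0, 0.0], df))


def test_filter_boundaries_are_strict():
    metrics = pd.DataFrame(
        {
            "species": ["ok", "cv_at_25", "r2_at_0.8", "both_bad"],
            "cv_percent": [10.0, 25.0, 10.0, 30.0],
            "dilution_r2": [0.95, 0.95, 0.8, 0.5],
        }
    )
    metrics["accepted"] = (metrics["cv_percent"] < 25.0) & (metrics["dilution_r2"] > 0.8)
    metrics["reject_reason"] = [
        "", "cv", "r2", "cv;r2"
    ]
    accepted, audit = filter_species(metrics)
    assert accepted == ["ok"]
    assert audit.loc[audit["species"] == "both_bad", "reject_reason"].item() == "cv;r2"


def test_qc_metrics_flags_noisy_species(clean_run):
    """Species given inflated QC noise are rejected with reason 'cv'."""
    table, peaks, sequence, library, _ = clean_run
    ann, _ = sq.match_peaks(peaks, library)
    conc = sq.quantify_injections(ann)
    sub = sequence[sequence["role"].isin(["study", "pooled_qc"])]
    mat = conc.loc[sub["injection_id"]].copy()
    qc_ids = sub.loc[sub["role"] == "pooled_qc", "injection_id"]
    noisy = table.species[:5]
    # alternating 1x/2x factors over the QC injections: CV ≈ 38% > 25%
    pattern = np.where(np.arange(len(qc_ids)) % 2 == 0, 1.0, 2.0)
    mat.loc[qc_ids, noisy] *= pattern[:, None]
    metrics = qc_metrics(mat, sub)
    rejected = set(metrics.loc[~metrics["accepted"], "species"])
    assert rejected == set(noisy)
    assert (metrics.set_index("species").loc[noisy, "reject_reason"] == "cv").all()


def test_correction_preserves_within_injection_ratio_for_shared_trend():
    seq = _sequence(n_study=6, qc_every=3)
    order = seq["order"].to_numpy(dtype=float)
    trend = 1.0 + 0.1 * order  # identical drift shape for both species
    areas = pd.DataFrame(
        {"a": 100.0 * trend, "b": 40.0 * trend}, index=seq["injection_id"]
    )
    out = correct_drift(areas, seq)
    ratio = out["a"] / out["b"]
    np.testing.assert_allclose(ratio.to_numpy(), 2.5, rtol=1e-12)
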
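"""Pooled-QC-anchored drift correction and species admission filters.

A pooled QC sample (an aliquot mix of every study extract) is injected at a
fixed cadence; because its composition is constant, any trend in its
response tracks instrument drift.  The correction here is deterministic:
per species and batch, the QC responses are interpolated piecewise-linearly
over injection order, every injection is divided by the local trend, and the
result is rescaled to the grand median of all QC responses, which also
aligns batches to a common level.

Species admission follows two gates computed on the QC material: precision
(CV over pooled-QC injections, post-correction, strictly below 25%) and
dilution linearity (R² of log signal on log relative concentration over the
serial dilution series, strictly above 0.8).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_DILUTION_FACTORS",
    "CV_THRESHOLD",
    "R2_THRESHOLD",
    "correct_drift",
    "loo_qc_corrected",
    "compute_cv",
    "dilution_linearity",
    "qc_metrics",
    "filter_species",
]

log = logging.getLogger(__name__)

#: serial dilution factors of the pooled QC
DEFAULT_DILUTION_FACTORS = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 2000, 5000, 10000)

CV_THRESHOLD = 25.0  # percent, strict
R2_THRESHOLD = 0.8  # strict
MIN_DILUTION_POINTS = 4


def _check_sequence(sequence: pd.DataFrame) -> None:
    required = {"injection_id", "role", "batch", "order"}
    missing = required - set(sequence.columns)
    if missing:
        raise ValueError(f"injection sequence missing columns {sorted(missing)}")
    for batch, sub in sequence.groupby("batch"):
        o = sub["order"].to_numpy()
        if not (np.diff(np.sort(o)) > 0).all():
            raise ValueError(f"injection order not strictly increasing in batch {batch}")


def correct_drift(areas: pd.DataFrame, sequence: pd.DataFrame) -> pd.DataFrame:
    """Remove intra- and inter-batch intensity drift guided by pooled QCs.

    Parameters
    ----------
    areas : injections × species frame (raw responses; index = injection_id)
    sequence : manifest with columns injection_id, role, batch, order

    Returns
    -------
    Corrected frame with the same shape and index.  With ≥ 2 pooled QCs per
    batch the per-species QC trend is piecewise-linear in injection order
    (nearest-QC extrapolation at the ends); a batch with fewer pooled QCs is
    scaled by a single factor (its only QC, or left on the raw scale) with a
    logged warning.  Dilution-series injections are passed through on the
    trend of their batch.
    """
    _check_sequence(sequence)
    seq = sequence.set_index("injection_id")
    missing = [i for i in areas.index if i not in seq.index]
    if missing:
        raise ValueError(f"injections absent from sequence manifest: {missing[:5]}")
    qc_ids = seq.index[seq["role"] == "pooled_qc"]
    qc_ids = [i for i in qc_ids if i in areas.index]
    if len(qc_ids) == 0:
        raise ValueError("no pooled QC injections found")
    grand_median = areas.loc[qc_ids].median(axis=0)

    corrected = areas.copy().astype(float)
    order = seq.loc[areas.index, "order"]
    batch = seq.loc[areas.index, "batch"]
    for b in batch.unique():
        in_batch = areas.index[batch == b]
        b_qc = [i for i in qc_ids if seq.loc[i, "batch"] == b]
        x = order.loc[in_batch].to_numpy(dtype=float)
        if len(b_qc) >= 2:
            xq = order.loc[b_qc].to_numpy(dtype=float)
            sort = np.argsort(xq)
            xq = xq[sort]
            yq = areas.loc[b_qc].to_numpy(dtype=float)[sort]  # nQC × species
            # np.interp clamps to edge values -> nearest-QC extrapolation
            trend = np.stack([np.interp(x, xq, yq[:, j]) for j in range(yq.shape[1])], axis=1)
        else:
            log.warning("batch %s has < 2 pooled QCs; median-only scaling applied", b)
            if len(b_qc) == 1:
                trend = np.tile(areas.loc[b_qc].to_numpy(dtype=float), (len(in_batch), 1))
            else:
                trend = np.tile(areas.loc[in_batch].median(axis=0).to_numpy(), (len(in_batch), 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = areas.loc[in_batch].to_numpy(dtype=float) / trend
        corrected.loc[in_batch] = vals * grand_median.to_numpy()[None, :]
    return corrected


def loo_qc_corrected(areas: pd.DataFrame, sequence: pd.DataFrame) -> pd.DataFrame:
    """Pooled-QC responses corrected by a leave-one-out drift trend.

    The production correction interpolates the QC trend *through* every QC,
    which maps each QC exactly onto the grand median and would make the
    post-correction QC CV identically zero — hiding the very imprecision the
    CV filter is meant to catch.  For precision assessment each QC is
    therefore divided by the trend interpolated from the *other* QCs of its
    batch (nearest-QC extrapolation; a batch with a single QC passes the raw
    value through) and rescaled to the grand median.
    """
    _check_sequence(sequence)
    seq = sequence.set_index("injection_id")
    qc_ids = [i for i in areas.index if seq.loc[i, "role"] == "pooled_qc"]
    if not qc_ids:
        raise ValueError("no pooled QC injections found")
    grand_median = areas.loc[qc_ids].median(axis=0).to_numpy()
    rows = {}
    for b, batch_qcs in pd.Series(qc_ids).groupby([seq.loc[i, "batch"] for i in qc_ids]):
        ids = list(batch_qcs)
        orders = seq.loc[ids, "order"].to_numpy(dtype=float)
        vals = areas.loc[ids].to_numpy(dtype=float)
        for j, qid in enumerate(ids):
            if len(ids) < 2:
                rows[qid] = vals[j]
                continue
            others = [k for k in range(len(ids)) if k != j]
            xq = orders[others]
            sort = np.argsort(xq)
            trend = np.array(
                [np.interp(orders[j], xq[sort], vals[others][sort][:, s])
                 for s in range(vals.shape[1])]
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                rows[qid] = vals[j] / trend * grand_median
    out = pd.DataFrame.from_dict(rows, orient="index", columns=areas.columns)
    return out.loc[[i for i in qc_ids if i in out.index]]


def compute_cv(values) -> float:
    """Percent coefficient of variation, ``100 × sd / mean`` with the sample
    (n−1) standard deviation; NaN (species rejected) if fewer than two values
    or a non-positive mean."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m <= 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / m)


def dilution_linearity(areas, dilution_factors=DEFAULT_DILUTION_FACTORS) -> float:
    """R² of ordinary least squares of log(area) on log(1/DF).

    Points with missing or non-positive area (signal below detection at high
    dilution) are dropped before the fit; fewer than four usable points
    leaves the species without a defined R² (NaN → rejected).
    """
    a = np.asarray(areas, dtype=float)
    df = np.asarray(dilution_factors, dtype=float)
    if a.shape != df.shape:
        raise ValueError("areas and dilution factors must align")
    ok = np.isfinite(a) & (a > 0)
    if ok.sum() < MIN_DILUTION_POINTS:
        return float("nan")
    la = np.log(a[ok])
    if np.ptp(la) == 0:  # flat signal: no concentration dependence at all
        return 0.0
    res = stats.linregress(np.log(1.0 / df[ok]), la)
    return float(res.rvalue**2)


def qc_metrics(
    areas: pd.DataFrame,
    sequence: pd.DataFrame,
    dilution_areas: pd.DataFrame | None = None,
    cv_threshold: float = CV_THRESHOLD,
    r2_threshold: float = R2_THRESHOLD,
) -> pd.DataFrame:
    """Per-species admission metrics: pooled-QC CV after drift correction
    (leave-one-out trend, see :func:`loo_qc_corrected`) and dilution-series
    R².

    ``areas`` are the uncorrected responses (or concentrations) of study and
    QC injections.  ``dilution_areas`` is a DF × species frame indexed by
    dilution factor (raw areas of the serial dilution injections); if
    omitted the R² gate is skipped (treated as passing, flagged NaN).
    """
    seq = sequence.set_index("injection_id")
    qc_ids = [i for i in areas.index if seq.loc[i, "role"] == "pooled_qc"]
    if len(qc_ids) < 2:
        raise ValueError("need at least two pooled QC injections for CV")
    qc_corrected = loo_qc_corrected(areas, sequence)
    rows = []
    for sp in areas.columns:
        cv = compute_cv(qc_corrected[sp])
        if dilution_areas is not None and sp in dilution_areas.columns:
            r2 = dilution_linearity(
                dilution_areas[sp].to_numpy(), dilution_areas.index.to_numpy(dtype=float)
            )
            r2_ok = bool(np.isfinite(r2) and r2 > r2_threshold)
        else:
            r2, r2_ok = float("nan"), True
        cv_ok = bool(np.isfinite(cv) and cv < cv_threshold)
        reasons = [] if cv_ok else ["cv"]
        if not r2_ok:
            reasons.append("r2")
        rows.append(
            {
                "species": sp,
                "cv_percent": cv,
                "dilution_r2": r2,
                "accepted": cv_ok and r2_ok,
                "reject_reason": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def filter_species(metrics: pd.DataFrame) -> tuple[list[str], pd.DataFrame]:
    """Split QC metrics into the accepted species list and an audit frame of
    rejections (species, metrics, reasons)."""
    accepted = metrics.loc[metrics["accepted"], "species"].tolist()
    audit = metrics.loc[~metrics["accepted"]].reset_index(drop=True)
    return accepted, audit
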
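"""Random-effects meta-analysis of per-dataset differential-expression
effects for sphingolipid-pathway genes.

Per-study effects (log2 fold change ± SE, or a 95% CI convertible to an SE)
are pooled per gene with the DerSimonian–Laird moment estimator of the
between-study variance τ²; heterogeneity is summarised by Cochran's Q and
I².  A REML estimate of τ² is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "StudyEffect",
    "PooledEffect",
    "effect_from_group_stats",
    "se_from_ci",
    "dl_pool",
    "pool_genes",
    "forest_table",
    "LYSOSOMAL_GENES",
    "SYNTHESIS_GENES",
    "DEFAULT_GENES",
]

_Z95 = 1.959963984540054

#: genes of the lysosomal GSL-degradation arm
LYSOSOMAL_GENES = ["GBA1", "GLB1", "GLA", "NEU1", "NEU3", "NEU4", "HEXA", "HEXB", "GM2A"]
#: genes of the de novo ceramide-synthesis arm
SYNTHESIS_GENES = [
    "SPTLC1", "SPTLC2", "SPTLC3", "SPTSSA", "SPTSSB", "KDSR",
    "CERS1", "CERS2", "CERS3", "CERS4", "CERS5", "CERS6",
    "DEGS1", "DEGS2", "FADS3",
]
DEFAULT_GENES = LYSOSOMAL_GENES + SYNTHESIS_GENES


@dataclass(frozen=True)
class StudyEffect:
    dataset_id: str
    gene: str
    log2fc: float
    se: float
    n_case: int | None = None
    n_control: int | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("SE must be positive")


@dataclass(frozen=True)
class PooledEffect:
    gene: str
    k: int
    log2fc: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    q: float
    i2: float

    def __post_init__(self) -> None:
        if self.k < 1 or self.tau2 < 0 or not 0 <= self.i2 <= 100:
            raise ValueError("invalid pooled effect")
        if not (self.ci_low <= self.log2fc <= self.ci_high):
            raise ValueError("CI must contain the pooled estimate")


def effect_from_group_stats(
    mean_case: float, sd_case: float, n_case: int,
    mean_ctrl: float, sd_ctrl: float, n_ctrl: int,
    gene: str = "", dataset_id: str = "",
) -> StudyEffect:
    """Study effect from group summary statistics on the log2 expression
    scale: difference of means with the unpooled (Welch) standard error."""
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need at least two samples per group")
    if sd_case <= 0 or sd_ctrl <= 0:
        raise ValueError("group SDs must be positive")
    se = float(np.sqrt(sd_case**2 / n_case + sd_ctrl**2 / n_ctrl))
    return StudyEffect(dataset_id, gene, float(mean_case - mean_ctrl), se, n_case, n_ctrl)


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """SE from a symmetric normal 95% CI: (upper − lower) / (2 × 1.959964)."""
    if ci_high <= ci_low:
        raise ValueError("upper CI bound must exceed the lower")
    return float((ci_high - ci_low) / (2.0 * _Z95))


def _tau2_reml(y: np.ndarray, v: np.ndarray) -> float:
    def neg_restricted_ll(tau2):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, 100.0), method="bounded")
    return float(res.x)


def dl_pool(effects, method: str = "DL") -> PooledEffect:
    """Pool study effects for one gene under the random-effects model.

    DerSimonian–Laird by default: with fixed-effect weights w = 1/SE²,
    Q = Σw(y − ŷ)², τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)); random-effects
    weights are 1/(SE² + τ²), the pooled CI is Wald-normal, and
    I² = max(0, (Q − (k−1))/Q) × 100.  ``method="REML"`` replaces the τ²
    moment estimate by restricted maximum likelihood.
    """
    effects = list(effects)
    if len(effects) == 0:
        raise ValueError("no study effects to pool")
    genes = {e.gene for e in effects}
    if len(genes) > 1:
        raise ValueError(f"effects mix genes: {sorted(genes)}")
    y = np.array([e.log2fc for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all SEs must be positive")
    k = y.size
    v = se**2
    w = 1.0 / v
    yhat = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - yhat) ** 2))
    if k == 1:
        tau2, i2 = 0.0, 0.0
    elif method == "DL":
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    elif method == "REML":
        tau2 = _tau2_reml(y, v)
        i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    w_re = 1.0 / (v + tau2)
    pooled = float(np.sum(w_re * y) / np.sum(w_re))
    se_pooled = float(np.sqrt(1.0 / np.sum(w_re)))
    z = pooled / se_pooled
    return PooledEffect(
        gene=effects[0].gene,
        k=k,
        log2fc=pooled,
        se=se_pooled,
        ci_low=pooled - _Z95 * se_pooled,
        ci_high=pooled + _Z95 * se_pooled,
        p=float(2 * stats.norm.sf(abs(z))),
        tau2=float(tau2),
        q=q,
        i2=float(i2),
    )


def _effects_from_frame(df: pd.DataFrame) -> list[StudyEffect]:
    effects = []
    for _, row in df.iterrows():
        if "se" in df.columns and np.isfinite(row.get("se", np.nan)):
            se = float(row["se"])
        elif {"ci_low", "ci_high"} <= set(df.columns):
            se = se_from_ci(float(row["ci_low"]), float(row["ci_high"]))
        else:
            raise ValueError("study table needs an 'se' column or ci_low/ci_high")
        effects.append(
            StudyEffect(
                str(row.get("dataset_id", "")),
                str(row["gene"]),
                float(row["log2fc"]),
                se,
                int(row["n_case"]) if "n_case" in df.columns else None,
                int(row["n_control"]) if "n_control" in df.columns else None,
            )
        )
    return effects


def pool_genes(studies: pd.DataFrame, genes: list[str] | None = None, method: str = "DL") -> pd.DataFrame:
    """Pool a long study table (dataset_id, gene, log2fc, se|ci) per gene.

    Returns a frame indexed by gene with k, pooled log2fc, CI, p, τ², Q, I².
    """
    rows = []
    for gene, sub in studies.groupby("gene"):
        if genes is not None and gene not in genes:
            continue
        pe = dl_pool(_effects_from_frame(sub), method=method)
        rows.append(
            {
                "gene": gene, "k": pe.k, "log2fc": pe.log2fc, "se": pe.se,
                "ci_low": pe.ci_low, "ci_high": pe.ci_high, "p": pe.p,
                "tau2": pe.tau2, "Q": pe.q, "I2": pe.i2,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def forest_table(effects, pooled: PooledEffect | None = None, method: str = "DL") -> pd.DataFrame:
    """Per-study forest rows (estimate, CI, weight %) followed by the pooled
    row; random-effects weights sum to 100%."""
    effects = list(effects)
    if pooled is None:
        pooled = dl_pool(effects, method=method)
    v = np.array([e.se**2 for e in effects])
    w = 1.0 / (v + pooled.tau2)
    w = 100.0 * w / w.sum()
    rows = [
        {
            "row": e.dataset_id or f"study {i + 1}",
            "log2fc": e.log2fc,
            "ci_low": e.log2fc - _Z95 * e.se,
            "ci_high": e.log2fc + _Z95 * e.se,
            "weight_pct": float(w[i]),
        }
        for i, e in enumerate(effects)
    ]
    rows.append(
        {
            "row": f"pooled ({method}, k={pooled.k})",
            "log2fc": pooled.log2fc,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
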
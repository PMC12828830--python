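"""DerSimonian–Laird pooling, heterogeneity and forest output."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import sphingoquant as sq
from sphingoquant.meta import (
    PooledEffect,
    StudyEffect,
    dl_pool,
    effect_from_group_stats,
    forest_table,
    pool_genes,
    se_from_ci,
)


def test_effect_from_group_stats():
    e = effect_from_group_stats(5.0, 1.0, 20, 4.5, 1.0, 20, gene="G")
    assert e.log2fc == pytest.approx(0.5)
    assert e.se == pytest.approx(np.sqrt(0.1), abs=1e-12)
    e4 = effect_from_group_stats(5.0, 1.0, 80, 4.5, 1.0, 80, gene="G")
    assert e4.se == pytest.approx(e.se / 2.0, abs=1e-12)
    with pytest.raises(ValueError):
        effect_from_group_stats(5.0, 0.0, 20, 4.5, 1.0, 20)


def test_se_from_ci_inverts_wald_interval():
    assert se_from_ci(-0.71, -0.24) == pytest.approx((0.71 - 0.24) / (2 * 1.959964), abs=1e-6)
    with pytest.raises(ValueError):
        se_from_ci(0.5, 0.5)


def test_two_study_hand_walkthrough():
    """Hand-executed DL formulas: w=100 each, Q=8, tau2=7/100, RE SE=0.2."""
    effects = [StudyEffect("a", "G", 0.2, 0.1), StudyEffect("b", "G", 0.6, 0.1)]
    p = dl_pool(effects)
    assert p.q == pytest.approx(8.0, abs=1e-12)
    assert p.tau2 == pytest.approx(0.07, abs=1e-12)
    assert p.log2fc == pytest.approx(0.4, abs=1e-12)
    assert p.se == pytest.approx(0.2, abs=1e-12)
    assert p.ci_low == pytest.approx(0.4 - 1.959964 * 0.2, abs=1e-5)
    assert p.i2 == pytest.approx(87.5, abs=1e-9)


def test_single_study_identity():
    p = dl_pool([StudyEffect("a", "G", -0.3, 0.12)])
    assert p.log2fc == pytest.approx(-0.3)
    assert p.se == pytest.approx(0.12)
    assert p.tau2 == 0.0 and p.i2 == 0.0 and p.k == 1


def test_identical_studies_no_heterogeneity():
    effects = [StudyEffect(f"s{i}", "G", 0.25, 0.1) for i in range(5)]
    p = dl_pool(effects)
    assert p.log2fc == pytest.approx(0.25)
    assert p.q == pytest.approx(0.0, abs=1e-12)
    assert p.tau2 == 0.0


def test_tau_zero_equals_fixed_effect_pool():
    rng = np.random.default_rng(8)
    se = rng.uniform(0.05, 0.3, 6)
    y = rng.normal(0.1, 0.01, 6)  # tiny spread -> Q < k-1 -> tau2 = 0
    effects = [StudyEffect(f"s{i}", "G", y[i], se[i]) for i in range(6)]
    p = dl_pool(effects)
    assert p.tau2 == 0.0
    w = 1 / se**2
    assert p.log2fc == pytest.approx(float(np.sum(w * y) / np.sum(w)), abs=1e-12)


def test_pooling_permutation_invariant():
    rng = np.random.default_rng(9)
    effects = [StudyEffect(f"s{i}", "G", rng.normal(), rng.uniform(0.1, 0.5)) for i in range(10)]
    p1 = dl_pool(effects)
    p2 = dl_pool(effects[::-1])
    assert p1.log2fc == pytest.approx(p2.log2fc, abs=1e-12)
    assert p1.tau2 == pytest.approx(p2.tau2, abs=1e-12)


def test_mixed_gene_input_rejected():
    with pytest.raises(ValueError, match="mix"):
        dl_pool([StudyEffect("a", "G1", 0.1, 0.1), StudyEffect("b", "G2", 0.1, 0.1)])
    with pytest.raises(ValueError):
        dl_pool([])


def test_against_metafor_reference():
    """Independent oracle: R metafor rma(method='DL') on a fixed study set."""
    rng = np.random.default_rng(14)
    y = np.round(rng.normal(-0.4, 0.3, 8), 4)
    se = np.round(rng.uniform(0.1, 0.4, 8), 4)
    p = dl_pool([StudyEffect(f"s{i}", "G", y[i], se[i]) for i in range(8)])
    script = (
        "suppressMessages(library(metafor));"
        f"r <- rma(yi=c({','.join(map(str, y))}), sei=c({','.join(map(str, se))}), method='DL');"
        "cat(sprintf('%.12f', c(r$b, r$se, r$tau2, r$QE)))"
    )
    try:
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120, check=True
        )
    except (FileNotFoundError, subprocess.SubprocessError):
        pytest.skip("Rscript/metafor unavailable")
    b, se_r, tau2, q = map(float, out.stdout.split())
    assert p.log2fc == pytest.approx(b, abs=1e-6)
    assert p.se == pytest.approx(se_r, abs=1e-6)
    assert p.tau2 == pytest.approx(tau2, abs=1e-6)
    assert p.q == pytest.approx(q, abs=1e-6)


def test_reml_close_to_dl_on_wellbehaved_data():
    rng = np.random.default_rng(15)
    effects = [
        StudyEffect(f"s{i}", "G", rng.normal(-0.4, 0.2), rng.uniform(0.15, 0.3))
        for i in range(18)
    ]
    dl = dl_pool(effects, method="DL")
    reml = dl_pool(effects, method="REML")
    assert reml.log2fc == pytest.approx(dl.log2fc, abs=0.05)
    assert reml.tau2 >= 0


def test_forest_weights_sum_to_100():
    rng = np.random.default_rng(16)
    effects = [StudyEffect(f"s{i}", "G", rng.normal(), rng.uniform(0.1, 0.5)) for i in range(7)]
    f = forest_table(effects)
    assert f["weight_pct"].iloc[:-1].sum() == pytest.approx(100.0, abs=1e-9)
    single = forest_table([StudyEffect("only", "G", 0.1, 0.2)])
    assert single["weight_pct"].iloc[0] == pytest.approx(100.0)


def test_pool_genes_recovers_generator_truth():
    cfg = sq.GeneratorConfig(seed=3)
    studies, truth = sq.generate_meta_studies(cfg)
    pooled = pool_genes(studies)
    assert (pooled["k"] == 18).all()
    for gene in ("GLA", "GBA1", "KDSR"):
        mu = truth["genes"][gene]["true_effect"]
        row = pooled.loc[gene]
        assert row["ci_low"] - 0.1 < mu < row["ci_high"] + 0.1
    # strong negative effect detected as such
    assert pooled.loc["GLA", "log2fc"] < 0 and pooled.loc["GLA", "p"] < 0.01


def test_coverage_simulation():
    """95% Wald CI of the DL pool covers the true effect at ~nominal rate."""
    cover = 0
    reps = 150
    for seed in range(reps):
        cfg = sq.GeneratorConfig(seed=seed)
        studies, _ = sq.generate_meta_studies(cfg, genes={"G": -0.45})
        effects = [
            StudyEffect(r.dataset_id, "G", r.log2fc, r.se) for r in studies.itertuples()
        ]
        p = dl_pool(effects)
        cover += p.ci_low <= -0.45 <= p.ci_high
    assert 0.90 <= cover / reps <= 0.99
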
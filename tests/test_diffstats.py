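"""Case-control statistics: tests, FDR, aggregation, ratios, ROC, regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import sphingoquant as sq
from sphingoquant.diffstats import (
    RatioDefinition,
    aggregate,
    auc_mann_whitney,
    benjamini_hochberg,
    chain_distribution,
    clinical_table,
    compute_ratio,
    compute_ratios,
    logistic_adjusted_or,
    roc_models,
    severity_association,
    species_tests,
)
from sphingoquant.tables import ConcentrationTable


from oracles import bh_oracle, fisher_enum


def test_bh_hand_example():
    np.testing.assert_allclose(
        benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(benjamini_hochberg([0.37]), [0.37])


def test_bh_agrees_with_stepup_oracle_on_random_vectors():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = rng.integers(1, 11)
        p = rng.uniform(size=n)
        np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p), atol=1e-12)


def test_bh_dominates_raw_p():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=50)
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


def _toy_table(a, b, species="X"):
    n1, n2 = len(a), len(b)
    samples = pd.DataFrame(
        {"group": ["PD"] * n1 + ["control"] * n2},
        index=[f"s{i}" for i in range(n1 + n2)],
    )
    conc = pd.DataFrame({species: list(a) + list(b)}, index=samples.index)
    return ConcentrationTable(samples, conc)


def test_welch_t_matches_closed_form():
    rng = np.random.default_rng(0)
    a = rng.lognormal(3.0, 0.4, 30)
    b = rng.lognormal(2.8, 0.6, 25)
    res = species_tests(_toy_table(a, b))
    la, lb = np.log(a), np.log(b)
    se = np.sqrt(la.var(ddof=1) / 30 + lb.var(ddof=1) / 25)
    t_oracle = (la.mean() - lb.mean()) / se
    assert res["t"].iloc[0] == pytest.approx(t_oracle, abs=1e-10)
    assert res["log2fc"].iloc[0] == pytest.approx((la.mean() - lb.mean()) / np.log(2), abs=1e-12)


def test_identical_groups_give_t_zero_p_one():
    vals = np.array([2.0, 3.0, 4.0, 5.0])
    res = species_tests(_toy_table(vals, vals))
    assert res["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert res["p"].iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_aggregate_linearity_and_partition(small_cohort):
    table, _ = small_cohort
    total_all = table.concentrations.sum(axis=1)
    parts = []
    for sub in ["Cer", "DHS-Cer", "PHS-Cer", "HexCer", "Hex2Cer", "Hex3Cer",
                "HexNAcHex3Cer", "GM3"]:
        parts.append(aggregate(table, subclasses=(sub,))["total"])
    np.testing.assert_allclose(sum(parts).to_numpy(), total_all.to_numpy(), rtol=1e-12)

    sel = aggregate(table, subclasses=("HexCer",), spb_classes=("C18-SPH/D",), acyl_classes=("C24",))
    sp = sel.attrs["species"][0]
    doubled = ConcentrationTable(
        table.samples, table.concentrations.assign(**{sp: table.concentrations[sp] * 2})
    )
    sel2 = aggregate(doubled, subclasses=("HexCer",), spb_classes=("C18-SPH/D",), acyl_classes=("C24",))
    np.testing.assert_allclose(
        (sel2["total"] - sel["total"]).to_numpy(), table.concentrations[sp].to_numpy(), rtol=1e-9
    )
    with pytest.raises(ValueError, match="matches no species"):
        aggregate(table, subclasses=("Cer",), spb_classes=("C14-PHS",))


def test_chain_distribution_normalisation(small_cohort):
    table, _ = small_cohort
    props, tests = chain_distribution(table)
    sums = props.sum(axis=1)
    np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)
    assert set(tests.columns) >= {"p", "p_adj"}


def test_chain_distribution_detects_designed_redistribution():
    cfg = sq.GeneratorConfig(seed=31, n_per_group=250)
    table, _ = sq.generate_cohort(cfg)
    _, tests = chain_distribution(table)
    assert tests.loc["C22", "p_adj"] < 0.05 and tests.loc["C22", "t"] < 0
    assert tests.loc["C24", "t"] > 0


def test_ratio_scale_invariance_and_identity(small_cohort):
    table, _ = small_cohort
    defs = sq.default_ratio_definitions(table.species)
    scaled = ConcentrationTable(table.samples, table.concentrations * 3.7)
    r1, _ = compute_ratio(table, defs[0])
    r2, _ = compute_ratio(scaled, defs[0])
    np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), rtol=1e-12)
    with pytest.raises(ValueError, match="disjoint"):
        RatioDefinition("x", ("a", "b"), ("b", "c"))


def test_elevated_numerator_ratio_detected_at_study_scale():
    panel = sq.generate_panel()
    effects = {
        n: 1.10
        for n in panel.loc[panel["head_class"] == "HexCer", "name"]
    }
    cfg = sq.GeneratorConfig(seed=17, n_per_group=250, effect_map=effects)
    table, _ = sq.generate_cohort(cfg)
    _, tests = compute_ratios(table)
    row = tests.loc["HexCer/Cer"]
    assert row["log2fc"] > 0 and row["p_adj"] < 0.01


def test_auc_brute_force_example():
    # all four case-control pairs, ties counting 1/2
    assert auc_mann_whitney([2, 3], [1, 2]) == pytest.approx(0.875)
    assert auc_mann_whitney([5, 6], [1, 2]) == pytest.approx(1.0)


def test_auc_equals_trapezoidal_roc_integral():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(7)
    for _ in range(25):
        n1, n0 = rng.integers(5, 40, size=2)
        scores = np.concatenate([rng.normal(0.5, 1, n1), rng.normal(0, 1, n0)])
        scores = np.round(scores, 1)  # force ties
        labels = np.r_[np.ones(n1), np.zeros(n0)]
        mine = auc_mann_whitney(scores[: n1], scores[n1:])
        assert mine == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_roc_models_on_designed_cohort():
    cfg = sq.GeneratorConfig(seed=13, n_per_group=250)
    table, _ = sq.generate_cohort(cfg)
    res = roc_models(table, n_boot=200, seed=0)
    assert res["basic"].auc < 0.62  # demographics carry no signal
    assert res["full"].auc > res["basic"].auc
    assert res["full"].ci_low <= res["full"].auc <= res["full"].ci_high


def test_logistic_or_consistency_large_n():
    rng = np.random.default_rng(1)
    n = 20000
    x = rng.normal(size=n)
    age = rng.normal(67, 7, n)
    logit = np.log(2.0) * x + 0.0 * age
    y = rng.uniform(size=n) < 1 / (1 + np.exp(-logit))
    res = logistic_adjusted_or(y.astype(int), x, pd.DataFrame({"age": age}))
    assert res.odds_ratio == pytest.approx(2.0, rel=0.05)
    assert res.ci_low < 2.0 < res.ci_high


def test_logistic_or_null_coverage():
    rng = np.random.default_rng(2)
    hits = 0
    reps = 200
    for _ in range(reps):
        x = rng.normal(size=400)
        y = rng.integers(0, 2, size=400)
        res = logistic_adjusted_or(y, x)
        hits += res.ci_low <= 1.0 <= res.ci_high
    assert hits / reps == pytest.approx(0.95, abs=0.04)


def test_logistic_degenerate_exposure_errors():
    with pytest.raises(ValueError, match="constant"):
        logistic_adjusted_or([0, 1, 0, 1], [1.0, 1.0, 1.0, 1.0])


def test_severity_regression_recovers_slope():
    cfg = sq.GeneratorConfig(seed=19, n_per_group=120)
    table, _ = sq.generate_cohort(cfg)
    rng = np.random.default_rng(4)
    pd_mask = table.group_mask("PD")
    sp = table.species[0]
    true_slope = 5.0
    outcome = true_slope * np.log(table.concentrations.loc[pd_mask, sp]) + rng.normal(
        0, 2.0, int(pd_mask.sum())
    )
    table.samples.loc[pd_mask, "updrs3"] = outcome.to_numpy()
    res = severity_association(table, "updrs3")
    row = res.loc[sp]
    assert row["ci_low"] < true_slope < row["ci_high"]
    assert row["p_adj"] < 0.01


def test_severity_regression_null_covers_zero():
    cfg = sq.GeneratorConfig(seed=23, n_per_group=80)
    table, _ = sq.generate_cohort(cfg)
    res = severity_association(table, "updrs3")  # outcome independent of lipids
    frac_cover = ((res["ci_low"] < 0) & (res["ci_high"] > 0)).mean()
    assert frac_cover > 0.90


def test_clinical_table_counts_and_fisher_oracle(small_cohort):
    table, _ = small_cohort
    tab = clinical_table(table.samples)
    female = tab[tab["variable"].str.startswith("Female")].iloc[0]
    n_f = int((table.samples.loc[table.group_mask("control"), "sex"] == "F").sum())
    n = int(table.group_mask("control").sum())
    assert f"{n_f} ({100 * n_f / n:.1f})" == female["control"]
    # Fisher p equals the exact hypergeometric enumeration
    a, b, c, d = 7, 3, 2, 8
    _, p_scipy = sps.fisher_exact([[a, b], [c, d]])
    p_enum = fisher_enum(a, b, c, d)
    assert p_scipy == pytest.approx(p_enum, abs=1e-12)




def test_null_fdr_control_across_replicates():
    """Realised false-discovery proportion under the global null stays small."""
    panel = sq.generate_panel()
    any_rejection = 0
    reps = 50
    for seed in range(reps):
        cfg = sq.GeneratorConfig(seed=1000 + seed, n_per_group=100, effect_map={})
        table, _ = sq.generate_cohort(cfg, panel)
        res = species_tests(table)
        any_rejection += (res["p_adj"] < 0.01).any()
    assert any_rejection / reps <= 0.05


def test_designed_effects_recovered_in_direction():
    """Strong designed effects are detected with the right sign; nulls stay quiet."""
    panel = sq.generate_panel()
    eff = sq.default_effect_map(panel)
    strong = {n for n, e in eff.items() if abs(np.log(e)) >= abs(np.log(0.88))}
    cfg = sq.GeneratorConfig(seed=77, n_per_group=250)
    table, _ = sq.generate_cohort(cfg, panel)
    res = species_tests(table)
    sig = res[res["p_adj"] < 0.01]
    # every significant species is a designed one, with the designed direction
    for name in sig.index:
        assert name in eff
        assert np.sign(sig.loc[name, "log2fc"]) == np.sign(np.log(eff[name]))
    # strong effects are essentially always found at this sample size
    assert len(strong - set(sig.index)) <= max(1, len(strong) // 10)
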
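"""Generator contracts: panel composition, determinism, run structure."""

import numpy as np
import pandas as pd
import pytest

import sphingoquant as sq
from sphingoquant.nomenclature import parse_species_name, subclass_label


def test_default_panel_size_and_parseability(panel):
    assert len(panel) == 119
    assert panel["name"].is_unique
    for name in panel["name"]:
        parse_species_name(name)  # must not raise


def test_panel_covers_all_subclasses(panel):
    subs = {subclass_label(parse_species_name(n)) for n in panel["name"]}
    assert subs >= {"Cer", "DHS-Cer", "PHS-Cer", "HexCer", "Hex2Cer", "Hex3Cer",
                    "HexNAcHex3Cer", "GM3"}
    bases = set(panel["spb"])
    assert {"C16-SPH", "C17-SPH", "C18-SPH", "C18-SPD", "C18-DHS", "C18-PHS", "C19-SPH"} <= bases


def test_panel_determinism_and_stratified_subsets():
    p1 = sq.generate_panel(sq.GeneratorConfig(seed=1))
    p2 = sq.generate_panel(sq.GeneratorConfig(seed=99))
    pd.testing.assert_frame_equal(p1, p2)  # panel is design, not randomness
    small = sq.generate_panel(sq.GeneratorConfig(panel_size=40))
    assert len(small) == 40
    subs = {subclass_label(parse_species_name(n)) for n in small["name"]}
    assert len(subs) >= 6


def test_cohort_shapes_and_determinism():
    cfg = sq.GeneratorConfig(seed=4, n_per_group=25)
    t1, truth1 = sq.generate_cohort(cfg)
    t2, _ = sq.generate_cohort(cfg)
    assert len(t1.samples) == 50
    pd.testing.assert_frame_equal(t1.concentrations, t2.concentrations)
    pd.testing.assert_frame_equal(t1.samples, t2.samples)
    assert set(t1.samples["group"]) == {"PD", "control"}
    assert (t1.concentrations.to_numpy() > 0).all()


def test_null_effect_map_gives_exchangeable_groups():
    cfg = sq.GeneratorConfig(seed=6, n_per_group=150, effect_map={})
    table, truth = sq.generate_cohort(cfg)
    assert truth["effects"] == {}
    res = sq.species_tests(table)
    # p-values approximately uniform: mean near 0.5, no mass pile-up
    assert abs(res["p"].mean() - 0.5) < 0.06
    assert (res["p_adj"] < 0.01).sum() == 0


def test_default_effects_move_anchored_ratio():
    """PD/control ratio of the C24 C18-SPH/D HexCer total lands near the
    designed 9% elevation."""
    ratios = []
    for seed in range(5):
        cfg = sq.GeneratorConfig(seed=seed, n_per_group=250)
        table, _ = sq.generate_cohort(cfg)
        agg = sq.aggregate(table, subclasses=("HexCer",), spb_classes=("C18-SPH/D",),
                           acyl_classes=("C24",))
        r = (agg.loc[table.group_mask("PD"), "total"].mean()
             / agg.loc[table.group_mask("control"), "total"].mean())
        ratios.append(r)
    assert 1.05 <= np.mean(ratios) <= 1.13


def test_qc_cadence_in_manifest(small_cohort):
    table, _ = small_cohort
    cfg = sq.GeneratorConfig(seed=11, n_per_group=40)
    peaks, seq, lib, _ = sq.generate_injection_run(table, cfg)
    for b, sub in seq.groupby("batch"):
        sub = sub.sort_values("order")
        roles = sub["role"].tolist()
        assert roles[0] == "pooled_qc"
        # a pooled QC after every 10 study injections
        study_count = 0
        for role in roles:
            if role == "study":
                study_count += 1
                assert study_count <= cfg.qc_interval
            elif role == "pooled_qc":
                study_count = 0
        assert (np.diff(sub["order"]) > 0).all()


def test_dilution_series_monotone_when_noise_free(clean_run):
    _, peaks, seq, lib, _ = clean_run
    dil = seq[seq["role"] == "dilution_qc"].sort_values("dilution_factor")
    assert list(dil["dilution_factor"]) == [1, 2, 5, 10, 20, 50, 100, 200, 500,
                                            1000, 2000, 5000, 10000]
    merged = peaks.merge(dil[["injection_id", "dilution_factor"]], on="injection_id")
    wide = merged.pivot_table(index="dilution_factor", columns="product_mz", values="area",
                              aggfunc="sum").sort_index()
    assert (wide.diff().dropna() < 0).all().all()


def test_injection_run_determinism():
    cfg = sq.GeneratorConfig(seed=8, n_per_group=8)
    table, _ = sq.generate_cohort(cfg)
    p1, s1, l1, _ = sq.generate_injection_run(table, cfg)
    p2, s2, l2, _ = sq.generate_injection_run(table, cfg)
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(s1, s2)


def test_meta_studies_determinism_and_truth():
    cfg = sq.GeneratorConfig(seed=12)
    s1, t1 = sq.generate_meta_studies(cfg)
    s2, _ = sq.generate_meta_studies(cfg)
    pd.testing.assert_frame_equal(s1, s2)
    assert s1["dataset_id"].nunique() == 18
    assert (s1["se"] > 0).all()
    assert set(t1["genes"]) == set(sq.synthetic.DEFAULT_GENE_EFFECTS)


def test_zero_tau_observed_variance_matches_se():
    """With no heterogeneity the spread of observed effects matches the SEs."""
    diffs = []
    for seed in range(40):
        cfg = sq.GeneratorConfig(seed=seed, meta_tau=0.0)
        studies, _ = sq.generate_meta_studies(cfg, genes={"G": 0.0})
        z = studies["log2fc"] / studies["se"]
        diffs.append(z.var(ddof=1))
    assert np.mean(diffs) == pytest.approx(1.0, abs=0.15)


def test_config_validation():
    with pytest.raises(ValueError):
        sq.GeneratorConfig(qc_interval=1)
    with pytest.raises(ValueError):
        sq.GeneratorConfig(species_cv=0.0)
    with pytest.raises(ValueError):
        sq.GeneratorConfig(effect_map={"Cer 18:1;O2/24:0": -1.0})


def test_table_csv_roundtrip(tmp_path, small_cohort):
    table, _ = small_cohort
    path = tmp_path / "conc.csv"
    table.to_csv(path)
    back = sq.ConcentrationTable.from_csv(path)
    pd.testing.assert_frame_equal(back.concentrations, table.concentrations)
    assert list(back.samples["group"]) == list(table.samples["group"])
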
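"""Synthetic data generator for the whole pipeline.

Emulates a two-group (PD vs control) plasma sphingolipidomics study:

* a 119-species panel spanning ceramide and glycosphingolipid subclasses
  with diverse sphingoid bases and acyl chains;
* log-normal plasma concentrations whose control-group subclass totals are
  anchored to study-scale values (e.g. the C24, C18-SPH/D HexCer total near
  5.7 µM) and whose default PD effects encode the qualitative findings the
  statistics modules are meant to recover (GSLs up ~9%, dihydroceramides
  down, noncanonical-base ceramides down, a C22→C24 acyl redistribution);
* raw MRM injection runs with batch structure, smooth multiplicative
  intensity drift, pooled QCs at a fixed cadence, a 13-point serial dilution
  series and internal-standard peaks;
* multi-study gene-expression effect sets with between-study variance for
  the meta-analysis module.

Every draw flows from the single config seed; equal configs give identical
output.  Ground truth (true means, effects, drift, study effects) is
returned alongside so tests can verify downstream estimates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import annotation
from .nomenclature import (
    SphingolipidSpecies,
    classify_acyl,
    classify_spb,
    parse_species_name,
    subclass_label,
)
from .quantify import DEFAULT_INTERNAL_STANDARDS, InternalStandard, assign_quant_level
from .tables import ConcentrationTable

__all__ = [
    "GeneratorConfig",
    "generate_panel",
    "default_effect_map",
    "baseline_means",
    "generate_cohort",
    "generate_injection_run",
    "generate_meta_studies",
    "internal_standard_transitions",
    "DEFAULT_GENE_EFFECTS",
    "SUBCLASS_ANCHORS_NM",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs; defaults reproduce the emulated study conditions."""

    seed: int = 0
    n_per_group: int = 250
    panel_size: int = 119
    species_cv: float = 0.30
    effect_map: dict | None = None  # species name -> PD multiplier; None = defaults
    n_batches: int = 2
    drift_amplitude: float = 0.2
    qc_interval: int = 10
    dilution_factors: tuple = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 2000, 5000, 10000)
    noise_cv: float = 0.05
    rf_spread: float = 0.0  # per-species response-factor spread (log-sd); 0 = class-exact
    mz_jitter: float = 0.01
    rt_jitter: float = 0.03
    volume_factor: float = 10.0
    # meta-analysis study sets
    meta_k: int = 18
    meta_tau: float = 0.15
    meta_within_sd: float = 1.0
    meta_total_case: int = 166
    meta_total_control: int = 140
    gene_effects: dict | None = None

    def __post_init__(self) -> None:
        if self.species_cv <= 0 or self.noise_cv < 0:
            raise ValueError("CVs must be positive (noise CV may be 0)")
        if self.qc_interval < 2:
            raise ValueError("QC interval must be >= 2")
        if self.effect_map is not None and any(v <= 0 for v in self.effect_map.values()):
            raise ValueError("effects must be positive multipliers")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


# ---------------------------------------------------------------------------
# panel

_GLYCO_HEADS = ["HexCer", "Hex2Cer", "Hex3Cer", "HexNAcHex3Cer", "GM3"]
_ALL_HEADS = ["Cer"] + _GLYCO_HEADS


def _species(cls: str, bc: int, bdb: int, boh: int, ac: int, adb: int, aoh: int = 0) -> str:
    from .nomenclature import AcylChain, HeadGroup, SphingoidBase

    return SphingolipidSpecies(
        HeadGroup(cls), SphingoidBase(bc, bdb, boh), AcylChain(ac, adb, aoh)
    ).name


def _full_panel() -> list[str]:
    names: list[str] = []
    core_acyls = [(16, 0), (18, 0), (20, 0), (22, 0), (23, 0), (24, 0), (24, 1), (26, 0)]
    for cls in _ALL_HEADS:  # canonical C18 sphingosine backbone
        for ac, adb in core_acyls:
            names.append(_species(cls, 18, 1, 2, ac, adb))
    for cls in _ALL_HEADS:  # C18 sphingadiene
        for ac, adb in [(16, 0), (22, 0), (24, 0), (24, 1)]:
            names.append(_species(cls, 18, 2, 2, ac, adb))
    for ac, adb in [(16, 0), (18, 0), (20, 0), (22, 0), (24, 0), (24, 1), (26, 0)]:
        names.append(_species("Cer", 18, 0, 2, ac, adb))  # dihydroceramides
    for ac, adb in [(16, 0), (22, 0), (24, 0), (24, 1)]:
        names.append(_species("Cer", 18, 0, 3, ac, adb))  # phytoceramides
    for bc in (16, 17, 19):  # noncanonical sphingosines
        for ac, adb in [(16, 0), (20, 0), (22, 0), (24, 0), (24, 1)]:
            names.append(_species("Cer", bc, 1, 2, ac, adb))
    for cls in ("Hex2Cer", "GM3"):  # C16-SPH glycosphingolipids
        for ac, adb in [(22, 0), (24, 0), (24, 1)]:
            names.append(_species(cls, 16, 1, 2, ac, adb))
    for ac, adb in [(16, 0), (22, 0), (24, 0), (24, 1)]:
        names.append(_species("Cer", 18, 1, 2, ac, adb, aoh=1))  # hydroxy-acyl ceramides
    for ac in (17, 21, 25):  # odd acyl chains
        names.append(_species("Cer", 18, 1, 2, ac, 0))
    for ac, adb in [(18, 1), (20, 1), (22, 1), (26, 1)]:  # monounsaturated acyls
        names.append(_species("Cer", 18, 1, 2, ac, adb))
    names.append(_species("GM3", 18, 1, 2, 22, 1))
    names.append(_species("Cer", 18, 0, 2, 16, 1))  # DHS-Cer 16:1
    names.append(_species("HexCer", 18, 0, 2, 24, 0))  # DHS-base HexCer
    names.append(_species("HexCer", 18, 0, 2, 22, 0))
    assert len(names) == len(set(names))
    return names


def generate_panel(config: GeneratorConfig = GeneratorConfig()) -> pd.DataFrame:
    """Deterministic species panel (default: exactly 119 canonical names).

    Returns the panel frame (name, head_class, spb, acyl, quant_level).
    Smaller panels are stratified subsets preserving subclass coverage.
    """
    names = _full_panel()
    if config.panel_size > len(names):
        raise ValueError(f"panel size {config.panel_size} exceeds the {len(names)}-species design")
    if config.panel_size < len(names):
        by_sub: dict[str, list[str]] = {}
        for n in names:
            by_sub.setdefault(subclass_label(parse_species_name(n)), []).append(n)
        picked: list[str] = []
        pools = list(by_sub.values())
        i = 0
        while len(picked) < config.panel_size:  # round-robin across subclasses
            pool = pools[i % len(pools)]
            if pool:
                picked.append(pool.pop(0))
            i += 1
        names = [n for n in _full_panel() if n in set(picked)]
    rows = []
    for n in names:
        sp = parse_species_name(n)
        rows.append(
            {
                "name": n,
                "head_class": sp.head.class_label,
                "spb": classify_spb(sp),
                "acyl": classify_acyl(sp),
                "quant_level": assign_quant_level(sp),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# concentrations

#: control-group arithmetic-mean anchors (nM) for the C24-acyl, C18-backbone
#: total of each subclass; glyco values follow the emulated study's printed
#: control means, ceramide-side values are chosen at plasma-realistic scale.
SUBCLASS_ANCHORS_NM: dict[str, float] = {
    "Cer": 2800.0,
    "DHS-Cer": 220.0,
    "PHS-Cer": 60.0,
    "HexCer": 5734.3,
    "Hex2Cer": 1600.0,
    "Hex3Cer": 539.2,
    "HexNAcHex3Cer": 150.0,
    "GM3": 2210.5,
}

_ACYL_WEIGHT = {
    (24, 0): 1.0, (24, 1): 0.55, (22, 0): 0.50, (26, 0): 0.18, (23, 0): 0.25,
    (20, 0): 0.12, (18, 0): 0.10, (16, 0): 0.15, (17, 0): 0.05, (21, 0): 0.04,
    (25, 0): 0.06, (18, 1): 0.05, (20, 1): 0.04, (22, 1): 0.06, (26, 1): 0.04,
    (16, 1): 0.05,
}

_BASE_WEIGHT = {
    (18, "SPH"): 1.0, (18, "SPD"): 0.12, (18, "DHS"): 0.08, (18, "PHS"): 0.05,
    (16, "SPH"): 0.05, (17, "SPH"): 0.04, (19, "SPH"): 0.05,
}


def baseline_means(panel: pd.DataFrame) -> pd.Series:
    """Per-species control arithmetic means (nM).

    Within each subclass, species weights follow acyl- and base-abundance
    profiles (C24 dominant, canonical C18-SPH dominant, hydroxylated acyls
    minor); the subclass scale is set so that the C24-acyl total over
    C18-backbone members matches ``SUBCLASS_ANCHORS_NM``.
    """
    weights, subclasses, anchor_member = {}, {}, {}
    for n in panel["name"]:
        sp = parse_species_name(n)
        w = _ACYL_WEIGHT[(sp.acyl.carbons, sp.acyl.double_bonds)]
        w *= _BASE_WEIGHT[(sp.base.carbons, sp.base.kind)]
        if sp.acyl.hydroxyls:
            w *= 0.10
        weights[n] = w
        subclasses[n] = subclass_label(sp)
        # the anchored total: C24 acyl on the subclass's canonical C18 backbone
        # (SPH/SPD for Cer and the glyco classes, the defining base for
        # DHS-/PHS-ceramides)
        backbone_ok = sp.base.carbons == 18 and (
            sp.base.kind in ("SPH", "SPD") or subclasses[n] in ("DHS-Cer", "PHS-Cer")
        )
        anchor_member[n] = sp.acyl.carbons == 24 and backbone_ok and not sp.acyl.hydroxyls
    means = {}
    for sub, anchor in SUBCLASS_ANCHORS_NM.items():
        members = [n for n in weights if subclasses[n] == sub]
        denom = sum(weights[n] for n in members if anchor_member[n])
        scale = anchor / denom if denom > 0 else 0.0
        for n in members:
            means[n] = weights[n] * scale
    return pd.Series(means).reindex(panel["name"].tolist())


def default_effect_map(panel: pd.DataFrame) -> dict[str, float]:
    """Default PD multiplicative effects: canonical-base HexCer/Hex3Cer/GM3
    up 9%, dihydroceramides down 10%, noncanonical-base ceramides down 15%,
    and a C22→C24 redistribution within canonical ceramides."""
    effects: dict[str, float] = {}
    for n in panel["name"]:
        sp = parse_species_name(n)
        sub = subclass_label(sp)
        canonical = sp.base.carbons == 18 and sp.base.kind in ("SPH", "SPD")
        e = 1.0
        if sub in ("HexCer", "Hex3Cer", "GM3") and canonical:
            e = 1.09
        elif sub == "DHS-Cer":
            e = 0.90
        elif sub == "Cer" and sp.base.carbons in (16, 17, 19):
            e = 0.85
        elif sub == "Cer" and canonical:
            e = {20: 1.05, 22: 0.93, 24: 1.03}.get(sp.acyl.carbons, 1.0)
        if e != 1.0:
            effects[n] = e
    return effects


def _clinical_frame(rng: np.random.Generator, n_pd: int, n_ctrl: int) -> pd.DataFrame:
    def sexes(n, frac_female):
        k = int(round(frac_female * n))
        arr = np.array(["F"] * k + ["M"] * (n - k))
        rng.shuffle(arr)
        return arr

    def flags(n, frac):
        k = int(round(frac * n))
        arr = np.zeros(n, dtype=int)
        arr[:k] = 1
        rng.shuffle(arr)
        return arr

    rows = []
    for group, n in (("control", n_ctrl), ("PD", n_pd)):
        pd_grp = group == "PD"
        df = pd.DataFrame(
            {
                "group": group,
                "age": rng.normal(67.4, 7.7 if pd_grp else 7.5, n).round(1),
                "sex": sexes(n, 0.344 if pd_grp else 0.34),
                "bmi": rng.normal(22.7 if pd_grp else 22.6, 1.5, n).round(1),
                "hypertension": flags(n, 0.212 if pd_grp else 0.272),
                "diabetes": flags(n, 0.196 if pd_grp else 0.244),
                "cardiovascular_disease": flags(n, 0.124 if pd_grp else 0.16),
                "cerebrovascular_disease": flags(n, 0.092 if pd_grp else 0.128),
                "constipation": flags(n, 0.52 if pd_grp else 0.412),
                "mmse": np.clip(
                    rng.normal(26.5 if pd_grp else 28.7, 2.7 if pd_grp else 1.8, n), 0, 30
                ).round(0),
                "creatinine": rng.normal(0.92, 0.24 if pd_grp else 0.26, n).round(2),
            }
        )
        if pd_grp:
            df["disease_duration"] = np.clip(rng.normal(7.4, 2.4, n), 0.5, None).round(1)
            df["hy_stage"] = np.clip(rng.normal(3.2, 1.0, n), 1, 5).round(1)
            df["updrs3"] = np.clip(rng.normal(35.0, 9.9, n), 0, None).round(0)
            df["ledd"] = np.clip(rng.normal(649, 206, n), 50, None).round(0)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    return out


def generate_cohort(
    config: GeneratorConfig, panel: pd.DataFrame | None = None
) -> tuple[ConcentrationTable, dict]:
    """Draw per-sample plasma concentrations and a clinical cohort table.

    Concentrations are independent log-normals per species at the configured
    CV, PD means multiplied by the effect map.  Returns the concentration
    table (samples carry group, age, sex, batch, injection order and the
    clinical columns) and the ground-truth record.
    """
    if panel is None:
        panel = generate_panel(config)
    means = baseline_means(panel)
    effects = config.effect_map if config.effect_map is not None else default_effect_map(panel)
    unknown = set(effects) - set(panel["name"])
    if unknown:
        raise ValueError(f"effect map names not in panel: {sorted(unknown)[:5]}")
    n = config.n_per_group
    rng = config.rng(1)
    clin = _clinical_frame(rng, n, n)
    clin.index = [f"S{i:04d}" for i in range(len(clin))]
    clin.index.name = "sample_id"

    sigma = np.sqrt(np.log1p(config.species_cv**2))
    mu = np.log(means.to_numpy()) - sigma**2 / 2.0
    eff = np.array([effects.get(nm, 1.0) for nm in panel["name"]])
    shift = np.where((clin["group"] == "PD").to_numpy()[:, None], np.log(eff)[None, :], 0.0)
    z = rng.standard_normal((len(clin), len(means)))
    conc = np.exp(mu[None, :] + shift + sigma * z)
    conc_df = pd.DataFrame(conc, index=clin.index, columns=panel["name"].tolist())

    # randomized injection order across groups, split into batches
    order = rng.permutation(len(clin))
    per_batch = int(np.ceil(len(clin) / config.n_batches))
    batch = np.empty(len(clin), dtype=int)
    inj_order = np.empty(len(clin), dtype=int)
    for rank, idx in enumerate(order):
        batch[idx] = rank // per_batch + 1
        inj_order[idx] = rank % per_batch
    clin.insert(2, "batch", batch)
    clin.insert(3, "injection_order", inj_order)

    truth = {
        "control_means": means,
        "effects": dict(effects),
        "pd_means": means * eff,
        "sigma_log": float(sigma),
    }
    return ConcentrationTable(clin, conc_df), truth


# ---------------------------------------------------------------------------
# injection runs

_IS_LABEL = re.compile(r"^(?P<core>.+?)-d(?P<n>\d+) \(IS\)$")
_D_MINUS_H = 1.00627675


def internal_standard_transitions(
    standards: list[InternalStandard] = DEFAULT_INTERNAL_STANDARDS,
) -> pd.DataFrame:
    """Library entries for deuterated internal standards (precursor shifted by
    the labelled-hydrogen count)."""
    rows = []
    for std in standards:
        m = _IS_LABEL.match(std.species_name)
        if m is None:
            raise ValueError(f"cannot derive transitions for standard {std.species_name!r}")
        core = parse_species_name(m.group("core"))
        ndeut = int(m.group("n"))
        rows.append(
            {
                "name": std.species_name,
                "adduct": "[M+H]+",
                "precursor_mz": annotation.adduct_mz(annotation.elemental_formula(core))
                + ndeut * _D_MINUS_H,
                "product_mz": annotation.spb_fragment_mz(core),
                "expected_rt": annotation.default_rt_model(core),
            }
        )
    return pd.DataFrame(rows)


_CLASS_RF = {  # area units per nM of extract, per head class
    "Cer": 150.0,
    "HexCer": 110.0,
    "Hex2Cer": 95.0,
    "Hex3Cer": 80.0,
    "HexNAcHex3Cer": 70.0,
    "GM3": 60.0,
}


def generate_injection_run(
    table: ConcentrationTable,
    config: GeneratorConfig,
    standards: list[InternalStandard] = DEFAULT_INTERNAL_STANDARDS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the MRM acquisition of a cohort.

    Study samples are injected in their assigned batch/order with a pooled QC
    at the start, after every ``qc_interval`` study samples, and at the end
    of each batch; the serial dilution series is appended to the last batch.
    Per-injection species areas are extract concentration × class response
    factor × drift(order) × log-normal noise; internal standards are spiked
    at their nominal concentration in every extract.

    Returns ``(peaks, sequence, library, truth)``: a long peak list
    (injection_id, rt, precursor_mz, product_mz, area), the injection
    manifest, the transition library (panel + standards), and ground truth.
    """
    rng = config.rng(2)
    species = table.species
    lib_panel = annotation.build_transition_library(species)
    lib_is = internal_standard_transitions(standards)
    library = pd.concat([lib_panel, lib_is], ignore_index=True)

    # response factors follow the assigned internal standard's class (the
    # level-2/3 working assumption of equal response to the class or
    # surrogate standard), with optional per-species spread to break it
    from .quantify import assign_internal_standard

    rf = np.array(
        [_CLASS_RF[assign_internal_standard(s, standards).head_class] for s in species]
    )
    if config.rf_spread > 0:
        rf = rf * np.exp(rng.normal(0, config.rf_spread, len(rf)))
    rf_is = np.array([_CLASS_RF[std.head_class] for std in standards])
    is_conc = np.array([std.spiked_conc for std in standards])

    # per-species drift modulation, shared by the class standard so that the
    # standard tracks (but does not fully cancel) analyte drift
    mod = rng.uniform(0.6, 1.4, len(species))
    mod_is = rng.uniform(0.6, 1.4, len(standards))

    extract = table.concentrations.to_numpy() / config.volume_factor  # nM in extract
    qc_extract = np.nanmean(extract, axis=0)

    seq_rows, peak_frames = [], []
    truth_drift = {}
    sample_batch = table.samples["batch"]
    sample_order = table.samples["injection_order"]

    def emit(injection_id, role, batch, order, conc_vec, g_study, df=np.nan):
        noise = (
            np.exp(rng.normal(0, np.sqrt(np.log1p(config.noise_cv**2)), len(species) + len(standards)))
            if config.noise_cv > 0
            else np.ones(len(species) + len(standards))
        )
        areas = np.concatenate(
            [conc_vec * rf * g_study[: len(species)], is_conc / (df if np.isfinite(df) else 1.0) * rf_is * g_study[len(species):]]
        ) * noise
        frame = pd.DataFrame(
            {
                "injection_id": injection_id,
                "rt": library["expected_rt"].to_numpy()
                + (rng.normal(0, config.rt_jitter, len(library)) if config.rt_jitter > 0 else 0.0),
                "precursor_mz": library["precursor_mz"].to_numpy()
                + (rng.normal(0, config.mz_jitter, len(library)) if config.mz_jitter > 0 else 0.0),
                "product_mz": library["product_mz"].to_numpy()
                + (rng.normal(0, config.mz_jitter, len(library)) if config.mz_jitter > 0 else 0.0),
                "area": areas,
            }
        )
        peak_frames.append(frame)
        seq_rows.append(
            {"injection_id": injection_id, "role": role, "batch": batch, "order": order,
             "dilution_factor": df}
        )

    batches = sorted(sample_batch.unique())
    phases = rng.uniform(0, 2 * np.pi, len(batches))
    batch_offset = (
        np.exp(config.drift_amplitude * rng.uniform(-0.5, 0.5, len(batches)))
        if config.drift_amplitude > 0
        else np.ones(len(batches))
    )

    for bi, b in enumerate(batches):
        ids = sample_batch.index[sample_batch == b]
        ids = ids[np.argsort(sample_order.loc[ids].to_numpy())]
        n_study = len(ids)
        amp = config.drift_amplitude

        def drift_at(t: float) -> np.ndarray:
            m = np.concatenate([mod, mod_is])
            g = 1.0 + amp * m * (t - 0.5) + 0.3 * amp * m * np.sin(2 * np.pi * (1.3 * t) + phases[bi])
            return np.clip(g, 0.05, None) * batch_offset[bi]

        pos = 0
        qc_count = 0
        n_slots = n_study + 1  # normalise order to [0, 1] over the batch

        def next_order():
            nonlocal pos
            pos += 1
            return pos

        g = drift_at(0.0)
        emit(f"QC_b{b}_{qc_count}", "pooled_qc", b, next_order(), qc_extract, g)
        for k, sid in enumerate(ids):
            t = (k + 1) / n_slots
            emit(sid, "study", b, next_order(), extract[table.samples.index.get_loc(sid)], drift_at(t))
            truth_drift[sid] = drift_at(t)[: len(species)]
            if (k + 1) % config.qc_interval == 0 and k + 1 < n_study:
                qc_count += 1
                emit(f"QC_b{b}_{qc_count}", "pooled_qc", b, next_order(), qc_extract, drift_at(t))
        qc_count += 1
        emit(f"QC_b{b}_{qc_count}", "pooled_qc", b, next_order(), qc_extract, drift_at(1.0))
        if b == batches[-1]:
            for df in config.dilution_factors:
                emit(f"DIL_{df}", "dilution_qc", b, next_order(), qc_extract / df, drift_at(1.0), df=float(df))

    peaks = pd.concat(peak_frames, ignore_index=True)
    sequence = pd.DataFrame(seq_rows)
    truth = {
        "response_factors": pd.Series(rf, index=species),
        "qc_extract": pd.Series(qc_extract, index=species),
        "drift": truth_drift,
    }
    return peaks, sequence, library, truth


# ---------------------------------------------------------------------------
# meta-analysis study sets

#: default per-gene true log2 fold changes for the synthetic study sets;
#: pathway genes with study-scale effects, remaining genes null.
DEFAULT_GENE_EFFECTS: dict[str, float] = {
    # lysosomal degradation
    "GBA1": -0.27, "GLB1": -0.28, "GLA": -0.47, "NEU1": -0.21, "NEU3": 0.0,
    "NEU4": 0.0, "HEXA": -0.43, "HEXB": 0.0, "GM2A": 0.0,
    # de novo synthesis
    "SPTLC1": 0.0, "SPTLC2": 0.31, "SPTLC3": 0.31, "SPTSSA": 0.27, "SPTSSB": 0.0,
    "KDSR": 0.56, "CERS1": 0.0, "CERS2": 0.35, "CERS3": 0.0, "CERS4": 0.37,
    "CERS5": 0.0, "CERS6": -0.51, "DEGS1": 0.0, "DEGS2": 0.0, "FADS3": 0.0,
}


def generate_meta_studies(
    config: GeneratorConfig, genes: dict[str, float] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate per-dataset differential-expression effects for ``meta_k``
    studies.

    Per gene, study-level true effects are drawn N(true effect, τ²) and
    observed effects N(study truth, SE²), with SE from the drawn group sizes
    and the within-study log2-expression SD.  Group sizes are drawn around
    the configured case/control totals.

    Returns a long frame (dataset_id, gene, log2fc, se, n_case, n_control)
    and the ground-truth record.
    """
    if config.meta_k < 1:
        raise ValueError("need at least one study")
    rng = config.rng(3)
    gene_effects = dict(DEFAULT_GENE_EFFECTS if genes is None else genes)
    if config.gene_effects is not None and genes is None:
        gene_effects = dict(config.gene_effects)
    k = config.meta_k
    n_case = np.maximum(3, rng.poisson(config.meta_total_case / k, k))
    n_ctrl = np.maximum(3, rng.poisson(config.meta_total_control / k, k))
    sd = config.meta_within_sd
    se = sd * np.sqrt(1.0 / n_case + 1.0 / n_ctrl)
    rows, truth_effects = [], {}
    for gene, mu in gene_effects.items():
        study_truth = mu + config.meta_tau * rng.standard_normal(k)
        observed = study_truth + se * rng.standard_normal(k)
        truth_effects[gene] = {"true_effect": mu, "study_effects": study_truth.tolist()}
        for i in range(k):
            rows.append(
                {
                    "dataset_id": f"DS{i + 1:02d}",
                    "gene": gene,
                    "log2fc": float(observed[i]),
                    "se": float(se[i]),
                    "n_case": int(n_case[i]),
                    "n_control": int(n_ctrl[i]),
                }
            )
    truth = {"tau": config.meta_tau, "genes": truth_effects,
             "n_case": n_case.tolist(), "n_control": n_ctrl.tolist()}
    return pd.DataFrame(rows), truth
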
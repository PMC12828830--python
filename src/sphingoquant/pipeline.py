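"""Pipeline stages over a single YAML run configuration.

Each stage reads its declared inputs from the run directory, writes its
outputs there, and appends a manifest entry (file list with content hashes)
so reruns under the same configuration are verifiably identical.  The CLI
in :mod:`sphingoquant.cli` is a thin wrapper over these functions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, diffstats, meta as meta_mod, qc as qc_mod
from .lsea import lsea as _lsea
from .quantify import DEFAULT_INTERNAL_STANDARDS, quantify_injections
from .synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_injection_run,
    generate_meta_studies,
    generate_panel,
)
from .tables import ConcentrationTable

__all__ = ["DEFAULT_CONFIG", "load_config", "run_stage", "full_report", "STAGES"]

DEFAULT_CONFIG: dict = {
    "outdir": "sphingoquant_run",
    "seed": 0,
    "tolerances": {"mz": 0.3, "rt": 0.3},
    "qc": {"cv_percent": 25.0, "r2": 0.8},
    "stats": {"welch": True, "bh_alpha": 0.01},
    "lsea": {"n_perm": 1000, "seed": 0, "min_set_size": 3},
    "meta": {"method": "DL", "studies_file": None},
    "generator": {},
}


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML config over the defaults; unknown top-level keys error."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in user.items():
            if isinstance(cfg.get(key), dict) and isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _outdir(cfg: dict) -> Path:
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest(outdir: Path, stage: str, files: list[Path]) -> Path:
    mpath = outdir / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
    manifest[stage] = {str(f.name): _sha256(f) for f in files}
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def _require(outdir: Path, name: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise FileNotFoundError(f"stage input missing: {p} (run the producing stage first)")
    return p


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def _generator_config(cfg: dict) -> GeneratorConfig:
    gen = dict(cfg.get("generator") or {})
    gen.setdefault("seed", cfg.get("seed", 0))
    if "dilution_factors" in gen:
        gen["dilution_factors"] = tuple(gen["dilution_factors"])
    return GeneratorConfig(**gen)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: dict) -> list[Path]:
    out = _outdir(cfg)
    gc = _generator_config(cfg)
    panel = generate_panel(gc)
    table, truth = generate_cohort(gc, panel)
    peaks, sequence, library, _ = generate_injection_run(table, gc)
    files = []
    panel.to_csv(out / "panel.csv", index=False)
    table.to_csv(out / "true_concentrations.csv")
    peaks.to_csv(out / "peaks.csv", index=False)
    sequence.to_csv(out / "sequence.csv", index=False)
    library.to_csv(out / "library.csv", index=False)
    (out / "truth.json").write_text(
        json.dumps(
            {
                "effects": truth["effects"],
                "sigma_log": truth["sigma_log"],
                "control_means": truth["control_means"].round(4).to_dict(),
            },
            indent=2,
            sort_keys=True,
        )
    )
    files = [out / n for n in
             ["panel.csv", "true_concentrations.csv", "peaks.csv", "sequence.csv",
              "library.csv", "truth.json"]]
    _manifest(out, "simulate", files)
    return files


def stage_annotate(cfg: dict) -> list[Path]:
    out = _outdir(cfg)
    peaks = pd.read_csv(_require(out, "peaks.csv"))
    _check_columns(peaks, ["injection_id", "rt", "precursor_mz", "product_mz", "area"], "peaks.csv")
    library = pd.read_csv(_require(out, "library.csv"))
    annotated, unmatched = annotation.match_peaks(
        peaks, library, mz_tol=cfg["tolerances"]["mz"], rt_tol=cfg["tolerances"]["rt"]
    )
    annotated.to_csv(out / "annotated.csv", index=False)
    unmatched.to_csv(out / "unmatched.csv", index=False)
    files = [out / "annotated.csv", out / "unmatched.csv"]
    _manifest(out, "annotate", files)
    return files


def stage_quantify(cfg: dict) -> list[Path]:
    out = _outdir(cfg)
    annotated = pd.read_csv(_require(out, "annotated.csv"))
    _check_columns(annotated, ["injection_id", "species", "area"], "annotated.csv")
    conc = quantify_injections(annotated, DEFAULT_INTERNAL_STANDARDS)
    conc.index.name = "injection_id"
    conc.to_csv(out / "injection_concentrations.csv")
    files = [out / "injection_concentrations.csv"]
    _manifest(out, "quantify", files)
    return files


def stage_qc(cfg: dict) -> list[Path]:
    out = _outdir(cfg)
    conc = pd.read_csv(_require(out, "injection_concentrations.csv"), index_col="injection_id")
    sequence = pd.read_csv(_require(out, "sequence.csv"))
    _check_columns(sequence, ["injection_id", "role", "batch", "order"], "sequence.csv")
    annotated = pd.read_csv(_require(out, "annotated.csv"))
    study_qc = sequence[sequence["role"].isin(["study", "pooled_qc"])]
    corrected = qc_mod.correct_drift(conc.loc[study_qc["injection_id"]], study_qc)
    # dilution-series raw areas, indexed by dilution factor
    dil = sequence[sequence["role"] == "dilution_qc"].set_index("injection_id")
    dilution_areas = None
    if len(dil):
        sub = annotated[annotated["injection_id"].isin(dil.index)]
        dilution_areas = sub.pivot_table(
            index="injection_id", columns="species", values="area", aggfunc="first"
        )
        dilution_areas.index = dil.loc[dilution_areas.index, "dilution_factor"].to_numpy()
    metrics = qc_mod.qc_metrics(
        conc.loc[study_qc["injection_id"]], study_qc, dilution_areas,
        cv_threshold=cfg["qc"]["cv_percent"], r2_threshold=cfg["qc"]["r2"],
    )
    accepted, audit = qc_mod.filter_species(metrics)
    metrics.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    audit.to_csv(out / "qc_rejections.tsv", sep="\t", index=False)

    truth_table = ConcentrationTable.from_csv(_require(out, "true_concentrations.csv"))
    study_ids = sequence.loc[sequence["role"] == "study", "injection_id"]
    measured = corrected.loc[study_ids, accepted]
    table = ConcentrationTable(truth_table.samples.loc[measured.index], measured)
    table.to_csv(out / "concentrations.csv")
    files = [out / "qc_report.tsv", out / "qc_rejections.tsv", out / "concentrations.csv"]
    _manifest(out, "qc", files)
    return files


def stage_stats(cfg: dict) -> list[Path]:
    out = _outdir(cfg)
    table = ConcentrationTable.from_csv(_require(out, "concentrations.csv"))
    _check_columns(table.samples, ["group"], "concentrations.csv")
    alpha = cfg["stats"]["bh_alpha"]
    stats_df = diffstats.species_tests(table, equal_var=not cfg["stats"]["welch"])
    volcano = stats_df.copy()
    volcano["significant"] = volcano["p_adj"] < alpha
    volcano.to_csv(out / "volcano.tsv", sep="\t")

    _, ratio_tests = diffstats.compute_ratios(table)
    ratio_tests.to_csv(out / "ratios.tsv", sep="\t")

    totals_rows = []
    for sub in ["Cer", "DHS-Cer", "HexCer", "Hex2Cer", "Hex3Cer", "GM3"]:
        try:
            agg = diffstats.aggregate(
                table, subclasses=(sub,),
                spb_classes=None if sub in ("DHS-Cer", "PHS-Cer") else ("C18-SPH/D",),
                acyl_classes=("C24",), label=sub,
            )
        except ValueError:
            continue
        for group in ("PD", "control"):
            vals = agg.loc[table.group_mask(group), "total"]
            totals_rows.append(
                {"subclass": sub, "group": group, "mean_nM": vals.mean(), "sd_nM": vals.std(ddof=1)}
            )
    pd.DataFrame(totals_rows).to_csv(out / "subclass_totals.tsv", sep="\t", index=False)

    try:
        props, chain_tests = diffstats.chain_distribution(table)
        chain_tests.to_csv(out / "chain_distribution.tsv", sep="\t")
    except ValueError:
        pass

    roc = diffstats.roc_models(
        table, stats_df, p_adj_threshold=alpha, seed=cfg["seed"], on_empty="skip"
    )
    (out / "roc.json").write_text(
        json.dumps(
            {
                k: {"auc": v.auc, "ci": [v.ci_low, v.ci_high], "n_predictors": len(v.predictors)}
                for k, v in roc.items()
            },
            indent=2,
        )
    )
    diffstats.clinical_table(table.samples).to_csv(out / "table1.tsv", sep="\t", index=False)

    from .plots import volcano_plot

    volcano_plot(stats_df, out / "volcano.svg", p_adj_threshold=alpha)
    files = [out / n for n in
             ["volcano.tsv", "ratios.tsv", "subclass_totals.tsv", "roc.json",
              "table1.tsv", "volcano.svg"]]
    if (out / "chain_distribution.tsv").exists():
        files.append(out / "chain_distribution.tsv")
    _manifest(out, "stats", files)
    return files


def stage_lsea(cfg: dict) -> list[Path]:
    out = _outdir(cfg)
    stats_df = pd.read_csv(_require(out, "volcano.tsv"), sep="\t", index_col="species")
    res = _lsea(
        stats_df,
        n_perm=cfg["lsea"]["n_perm"],
        seed=cfg["lsea"]["seed"],
        min_size=cfg["lsea"]["min_set_size"],
    )
    res.to_csv(out / "lsea.tsv", sep="\t", index=False)
    files = [out / "lsea.tsv"]
    _manifest(out, "lsea", files)
    return files


def stage_meta(cfg: dict) -> list[Path]:
    out = _outdir(cfg)
    studies_file = cfg["meta"].get("studies_file")
    if studies_file:
        studies = pd.read_csv(studies_file, sep="\t")
        _check_columns(studies, ["dataset_id", "gene", "log2fc"], "meta studies table")
    else:
        studies, _ = generate_meta_studies(_generator_config(cfg))
    pooled = meta_mod.pool_genes(studies, method=cfg["meta"]["method"])
    studies.to_csv(out / "meta_studies.tsv", sep="\t", index=False)
    pooled.to_csv(out / "meta_pooled.tsv", sep="\t")
    files = [out / "meta_studies.tsv", out / "meta_pooled.tsv"]
    _manifest(out, "meta", files)
    return files


def full_report(cfg: dict) -> Path:
    """Assemble the run report (markdown + figures) from stage outputs; any
    missing section is rendered with an explicit gap note."""
    out = _outdir(cfg)
    lines = ["# sphingoquant run report", ""]

    def section(title: str, fname: str, render) -> None:
        lines.append(f"## {title}")
        path = out / fname
        if not path.exists():
            lines.append(f"_missing: {fname} (stage not run)_")
        else:
            render(path)
        lines.append("")

    def table_md(df: pd.DataFrame, max_rows: int = 15) -> None:
        lines.append(df.head(max_rows).to_markdown())

    def render_volcano(path):
        df = pd.read_csv(path, sep="\t", index_col=0)
        sig = df[df["significant"]] if "significant" in df else df
        lines.append(f"{len(sig)} of {len(df)} species significant. Top by |log2FC|:")
        table_md(sig.reindex(sig["log2fc"].abs().sort_values(ascending=False).index)[
            ["log2fc", "p", "p_adj"]].round(4), 10)
        lines.append("\n![volcano](volcano.svg)")

    def render_simple(path):
        table_md(pd.read_csv(path, sep="\t").round(4), 20)

    def render_roc(path):
        roc = json.loads(Path(path).read_text())
        for model, rec in roc.items():
            lines.append(
                f"- **{model}**: AUC {rec['auc']:.3f} "
                f"(95% CI {rec['ci'][0]:.3f}-{rec['ci'][1]:.3f}, "
                f"{rec['n_predictors']} predictors)"
            )

    def render_lsea(path):
        df = pd.read_csv(path, sep="\t")
        if len(df) == 0:
            lines.append("_no sets passed the size filter_")
        else:
            table_md(df.sort_values("p").round(4), 15)

    def render_forest(path):
        pooled = pd.read_csv(path, sep="\t", index_col="gene").round(3)
        table_md(pooled.sort_values("p"), 30)
        studies_path = out / "meta_studies.tsv"
        if studies_path.exists():
            studies = pd.read_csv(studies_path, sep="\t")
            from .meta import dl_pool
            from .plots import forest_plot

            for gene in pooled.sort_values("p").index[:3]:
                sub = studies[studies["gene"] == gene]
                effects = [
                    meta_mod.StudyEffect(r.dataset_id, gene, r.log2fc, r.se)
                    for r in sub.itertuples()
                ]
                fp = out / f"forest_{gene}.svg"
                forest_plot(meta_mod.forest_table(effects), fp, title=gene)
                lines.append(f"\n![forest {gene}](forest_{gene}.svg)")

    section("Per-species differential abundance (volcano)", "volcano.tsv", render_volcano)
    section("ROC discrimination models", "roc.json", render_roc)
    section("Subclass totals (C18-SPH/D, C24-acyl)", "subclass_totals.tsv", render_simple)
    section("Lipid ratios", "ratios.tsv", render_simple)
    section("Acyl-chain distribution (ceramides, C18-SPH/D)", "chain_distribution.tsv", render_simple)
    section("Lipid set enrichment", "lsea.tsv", render_lsea)
    section("Meta-analysis of pathway enzymes", "meta_pooled.tsv", render_forest)

    report = out / "report.md"
    report.write_text("\n".join(lines))
    _manifest(out, "report", [report])
    return report


STAGES = {
    "simulate": stage_simulate,
    "annotate": stage_annotate,
    "quantify": stage_quantify,
    "qc": stage_qc,
    "stats": stage_stats,
    "lsea": stage_lsea,
    "meta": stage_meta,
    "report": lambda cfg: [full_report(cfg)],
}


def run_stage(stage: str, cfg: dict) -> list[Path]:
    """Run one named stage; returns the files it wrote."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(STAGES)}")
    return STAGES[stage](cfg)
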
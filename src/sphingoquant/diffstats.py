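"""Case-control statistics over the concentration table.

Implements the study's statistical battery: per-species Welch t-tests on
log-transformed concentrations with Benjamini–Hochberg FDR control,
structural aggregation (subclass × sphingoid-base × acyl-chain totals),
acyl-chain proportion profiles, lipid ratios with covariate-adjusted odds
ratios, ROC discrimination models, severity regressions, and the clinical
characteristics table.

Conventions: tests run on natural-log concentrations (the t statistic is
base-invariant); reported fold changes are base 2.  Welch (unequal-variance)
t is the default, switchable to the pooled-variance form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .nomenclature import classify_acyl, classify_spb, parse_species_name, subclass_label
from .tables import ConcentrationTable

__all__ = [
    "species_tests",
    "benjamini_hochberg",
    "aggregate",
    "chain_distribution",
    "RatioDefinition",
    "default_ratio_definitions",
    "compute_ratio",
    "compute_ratios",
    "LogisticResult",
    "logistic_adjusted_or",
    "auc_mann_whitney",
    "RocResult",
    "roc_models",
    "severity_association",
    "clinical_table",
]

_Z95 = 1.959963984540054


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def species_tests(
    table: ConcentrationTable,
    case: str = "PD",
    control: str = "control",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-species group tests on log concentrations with BH adjustment.

    Returns a frame indexed by species with log2fc (difference of group
    means of log2 values), t, p, p_adj, and group means ± sd on the nM
    scale.  Species with fewer than two non-missing values in either group
    are excluded (flagged in the ``tested`` column of the attrs).
    """
    x = table.concentrations
    case_mask = table.group_mask(case).to_numpy()
    ctrl_mask = table.group_mask(control).to_numpy()
    if case_mask.sum() == 0 or ctrl_mask.sum() == 0:
        raise ValueError("both groups must be non-empty")
    a = x.loc[case_mask].to_numpy(dtype=float)
    b = x.loc[ctrl_mask].to_numpy(dtype=float)
    ok = (np.sum(np.isfinite(a) & (a > 0), axis=0) >= 2) & (
        np.sum(np.isfinite(b) & (b > 0), axis=0) >= 2
    )
    cols = x.columns[ok]
    la = np.log(a[:, ok])
    lb = np.log(b[:, ok])
    t, p = stats.ttest_ind(la, lb, axis=0, equal_var=equal_var, nan_policy="omit")
    log2fc = (np.nanmean(la, axis=0) - np.nanmean(lb, axis=0)) / np.log(2.0)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "p_adj": benjamini_hochberg(p),
            "mean_case": np.nanmean(a[:, ok], axis=0),
            "sd_case": np.nanstd(a[:, ok], axis=0, ddof=1),
            "mean_control": np.nanmean(b[:, ok], axis=0),
            "sd_control": np.nanstd(b[:, ok], axis=0, ddof=1),
        },
        index=cols,
    )
    out.index.name = "species"
    dropped = [c for c in x.columns if c not in set(cols)]
    out.attrs["excluded"] = dropped
    return out


def _selection_mask(
    species: list[str],
    subclasses=None,
    spb_classes=None,
    acyl_classes=None,
    merge_sph_spd: bool = True,
    hydroxy_acyl: bool | None = None,
) -> np.ndarray:
    mask = np.ones(len(species), dtype=bool)
    parsed = [parse_species_name(s) for s in species]
    if subclasses is not None:
        mask &= np.array([subclass_label(sp) in set(subclasses) for sp in parsed])
    if spb_classes is not None:
        mask &= np.array(
            [classify_spb(sp, merge_sph_spd=merge_sph_spd) in set(spb_classes) for sp in parsed]
        )
    if acyl_classes is not None:
        mask &= np.array([classify_acyl(sp) in set(acyl_classes) for sp in parsed])
    if hydroxy_acyl is not None:
        mask &= np.array([(sp.acyl.hydroxyls > 0) == hydroxy_acyl for sp in parsed])
    return mask


def aggregate(
    table: ConcentrationTable,
    subclasses=None,
    spb_classes=None,
    acyl_classes=None,
    merge_sph_spd: bool = True,
    label: str | None = None,
) -> pd.DataFrame:
    """Per-sample summed totals over a structural selection.

    The selection is the intersection of the given subclass, sphingoid-base
    class and acyl class filters (each optional; SPH/SPD merge into
    ``C{n}-SPH/D`` labels when ``merge_sph_spd``).  Missing cells contribute
    nothing to the sum; a per-sample completeness count is returned.
    """
    mask = _selection_mask(table.species, subclasses, spb_classes, acyl_classes, merge_sph_spd)
    if not mask.any():
        raise ValueError(
            f"selection matches no species (subclasses={subclasses}, "
            f"spb={spb_classes}, acyl={acyl_classes})"
        )
    sel = table.concentrations.loc[:, mask]
    out = pd.DataFrame(
        {
            "total": sel.sum(axis=1, min_count=1),
            "n_species": sel.notna().sum(axis=1),
        }
    )
    out.attrs["species"] = list(sel.columns)
    out.attrs["label"] = label or "total"
    return out


def chain_distribution(
    table: ConcentrationTable,
    subclasses=("Cer",),
    spb_classes=("C18-SPH/D",),
    even_only: bool = True,
    case: str = "PD",
    control: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative acyl-chain-length distribution within a backbone selection.

    Returns ``(proportions, tests)``: per-sample proportions by acyl class
    (rows sum to 1; all-zero samples are missing) and per-class Welch tests
    on the proportions with BH adjustment.
    """
    mask = _selection_mask(table.species, subclasses, spb_classes, None, True)
    if even_only:
        mask &= np.array(
            [parse_species_name(s).acyl.carbons % 2 == 0 for s in table.species]
        )
    if not mask.any():
        raise ValueError("chain-distribution selection matches no species")
    sel = table.concentrations.loc[:, mask]
    acyl = pd.Series([classify_acyl(parse_species_name(s)) for s in sel.columns], index=sel.columns)
    by_class = sel.T.groupby(acyl).sum(min_count=1).T
    totals = by_class.sum(axis=1, min_count=1)
    props = by_class.div(totals, axis=0)
    props[totals <= 0] = np.nan

    case_mask = table.group_mask(case)
    ctrl_mask = table.group_mask(control)
    rows = []
    for cls in props.columns:
        a = props.loc[case_mask, cls].dropna()
        b = props.loc[ctrl_mask, cls].dropna()
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "acyl": cls,
                "mean_case": a.mean(),
                "mean_control": b.mean(),
                "t": t,
                "p": p,
            }
        )
    tests = pd.DataFrame(rows).set_index("acyl")
    tests["p_adj"] = benjamini_hochberg(tests["p"])
    return props, tests


@dataclass(frozen=True)
class RatioDefinition:
    """A named lipid ratio: summed numerator species over summed denominator."""

    label: str
    numerator: tuple
    denominator: tuple

    def __post_init__(self) -> None:
        num, den = set(self.numerator), set(self.denominator)
        if not num or not den:
            raise ValueError("numerator and denominator must be non-empty")
        if num & den:
            raise ValueError("numerator and denominator sets must be disjoint")


def default_ratio_definitions(
    species: list[str], spb=("C18-SPH/D",), acyl=("C24",)
) -> list[RatioDefinition]:
    """Built-in ratio family (restricted to the canonical C18-SPH/D backbone
    and C24-acyl chains by default): HexCer/Cer, GM3/Hex2Cer,
    Hex3Cer/Hex2Cer, and Cer/DHS-Cer."""

    def pick(subclass):
        mask = _selection_mask(species, (subclass,), spb, acyl)
        # dihydroceramides have a DHS base, never C18-SPH/D: select on acyl only
        if subclass in ("DHS-Cer", "PHS-Cer"):
            mask = _selection_mask(species, (subclass,), None, acyl)
        return tuple(np.array(species)[mask])

    defs = []
    for label, num_sub, den_sub in [
        ("HexCer/Cer", "HexCer", "Cer"),
        ("GM3/Hex2Cer", "GM3", "Hex2Cer"),
        ("Hex3Cer/Hex2Cer", "Hex3Cer", "Hex2Cer"),
        ("Cer/DHS-Cer", "Cer", "DHS-Cer"),
    ]:
        num, den = pick(num_sub), pick(den_sub)
        if num and den:
            defs.append(RatioDefinition(label, num, den))
    return defs


def compute_ratio(
    table: ConcentrationTable, definition: RatioDefinition, case: str = "PD", control: str = "control"
) -> tuple[pd.Series, dict]:
    """Per-sample ratio of summed numerator to summed denominator species,
    with a Welch test on the log ratio.  Samples with a non-positive
    denominator sum are missing (counted in the test record)."""
    num = table.concentrations[list(definition.numerator)].sum(axis=1, min_count=1)
    den = table.concentrations[list(definition.denominator)].sum(axis=1, min_count=1)
    ratio = num / den
    ratio[~(den > 0)] = np.nan
    a = np.log(ratio[table.group_mask(case)].dropna())
    b = np.log(ratio[table.group_mask(control)].dropna())
    t, p = stats.ttest_ind(a, b, equal_var=False)
    rec = {
        "label": definition.label,
        "mean_case": float(np.exp(a.mean())),
        "mean_control": float(np.exp(b.mean())),
        "log2fc": float((a.mean() - b.mean()) / np.log(2.0)),
        "t": float(t),
        "p": float(p),
        "n_missing": int(ratio.isna().sum()),
    }
    return ratio.rename(definition.label), rec


def compute_ratios(
    table: ConcentrationTable,
    definitions: list[RatioDefinition] | None = None,
    case: str = "PD",
    control: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All ratios of a family with BH adjustment across the family."""
    if definitions is None:
        definitions = default_ratio_definitions(table.species)
    series, recs = [], []
    for d in definitions:
        r, rec = compute_ratio(table, d, case, control)
        series.append(r)
        recs.append(rec)
    tests = pd.DataFrame(recs).set_index("label")
    tests["p_adj"] = benjamini_hochberg(tests["p"])
    return pd.concat(series, axis=1), tests


@dataclass(frozen=True)
class LogisticResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float
    covariates: tuple = ()

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must contain the odds ratio")


def logistic_adjusted_or(
    outcome, exposure, covariates: pd.DataFrame | None = None
) -> LogisticResult:
    """Covariate-adjusted odds ratio for a binary outcome.

    Maximum-likelihood logistic fit (statsmodels IRLS/Newton); the exposure
    coefficient's Wald 95% CI is exponentiated to an odds-ratio scale.
    Degenerate designs (constant columns, collinearity) and non-convergence
    or separation raise with an explicit diagnostic.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    x = pd.DataFrame({"exposure": np.asarray(exposure, dtype=float)})
    cov_names: tuple = ()
    if covariates is not None:
        cov = covariates.copy()
        for c in cov.columns:
            if cov[c].dtype == object or str(cov[c].dtype) == "category":
                cov[c] = pd.factorize(cov[c])[0].astype(float)
        x = pd.concat([x, cov.reset_index(drop=True)], axis=1)
        cov_names = tuple(cov.columns)
    if (x.std(ddof=0) == 0).any():
        bad = x.columns[(x.std(ddof=0) == 0)].tolist()
        raise ValueError(f"constant predictor column(s): {bad}")
    design = sm.add_constant(x.to_numpy())
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    model = sm.Logit(y, design)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge (possible separation)")
    coef = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or se > 50:
        raise RuntimeError("unstable exposure coefficient (possible separation)")
    return LogisticResult(
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - _Z95 * se)),
        ci_high=float(np.exp(coef + _Z95 * se)),
        p=float(res.pvalues[1]),
        coef=coef,
        se=se,
        covariates=cov_names,
    )


def auc_mann_whitney(scores_case, scores_control) -> float:
    """AUC as the pairwise Mann–Whitney probability: the fraction of
    case/control pairs ranked correctly, ties counting one half."""
    a = np.asarray(scores_case, dtype=float)
    b = np.asarray(scores_control, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def _bootstrap_auc_ci(scores, labels, n_boot=2000, seed=0) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    idx_case = np.flatnonzero(labels == 1)
    idx_ctrl = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        ca = scores[rng.choice(idx_case, idx_case.size)]
        co = scores[rng.choice(idx_ctrl, idx_ctrl.size)]
        aucs[i] = auc_mann_whitney(ca, co)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass(frozen=True)
class RocResult:
    label: str
    auc: float
    ci_low: float
    ci_high: float
    predictors: tuple = ()

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must lie in [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must contain the AUC")


_GSL_SUBCLASSES = ("HexCer", "Hex2Cer", "Hex3Cer", "HexNAcHex3Cer", "GM3")
_CER_SUBCLASSES = ("Cer", "DHS-Cer", "PHS-Cer")


def roc_models(
    table: ConcentrationTable,
    stats_df: pd.DataFrame | None = None,
    p_adj_threshold: float = 0.01,
    include_demographics: bool = True,
    case: str = "PD",
    control: str = "control",
    n_boot: int = 2000,
    seed: int = 0,
    on_empty: str = "raise",
) -> dict[str, RocResult]:
    """Logistic-score ROC models for group discrimination.

    Models: ``basic`` (age + sex only), ``gsl`` and ``ceramide`` (the
    significantly altered species of those families), and ``full`` (all
    species passing ``p_adj < threshold``).  Lipid models include age and
    sex unless ``include_demographics=False``.  The AUC is the pairwise
    Mann–Whitney statistic on the in-sample logistic score, with a seeded
    bootstrap percentile CI.
    """
    if stats_df is None:
        stats_df = species_tests(table, case, control)
    sig = stats_df.index[stats_df["p_adj"] < p_adj_threshold].tolist()
    keep = table.samples["group"].isin([case, control])
    if keep.sum() == 0 or table.samples.loc[keep, "group"].nunique() < 2:
        raise ValueError("need samples from both groups")
    y = (table.samples.loc[keep, "group"] == case).to_numpy(dtype=int)
    demo = pd.DataFrame(
        {
            "age": table.samples.loc[keep, "age"].astype(float),
            "sex": pd.factorize(table.samples.loc[keep, "sex"])[0].astype(float),
        }
    )

    def family(subclasses):
        return [s for s in sig if subclass_label(parse_species_name(s)) in subclasses]

    models = {
        "basic": [],
        "gsl": family(_GSL_SUBCLASSES),
        "ceramide": family(_CER_SUBCLASSES),
        "full": sig,
    }
    out = {}
    for label, specs in models.items():
        blocks = []
        if include_demographics or label == "basic":
            blocks.append(demo.to_numpy())
        if specs:
            blocks.append(np.log(table.concentrations.loc[keep, specs].to_numpy(dtype=float)))
        elif label != "basic":
            if on_empty == "skip":
                continue
            raise ValueError(f"no significant species available for the {label!r} model")
        x = np.column_stack(blocks)
        x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
        clf = LogisticRegression(C=np.inf, max_iter=5000)
        clf.fit(x, y)
        score = clf.decision_function(x)
        auc = auc_mann_whitney(score[y == 1], score[y == 0])
        lo, hi = _bootstrap_auc_ci(score, y, n_boot=n_boot, seed=seed)
        predictors = tuple((["age", "sex"] if (include_demographics or label == "basic") else []) + specs)
        out[label] = RocResult(label, auc, min(lo, auc), max(hi, auc), predictors)
    return out


def severity_association(
    table: ConcentrationTable,
    outcome: str,
    covariates=("age", "sex", "disease_duration", "ledd"),
    case: str = "PD",
) -> pd.DataFrame:
    """Per-species multivariate linear association with a severity outcome.

    Ordinary least squares of the outcome on log species concentration plus
    covariates, case-group samples only; per-species p with BH across
    species.  Zero-variance or collinear covariates raise.
    """
    import statsmodels.api as sm

    meta = table.samples.loc[table.group_mask(case)].copy()
    cov = meta[list(covariates)].copy()
    for c in cov.columns:
        if cov[c].dtype == object:
            cov[c] = pd.factorize(cov[c])[0].astype(float)
    complete = cov.notna().all(axis=1) & meta[outcome].notna()
    cov, meta = cov.loc[complete], meta.loc[complete]
    if (cov.std(ddof=0) == 0).any():
        bad = cov.columns[cov.std(ddof=0) == 0].tolist()
        raise ValueError(f"zero-variance covariate(s): {bad}")
    y = meta[outcome].to_numpy(dtype=float)
    rows = []
    for sp in table.species:
        lx = np.log(table.concentrations.loc[meta.index, sp].to_numpy(dtype=float))
        design = sm.add_constant(np.column_stack([lx, cov.to_numpy(dtype=float)]))
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(f"collinear design for species {sp}")
        res = sm.OLS(y, design, missing="drop").fit()
        rows.append(
            {
                "species": sp,
                "coef": float(res.params[1]),
                "ci_low": float(res.conf_int()[1, 0]),
                "ci_high": float(res.conf_int()[1, 1]),
                "p": float(res.pvalues[1]),
            }
        )
    out = pd.DataFrame(rows).set_index("species")
    out["p_adj"] = benjamini_hochberg(out["p"])
    return out


_DEFAULT_CONTINUOUS = [
    ("age", "Age (years)"),
    ("bmi", "BMI (kg/m2)"),
    ("mmse", "MMSE"),
    ("creatinine", "Creatinine (mg/dl)"),
]
_DEFAULT_CATEGORICAL = [
    ("sex", "Female, n (%)", "F"),
    ("hypertension", "Hypertension, n (%)", 1),
    ("diabetes", "Diabetes mellitus, n (%)", 1),
    ("cardiovascular_disease", "Cardiovascular disease, n (%)", 1),
    ("cerebrovascular_disease", "Cerebrovascular disease, n (%)", 1),
    ("constipation", "Constipation, n (%)", 1),
]


def clinical_table(
    cohort: pd.DataFrame,
    continuous=None,
    categorical=None,
    case: str = "PD",
    control: str = "control",
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Clinical characteristics summary with a between-group test per row.

    Continuous rows report mean ± sd per group with Student's t when both
    groups pass a Shapiro–Wilk normality gate (and Levene homogeneity is
    recorded), Mann–Whitney U otherwise; categorical rows report n (%) with
    Fisher's exact test.
    """
    continuous = _DEFAULT_CONTINUOUS if continuous is None else continuous
    categorical = _DEFAULT_CATEGORICAL if categorical is None else categorical
    a_mask = cohort["group"] == case
    b_mask = cohort["group"] == control
    rows = []
    for col, label in continuous:
        if col not in cohort.columns:
            continue
        a = cohort.loc[a_mask, col].dropna().to_numpy(dtype=float)
        b = cohort.loc[b_mask, col].dropna().to_numpy(dtype=float)
        normal = (
            a.size >= 3
            and b.size >= 3
            and stats.shapiro(a).pvalue > normality_alpha
            and stats.shapiro(b).pvalue > normality_alpha
        )
        levene_p = float(stats.levene(a, b).pvalue)
        if normal:
            test, p = "t", float(stats.ttest_ind(a, b, equal_var=levene_p > 0.05).pvalue)
        else:
            test, p = "mann-whitney", float(stats.mannwhitneyu(a, b).pvalue)
        rows.append(
            {
                "variable": label,
                "case": f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
                "control": f"{b.mean():.1f} ± {b.std(ddof=1):.1f}",
                "test": test,
                "p": p,
            }
        )
    for col, label, positive in categorical:
        if col not in cohort.columns:
            continue
        a = cohort.loc[a_mask, col]
        b = cohort.loc[b_mask, col]
        ka, kb = int((a == positive).sum()), int((b == positive).sum())
        na, nb = int(a.notna().sum()), int(b.notna().sum())
        _, p = stats.fisher_exact([[ka, na - ka], [kb, nb - kb]])
        rows.append(
            {
                "variable": label,
                "case": f"{ka} ({100 * ka / na:.1f})",
                "control": f"{kb} ({100 * kb / nb:.1f})",
                "test": "fisher",
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
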
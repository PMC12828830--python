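"""Transition-library construction and MRM peak annotation.

MRM (multiple reaction monitoring) acquisition records, per injection, one
chromatographic peak per monitored precursor→product ion transition.  This
module computes theoretical monoisotopic masses for library construction and
matches acquired peaks back to library entries by precursor m/z, product m/z
and retention time.

Product-ion convention: the library generator emits the dehydrated sphingoid
base fragment (base − 2 H2O + H+, e.g. m/z 264.27 for sphingosine) as the
product ion for every class.  This is a convention, not vendor-verified
chemistry; real transition lists can be loaded from CSV instead.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .nomenclature import SphingolipidSpecies, parse_species_name

__all__ = [
    "elemental_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "spb_fragment_mz",
    "default_rt_model",
    "build_transition_library",
    "match_peaks",
    "ADDUCTS",
    "DEFAULT_MZ_TOL",
    "DEFAULT_RT_TOL",
]

PROTON = 1.007276466
_WATER = 18.0105646863
_NH3 = 17.0265491

#: supported positive-mode adducts: label -> mass shift relative to the neutral
ADDUCTS: dict[str, float] = {
    "[M+H]+": PROTON,
    "[M+H-H2O]+": PROTON - _WATER,
    "[M+NH4]+": PROTON + _NH3,
}

# residue increments for glycan units (free sugar minus H2O)
_HEXOSE = Counter({"C": 6, "H": 10, "O": 5})
_HEXNAC = Counter({"C": 8, "H": 13, "N": 1, "O": 5})
_NEUAC = Counter({"C": 11, "H": 17, "N": 1, "O": 8})

DEFAULT_MZ_TOL = 0.3  # Da — unit-resolution quadrupole
DEFAULT_RT_TOL = 0.3  # min


def _base_formula(carbons: int, double_bonds: int, hydroxyls: int) -> Counter:
    # free sphingoid base CnH(2n+3-2db)N O(oh); sphingosine -> C18H37NO2
    return Counter({"C": carbons, "H": 2 * carbons + 3 - 2 * double_bonds, "N": 1, "O": hydroxyls})


def _fatty_acid_formula(carbons: int, double_bonds: int, hydroxyls: int) -> Counter:
    return Counter({"C": carbons, "H": 2 * carbons - 2 * double_bonds, "O": 2 + hydroxyls})


def elemental_formula(species: SphingolipidSpecies | str) -> dict[str, int]:
    """Element counts of the neutral species.

    The ceramide core is the sphingoid base amide-condensed with the fatty
    acid (−H2O); each hexose adds C6H10O5, HexNAc C8H13NO5 and NeuAc
    C11H17NO8 (glycosidic residues, water already removed).
    """
    if isinstance(species, str):
        species = parse_species_name(species)
    f = _base_formula(species.base.carbons, species.base.double_bonds, species.base.hydroxyls)
    f += _fatty_acid_formula(species.acyl.carbons, species.acyl.double_bonds, species.acyl.hydroxyls)
    f -= Counter({"H": 2, "O": 1})  # amide condensation
    hx, hn, na = species.head.hexoses, species.head.hexnac, species.head.neuac
    for unit, n in ((_HEXOSE, hx), (_HEXNAC, hn), (_NEUAC, na)):
        for _ in range(n):
            f += unit
    return dict(f)


def monoisotopic_mass(formula: dict[str, int]) -> float:
    """Neutral monoisotopic mass from pyteomics' atomic-mass tables."""
    return _pmass.calculate_mass(composition=_pmass.Composition(formula))


def adduct_mz(formula: dict[str, int], adduct: str = "[M+H]+") -> float:
    """Monoisotopic m/z of a singly-charged adduct of the given neutral."""
    if adduct not in ADDUCTS:
        raise KeyError(f"unknown adduct {adduct!r}; supported: {sorted(ADDUCTS)}")
    return monoisotopic_mass(formula) + ADDUCTS[adduct]


def spb_fragment_mz(species: SphingolipidSpecies | str) -> float:
    """m/z of the doubly-dehydrated sphingoid-base fragment (base − 2 H2O + H+)."""
    if isinstance(species, str):
        species = parse_species_name(species)
    b = species.base
    f = _base_formula(b.carbons, b.double_bonds, b.hydroxyls)
    return monoisotopic_mass(dict(f)) - 2 * _WATER + PROTON


def default_rt_model(species: SphingolipidSpecies | str) -> float:
    """Deterministic retention-time model over the 11-min gradient.

    Retention follows the equivalent carbon number (total carbons penalised
    for double bonds and extra hydroxyls), with glycan head groups eluting
    earlier.  Used to seed synthetic libraries; real libraries carry measured
    retention times.
    """
    if isinstance(species, str):
        species = parse_species_name(species)
    b, a = species.base, species.acyl
    ecn = (b.carbons + a.carbons) - 1.5 * (b.double_bonds + a.double_bonds)
    ecn -= 1.0 * (max(b.hydroxyls - 2, 0) + a.hydroxyls)
    offset = {
        "Cer": 0.0,
        "HexCer": -0.35,
        "Hex2Cer": -0.7,
        "Hex3Cer": -1.0,
        "HexNAcHex3Cer": -1.25,
        "GM3": -1.5,
    }[species.head.class_label]
    rt = 0.8 + 0.5 * (ecn - 26.0) + offset
    return float(np.clip(rt, 0.2, 10.9))


_DEFAULT_CLASS_ADDUCT = {
    "Cer": "[M+H]+",
    "HexCer": "[M+H]+",
    "Hex2Cer": "[M+H]+",
    "Hex3Cer": "[M+H]+",
    "HexNAcHex3Cer": "[M+H]+",
    "GM3": "[M+H]+",
}


def build_transition_library(
    species: list[SphingolipidSpecies | str],
    class_adducts: dict[str, str] | None = None,
    rt_model=default_rt_model,
) -> pd.DataFrame:
    """Build a transition library frame (name, adduct, precursor_mz, product_mz,
    expected_rt) for a species panel.

    Precursors are class-default adducts of the neutral species; products are
    the sphingoid-base fragment.
    """
    adducts = dict(_DEFAULT_CLASS_ADDUCT)
    if class_adducts:
        adducts.update(class_adducts)
    rows = []
    for sp in species:
        if isinstance(sp, str):
            sp = parse_species_name(sp)
        adduct = adducts[sp.head.class_label]
        rows.append(
            {
                "name": sp.name,
                "adduct": adduct,
                "precursor_mz": adduct_mz(elemental_formula(sp), adduct),
                "product_mz": spb_fragment_mz(sp),
                "expected_rt": rt_model(sp),
            }
        )
    return pd.DataFrame(rows)


def _check_library(library: pd.DataFrame) -> None:
    required = {"name", "precursor_mz", "product_mz", "expected_rt"}
    missing = required - set(library.columns)
    if missing:
        raise ValueError(f"transition library missing columns {sorted(missing)}")
    key = library[["precursor_mz", "product_mz", "expected_rt"]].round(4)
    if key.duplicated().any():
        dup = library.loc[key.duplicated(), "name"].tolist()
        raise ValueError(f"duplicate transitions (identical m/z pair and RT) in library: {dup}")


def match_peaks(
    peaks: pd.DataFrame,
    library: pd.DataFrame,
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate MRM peaks against a transition library.

    Candidate (peak, entry) pairs must pass both m/z gates (precursor and
    product within ``mz_tol``) and the RT gate (``rt_tol``).  Assignment is
    greedy by ascending |rt_delta| with each peak assigned to at most one
    entry and each entry claiming at most one peak per injection, which makes
    the result deterministic and independent of peak-list order.

    Parameters
    ----------
    peaks : frame with columns injection_id, rt, precursor_mz, product_mz, area
    library : frame with columns name, precursor_mz, product_mz, expected_rt

    Returns
    -------
    (annotated, unmatched) : annotated carries the peak columns plus
        species, rt_delta, mz_delta; unmatched carries the unassigned peaks.
    """
    if mz_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    _check_library(library)
    peaks = peaks.reset_index(drop=True)
    lib_prec = library["precursor_mz"].to_numpy()
    lib_prod = library["product_mz"].to_numpy()
    lib_rt = library["expected_rt"].to_numpy()
    lib_name = library["name"].to_numpy()

    assigned_rows: list[dict] = []
    unmatched_idx: list[int] = []
    # deterministic injection processing order
    for inj, sub in peaks.groupby("injection_id", sort=True):
        p_prec = sub["precursor_mz"].to_numpy()[:, None]
        p_prod = sub["product_mz"].to_numpy()[:, None]
        p_rt = sub["rt"].to_numpy()[:, None]
        ok = (np.abs(p_prec - lib_prec) <= mz_tol) & (np.abs(p_prod - lib_prod) <= mz_tol)
        rt_delta = p_rt - lib_rt
        ok &= np.abs(rt_delta) <= rt_tol
        pi, li = np.nonzero(ok)
        order = np.lexsort((li, pi, np.abs(rt_delta[pi, li])))
        taken_peak: set[int] = set()
        taken_entry: set[int] = set()
        sub_idx = sub.index.to_numpy()
        matched_here: set[int] = set()
        for k in order:
            p, e = int(pi[k]), int(li[k])
            if p in taken_peak or e in taken_entry:
                continue
            taken_peak.add(p)
            taken_entry.add(e)
            matched_here.add(sub_idx[p])
            row = sub.loc[sub_idx[p]].to_dict()
            row.update(
                species=lib_name[e],
                rt_delta=float(rt_delta[p, e]),
                mz_delta=float(p_prec[p, 0] - lib_prec[e]),
            )
            assigned_rows.append(row)
        unmatched_idx.extend(i for i in sub_idx if i not in matched_here)

    annotated = pd.DataFrame(
        assigned_rows,
        columns=list(peaks.columns) + ["species", "rt_delta", "mz_delta"],
    )
    unmatched = peaks.loc[sorted(unmatched_idx)].reset_index(drop=True)
    return annotated.reset_index(drop=True), unmatched
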
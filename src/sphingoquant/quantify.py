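"""Internal-standard quantification of annotated MRM peaks.

Single-point quantification against class-matched stable-isotope internal
standards spiked into the extraction solvent at a known concentration
(10 nM by default).  This yields Lipidomics Standards Initiative level-2
confidence where a same-class standard exists, and level-3 (surrogate
standard of the most similar head class) otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nomenclature import SphingolipidSpecies, parse_species_name, subclass_label

__all__ = [
    "InternalStandard",
    "DEFAULT_INTERNAL_STANDARDS",
    "assign_internal_standard",
    "concentration",
    "assign_quant_level",
    "quantify_injections",
    "DEFAULT_VOLUME_FACTOR",
]

log = logging.getLogger(__name__)

#: plasma volume 20 µl into 200 µl extraction solvent
DEFAULT_VOLUME_FACTOR = 10.0

# head-class similarity chain used for surrogate-standard lookup
_CLASS_CHAIN = ["Cer", "HexCer", "Hex2Cer", "Hex3Cer", "HexNAcHex3Cer"]


@dataclass(frozen=True)
class InternalStandard:
    """A spiked labelled standard: display name, head class it quantifies,
    and its concentration in the extraction solvent (nM)."""

    species_name: str
    head_class: str
    spiked_conc: float = 10.0

    def __post_init__(self) -> None:
        if self.spiked_conc <= 0:
            raise ValueError("spiked concentration must be positive")


#: default standard mix: one labelled standard per level-2 class plus GM3-d5
DEFAULT_INTERNAL_STANDARDS: list[InternalStandard] = [
    InternalStandard("Cer 18:1;O2/15:0-d7 (IS)", "Cer"),
    InternalStandard("HexCer 18:1;O2/15:0-d7 (IS)", "HexCer"),
    InternalStandard("Hex2Cer 18:1;O2/15:0-d7 (IS)", "Hex2Cer"),
    InternalStandard("GM3 18:1;O2/18:0-d5 (IS)", "GM3"),
]


def assign_internal_standard(
    species: SphingolipidSpecies | str, standards: list[InternalStandard]
) -> InternalStandard:
    """Pick the standard of the same — or most similar — head class.

    Exact class match wins.  Otherwise the nearest class along the glycan
    chain Cer↔HexCer↔Hex2Cer↔Hex3Cer↔HexNAcHex3Cer is used (ties resolved
    toward the less glycosylated class); a GM3 species without a GM3 standard
    falls back to Hex2Cer, its ganglioside core, before the chain rule.
    """
    if not standards:
        raise ValueError("internal standard list is empty")
    if isinstance(species, str):
        species = parse_species_name(species)
    cls = species.head.class_label
    by_class = {}
    for std in standards:
        by_class.setdefault(std.head_class, std)
    if cls in by_class:
        return by_class[cls]
    if cls == "GM3":
        if "Hex2Cer" in by_class:
            return by_class["Hex2Cer"]
        cls = "Hex2Cer"  # continue chain search from the ganglioside core
    pos = _CLASS_CHAIN.index(cls)
    best = None
    for candidate_cls, std in sorted(
        by_class.items(), key=lambda kv: _CLASS_CHAIN.index(kv[0]) if kv[0] in _CLASS_CHAIN else 99
    ):
        if candidate_cls not in _CLASS_CHAIN:
            continue
        d = abs(_CLASS_CHAIN.index(candidate_cls) - pos)
        if best is None or d < best[0]:
            best = (d, std)
    if best is None:
        raise ValueError(f"no internal standard assignable to class {cls}")
    return best[1]


def concentration(
    analyte_area: float,
    is_area: float,
    is_conc: float = 10.0,
    volume_factor: float = DEFAULT_VOLUME_FACTOR,
) -> float:
    """Plasma concentration (nM) by single-point internal-standard ratio:
    ``(analyte_area / is_area) × is_conc × volume_factor``.

    A non-positive standard area invalidates the value (returns NaN with a
    logged warning) rather than raising: a missing standard signal spoils the
    dependent species of that injection only.
    """
    if volume_factor <= 0:
        raise ValueError("volume_factor must be positive")
    if not is_area > 0:
        log.warning("non-positive internal-standard area (%s); concentration set missing", is_area)
        return float("nan")
    return float(analyte_area) / float(is_area) * is_conc * volume_factor


def assign_quant_level(species: SphingolipidSpecies | str) -> int:
    """Quantification confidence tier: 2 for Cer, DHS-Cer, HexCer, Hex2Cer and
    GM3 (class-matched standard), 3 for Hex3Cer and all remaining classes
    (surrogate standard)."""
    if isinstance(species, str):
        species = parse_species_name(species)
    sub = subclass_label(species)
    if sub in ("Cer", "DHS-Cer") or species.head.class_label in ("HexCer", "Hex2Cer", "GM3"):
        return 2
    return 3


def quantify_injections(
    annotated: pd.DataFrame,
    standards: list[InternalStandard] = DEFAULT_INTERNAL_STANDARDS,
    volume_factor: float = DEFAULT_VOLUME_FACTOR,
) -> pd.DataFrame:
    """Convert annotated peak areas to concentrations, injection by injection.

    ``annotated`` must carry columns injection_id, species, area, with the
    internal standards present as species rows (their ``species_name``).
    Returns an injections × species frame of concentrations (nM).
    """
    is_names = {std.species_name: std for std in standards}
    wide = annotated.pivot_table(
        index="injection_id", columns="species", values="area", aggfunc="first"
    )
    analyte_cols = [c for c in wide.columns if c not in is_names]
    out = pd.DataFrame(index=wide.index, columns=analyte_cols, dtype=float)
    assignment = {name: assign_internal_standard(name, standards) for name in analyte_cols}
    for name in analyte_cols:
        std = assignment[name]
        if std.species_name not in wide.columns:
            log.warning("internal standard %s absent from run; %s left missing", std.species_name, name)
            continue
        is_areas = wide[std.species_name].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = wide[name].to_numpy(dtype=float) / is_areas * std.spiked_conc * volume_factor
        vals[~(is_areas > 0)] = np.nan
        out[name] = vals
    out.columns.name = None
    return out
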
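"""Sphingolipid shorthand nomenclature: parsing, formatting and structural classification.

Every species handled by the pipeline is a ceramide or glycosphingolipid
built from three parts:

* a **head group** (Cer = none, HexCer/Hex2Cer/Hex3Cer = 1-3 hexoses,
  HexNAcHex3Cer = globo-series +HexNAc, GM3 = dihexose + one NeuAc),
* a **sphingoid base** (SPB), the long-chain amino-alcohol backbone, and
* an **N-acyl chain**, the amide-linked fatty acid.

Names follow the shorthand-2020 dialect, ``Class C:db;Ox/C:db(;O)``, e.g.
``HexCer 18:1;O2/24:0``.  The legacy ``d18:1/24:0`` dialect (d = dihydroxy
base, t = trihydroxy base, ``h``-prefix or ``(2OH)`` = hydroxylated acyl) is
accepted on input and normalised to the canonical form.

Species-level resolution only: double-bond positions and glycan linkage
isomers (GlcCer vs GalCer, Gb3 vs isoGb3) are not modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "SphingoidBase",
    "AcylChain",
    "HeadGroup",
    "SphingolipidSpecies",
    "NameParseError",
    "UnsupportedClassError",
    "parse_species_name",
    "format_species_name",
    "subclass_label",
    "classify_spb",
    "classify_acyl",
    "HEAD_CLASSES",
    "panel_table",
]


class NameParseError(ValueError):
    """Raised when a species name does not follow a recognised grammar."""


class UnsupportedClassError(ValueError):
    """Raised for head-group classes outside the measured panel."""


#: head-group composition: class label -> (hexoses, HexNAc, NeuAc)
HEAD_CLASSES: dict[str, tuple[int, int, int]] = {
    "Cer": (0, 0, 0),
    "HexCer": (1, 0, 0),
    "Hex2Cer": (2, 0, 0),
    "Hex3Cer": (3, 0, 0),
    "HexNAcHex3Cer": (3, 1, 0),
    "GM3": (2, 0, 1),
}

#: (double_bonds, hydroxyls) -> sphingoid-base kind
_BASE_KINDS: dict[tuple[int, int], str] = {
    (1, 2): "SPH",  # sphingosine
    (2, 2): "SPD",  # sphingadiene
    (0, 2): "DHS",  # dihydrosphingosine (sphinganine)
    (0, 3): "PHS",  # phytosphingosine
}


@dataclass(frozen=True, order=True)
class SphingoidBase:
    """Long-chain base: carbon count, double bonds, hydroxyl count (2 or 3)."""

    carbons: int
    double_bonds: int
    hydroxyls: int

    def __post_init__(self) -> None:
        if not 14 <= self.carbons <= 22:
            raise ValueError(f"sphingoid base carbons {self.carbons} outside [14, 22]")
        if (self.double_bonds, self.hydroxyls) not in _BASE_KINDS:
            raise ValueError(
                f"no sphingoid-base kind for {self.double_bonds} double bonds "
                f"and {self.hydroxyls} hydroxyls"
            )

    @property
    def kind(self) -> str:
        """SPH, SPD, DHS or PHS — a pure function of (double_bonds, hydroxyls)."""
        return _BASE_KINDS[(self.double_bonds, self.hydroxyls)]


@dataclass(frozen=True, order=True)
class AcylChain:
    """N-acyl chain: carbon count, double bonds, hydroxyl flag (0 or 1)."""

    carbons: int
    double_bonds: int
    hydroxyls: int = 0

    def __post_init__(self) -> None:
        if not 12 <= self.carbons <= 26:
            raise ValueError(f"acyl carbons {self.carbons} outside [12, 26]")
        if self.hydroxyls not in (0, 1):
            raise ValueError("acyl hydroxyl count must be 0 or 1")
        if not 0 <= self.double_bonds <= 3:
            raise ValueError("acyl double bonds must be in [0, 3]")


@dataclass(frozen=True)
class HeadGroup:
    class_label: str
    hexoses: int = field(default=-1)
    hexnac: int = field(default=-1)
    neuac: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.class_label not in HEAD_CLASSES:
            raise UnsupportedClassError(f"unsupported head-group class {self.class_label!r}")
        hx, hn, na = HEAD_CLASSES[self.class_label]
        # allow construction from the label alone; otherwise enforce consistency
        if self.hexoses == -1:
            object.__setattr__(self, "hexoses", hx)
            object.__setattr__(self, "hexnac", hn)
            object.__setattr__(self, "neuac", na)
        elif (self.hexoses, self.hexnac, self.neuac) != (hx, hn, na):
            raise ValueError(
                f"head-group composition {(self.hexoses, self.hexnac, self.neuac)} "
                f"inconsistent with class {self.class_label}"
            )


@dataclass(frozen=True)
class SphingolipidSpecies:
    head: HeadGroup
    base: SphingoidBase
    acyl: AcylChain

    @property
    def name(self) -> str:
        return format_species_name(self)

    @property
    def subclass(self) -> str:
        return subclass_label(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


_SHORTHAND_2020 = re.compile(
    r"^\s*(?P<cls>[A-Za-z][A-Za-z0-9]*)\s+"
    r"(?P<bc>\d+):(?P<bdb>\d+);O(?P<boh>\d*)\s*/\s*"
    r"(?P<ac>\d+):(?P<adb>\d+)(?P<aoh>;O\d*)?\s*$"
)

_LEGACY = re.compile(
    r"^\s*(?P<cls>[A-Za-z][A-Za-z0-9]*)\s*[\s(]\s*"
    r"(?P<pre>[dt])(?P<bc>\d+):(?P<bdb>\d+)\s*/\s*"
    r"(?P<hpre>h)?(?P<ac>\d+):(?P<adb>\d+)(?P<ohsuf>\(2OH\))?\s*\)?\s*$"
)


def parse_species_name(name: str) -> SphingolipidSpecies:
    """Parse a shorthand species name into its structured identity.

    Both the shorthand-2020 dialect (``Cer 18:1;O2/24:0``) and the legacy
    dialect (``Cer d18:1/24:0``, ``Cer(d18:1/h24:0)``) are accepted; the
    structured result formats back to the canonical 2020 form.

    Raises
    ------
    NameParseError
        if the name matches neither grammar, or its fields violate the
        structural invariants (e.g. an impossible base kind).
    UnsupportedClassError
        for head-group classes outside the measured panel.
    """
    if not name or not name.strip():
        raise NameParseError("empty species name")
    m = _SHORTHAND_2020.match(name)
    if m:
        boh = int(m.group("boh") or 1)
        aoh_tok = m.group("aoh")
        aoh = 0 if aoh_tok is None else int(aoh_tok[2:] or 1)
    else:
        m = _LEGACY.match(name)
        if m is None:
            raise NameParseError(
                f"malformed species name {name!r}: expected "
                f"'Class C:db;Ox/C:db(;O)' or legacy 'Class d18:1/24:0'"
            )
        boh = {"d": 2, "t": 3}[m.group("pre")]
        aoh = 1 if (m.group("hpre") or m.group("ohsuf")) else 0
    cls = m.group("cls")
    if cls not in HEAD_CLASSES:
        raise UnsupportedClassError(f"unsupported head-group class {cls!r} in {name!r}")
    try:
        base = SphingoidBase(int(m.group("bc")), int(m.group("bdb")), boh)
        acyl = AcylChain(int(m.group("ac")), int(m.group("adb")), aoh)
    except ValueError as exc:
        raise NameParseError(f"invalid species {name!r}: {exc}") from exc
    return SphingolipidSpecies(HeadGroup(cls), base, acyl)


def format_species_name(species: SphingolipidSpecies) -> str:
    """Canonical shorthand-2020 text; ``parse ∘ format`` is the identity."""
    b, a = species.base, species.acyl
    acyl_ox = ";O" if a.hydroxyls == 1 else ""
    return (
        f"{species.head.class_label} "
        f"{b.carbons}:{b.double_bonds};O{b.hydroxyls}/"
        f"{a.carbons}:{a.double_bonds}{acyl_ox}"
    )


def subclass_label(species: SphingolipidSpecies) -> str:
    """Subclass for aggregation: glyco heads keep their class label, while the
    ceramide class splits by base kind (Cer = SPH/SPD base, DHS-Cer, PHS-Cer)."""
    cls = species.head.class_label
    if cls == "Cer":
        kind = species.base.kind
        if kind in ("SPH", "SPD"):
            return "Cer"
        return f"{kind}-Cer"
    return cls


def classify_spb(species: SphingolipidSpecies, merge_sph_spd: bool = False) -> str:
    """Sphingoid-base class label, e.g. ``C18-SPH``.

    With ``merge_sph_spd=True``, sphingosine and sphingadiene bases of equal
    carbon number share the merged label ``C{n}-SPH/D`` (the canonical-base
    grouping used for subclass totals).
    """
    b = species.base
    kind = b.kind
    if merge_sph_spd and kind in ("SPH", "SPD"):
        kind = "SPH/D"
    return f"C{b.carbons}-{kind}"


def classify_acyl(species: SphingolipidSpecies) -> str:
    """Acyl-chain class label ``C{n}``; saturation is pooled (all 24:x → C24).

    Hydroxylation is deliberately not encoded in the label — it is flagged by
    ``species.acyl.hydroxyls`` and handled as its own axis.
    """
    return f"C{species.acyl.carbons}"


def panel_table(species: list[SphingolipidSpecies], quant_levels: dict[str, int] | None = None):
    """Panel summary frame: name, head_class, spb, acyl, quant_level."""
    import pandas as pd

    rows = []
    for sp in species:
        rows.append(
            {
                "name": sp.name,
                "head_class": sp.head.class_label,
                "spb": classify_spb(sp),
                "acyl": classify_acyl(sp),
                "quant_level": (quant_levels or {}).get(sp.name, ""),
            }
        )
    return pd.DataFrame(rows)
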
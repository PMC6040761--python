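"""Glycan composition algebra for serum/plasma N-glycomics.

Compositions are counted in four building blocks: hexose (H), N-acetyl-
hexosamine (N), deoxyhexose/fucose (F) and N-acetylneuraminic acid (S).
PNGase F-released N-glycans share the N2H3 trimannosyl-chitobiose core,
so compositions with fewer than two HexNAc or three Hex are rejected at
parse/construction time.

Masses default to permethylated, sodiated ([M+Na]+, singly charged)
species, matching MALDI-TOF acquisition of permethylated glycans.  The
permethylated elemental formula adds one CH2 per derivatizable site; the
site count is a pure function of the composition (free hydroxyls and N-H
positions after glycosidic bonding, plus the two reducing-end sites).

The module also hosts the derived glycome traits (class and antennarity
fractions, total fucosylation/sialylation) and the GLYCOV ovarian-cancer
index: the mean relative intensity of seven sialylated high-mass glycans
divided by the mean of the four oligomannose intensities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GlycanError",
    "GlycanParseError",
    "GlycanDomainError",
    "UndefinedScoreError",
    "ElementalFormula",
    "GlycanComposition",
    "GlycanPanel",
    "TraitVector",
    "parse_composition",
    "elemental_formula",
    "methylation_sites",
    "formula_mass",
    "mono_mass",
    "decompose_mz",
    "classify",
    "normalize_profile",
    "traits",
    "glycov",
    "DEFAULT_CALIBRANTS",
    "PERMETHYLATED_RESIDUE_INCREMENTS",
    "PERMETHYLATED_REDUCING_END_INCREMENT",
]


class GlycanError(ValueError):
    """Base class for glycan domain errors."""


class GlycanParseError(GlycanError):
    """A composition label could not be parsed."""


class GlycanDomainError(GlycanError):
    """A composition violates the N-glycan core constraint."""


class UndefinedScoreError(GlycanError):
    """A score is undefined for this profile (zero denominator)."""


# Monoisotopic atomic masses (Da).
ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
}
ELECTRON_MASS = 0.00054857990907
PROTON_MASS = ATOMIC_MASS["H"] - ELECTRON_MASS
CH2_MASS = ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["H"]
WATER_MASS = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]


@dataclass(frozen=True)
class ElementalFormula:
    """Atom counts C/H/N/O; addition and integer scaling are component-wise."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0

    def __post_init__(self) -> None:
        if min(self.c, self.h, self.n, self.o) < 0:
            raise GlycanError(f"negative atom count in {self!r}")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            self.c + other.c, self.h + other.h, self.n + other.n, self.o + other.o
        )

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula(self.c * k, self.h * k, self.n * k, self.o * k)

    __rmul__ = __mul__

    def __str__(self) -> str:
        parts = []
        for sym, count in (("C", self.c), ("H", self.h), ("N", self.n), ("O", self.o)):
            if count:
                parts.append(f"{sym}{count}")
        return "".join(parts)


def formula_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass of a neutral formula in Da."""
    return (
        f.c * ATOMIC_MASS["C"]
        + f.h * ATOMIC_MASS["H"]
        + f.n * ATOMIC_MASS["N"]
        + f.o * ATOMIC_MASS["O"]
    )


# Residue (dehydrated monosaccharide) formulas.
RESIDUE_FORMULAS = {
    "hex": ElementalFormula(6, 10, 0, 5),
    "hexnac": ElementalFormula(8, 13, 1, 5),
    "fuc": ElementalFormula(6, 10, 0, 4),
    "neuac": ElementalFormula(11, 17, 1, 8),
}

# Methylation sites of each residue as a free monosaccharide (open count:
# hydroxyls incl. the anomeric position, N-H, and the NeuAc carboxyl methyl
# ester). Each glycosidic bond consumes one site on each partner.
FREE_RESIDUE_SITES = {"hex": 5, "hexnac": 5, "fuc": 4, "neuac": 7}

# Hand-copied building-block increments for permethylated residues (Da) and
# the free-reducing-end terminal increment (H2O + 2 CH2). These are
# configuration constants; the test suite validates them against the
# elemental-formula oracle.
PERMETHYLATED_RESIDUE_INCREMENTS = {
    "hex": 204.09977,
    "hexnac": 245.12632,
    "fuc": 174.08921,
    "neuac": 361.17367,
}
PERMETHYLATED_REDUCING_END_INCREMENT = 46.04186


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of HexNAc (N), Hex (H), deoxyhexose (F) and NeuAc (S).

    Field order gives lexicographic (N, H, F, S) ordering.
    """

    hexnac: int
    hex: int
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for name in ("hexnac", "hex", "fuc", "neuac"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise GlycanError(f"{name} count must be a non-negative integer, got {v!r}")
        if self.hexnac < 2 or self.hex < 3:
            raise GlycanDomainError(
                f"composition N{self.hexnac}H{self.hex} violates the N2H3 core "
                "constraint (hexnac >= 2 and hex >= 3)"
            )

    @property
    def residues(self) -> int:
        return self.hexnac + self.hex + self.fuc + self.neuac

    @property
    def label(self) -> str:
        """Canonical rendering N#H#F#S# with zero-count letters omitted."""
        out = f"N{self.hexnac}H{self.hex}"
        if self.fuc:
            out += f"F{self.fuc}"
        if self.neuac:
            out += f"S{self.neuac}"
        return out

    def __str__(self) -> str:
        return self.label


_TOKEN = re.compile(r"([HNFS])(\d+)")
_LETTER_FIELD = {"H": "hex", "N": "hexnac", "F": "fuc", "S": "neuac"}


def parse_composition(text: str) -> GlycanComposition:
    """Parse a composition label in either dialect (H5N4S2 or N4H5S2).

    Letters may appear in any order, each at most once; absent letters mean
    count zero.  Raises :class:`GlycanParseError` naming the offending token
    for malformed labels and :class:`GlycanDomainError` for compositions
    violating the N2H3 core.
    """
    if not isinstance(text, str) or not text.strip():
        raise GlycanParseError(f"empty or non-string label {text!r}")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None:
            raise GlycanParseError(f"malformed label {text!r}: unexpected token at {s[pos:]!r}")
        letter, num = m.group(1), int(m.group(2))
        field = _LETTER_FIELD[letter]
        if field in counts:
            raise GlycanParseError(f"malformed label {text!r}: letter {letter} repeated")
        counts[field] = num
        pos = m.end()
    return GlycanComposition(
        hexnac=counts.get("hexnac", 0),
        hex=counts.get("hex", 0),
        fuc=counts.get("fuc", 0),
        neuac=counts.get("neuac", 0),
    )


def methylation_sites(c: GlycanComposition) -> int:
    """Number of derivatizable sites of the free reducing glycan.

    Sum of free-residue sites minus two per glycosidic bond (the donor
    anomeric hydroxyl and the acceptor hydroxyl), with residues - 1 bonds.
    """
    total = (
        c.hex * FREE_RESIDUE_SITES["hex"]
        + c.hexnac * FREE_RESIDUE_SITES["hexnac"]
        + c.fuc * FREE_RESIDUE_SITES["fuc"]
        + c.neuac * FREE_RESIDUE_SITES["neuac"]
    )
    return total - 2 * (c.residues - 1)


def elemental_formula(c: GlycanComposition, permethylated: bool = False) -> ElementalFormula:
    """Elemental formula of the (optionally permethylated) free glycan."""
    f = (
        c.hex * RESIDUE_FORMULAS["hex"]
        + c.hexnac * RESIDUE_FORMULAS["hexnac"]
        + c.fuc * RESIDUE_FORMULAS["fuc"]
        + c.neuac * RESIDUE_FORMULAS["neuac"]
        + ElementalFormula(0, 2, 0, 1)  # + H2O
    )
    if permethylated:
        f = f + methylation_sites(c) * ElementalFormula(1, 2, 0, 0)
    return f


def mono_mass(
    c: GlycanComposition, adduct: str | None = "Na", permethylated: bool = True
) -> float:
    """Monoisotopic m/z of the singly charged (or neutral) species.

    adduct 'Na' and 'H' add the cation mass minus the electron mass;
    adduct None (or 'none') returns the neutral monoisotopic mass.
    """
    m = formula_mass(elemental_formula(c, permethylated=permethylated))
    if adduct is None or adduct == "none":
        return m
    if adduct == "Na":
        return m + ATOMIC_MASS["Na"] - ELECTRON_MASS
    if adduct == "H":
        return m + PROTON_MASS
    raise GlycanError(f"unknown adduct {adduct!r}")


@lru_cache(maxsize=8)
def _composition_grid(
    bounds: tuple[int, int, int, int], adduct: str | None, permethylated: bool
) -> tuple[np.ndarray, tuple[GlycanComposition, ...]]:
    """All core-valid compositions within bounds with their m/z, mass-sorted."""
    hmax, nmax, fmax, smax = bounds
    comps = []
    masses = []
    base = mono_mass(GlycanComposition(2, 3), adduct=adduct, permethylated=permethylated)

    # residue m/z increments via additivity of the elemental formula
    def _inc(field: str) -> float:
        kwargs = dict(hexnac=2, hex=3, fuc=0, neuac=0)
        kwargs[field] += 1
        return (
            mono_mass(GlycanComposition(**kwargs), adduct=adduct, permethylated=permethylated)
            - base
        )

    d_hex, d_nac, d_fuc, d_sia = _inc("hex"), _inc("hexnac"), _inc("fuc"), _inc("neuac")
    for n in range(2, nmax + 1):
        for h in range(3, hmax + 1):
            for f in range(0, fmax + 1):
                for s in range(0, smax + 1):
                    comps.append(GlycanComposition(n, h, f, s))
                    masses.append(
                        base + (h - 3) * d_hex + (n - 2) * d_nac + f * d_fuc + s * d_sia
                    )
    order = np.argsort(masses, kind="stable")
    return np.asarray(masses)[order], tuple(comps[i] for i in order)


def decompose_mz(
    mz: float,
    window: float = 0.49,
    bounds: tuple[int, int, int, int] = (12, 8, 5, 5),
    adduct: str | None = "Na",
    permethylated: bool = True,
) -> list[GlycanComposition]:
    """Compositions whose theoretical m/z lies within ±window/2 of *mz*.

    *bounds* are maximum counts (H, N, F, S).  Results satisfy the N2H3 core
    constraint and are returned in lexicographic (N, H, F, S) order; an empty
    list is a valid result.
    """
    if window <= 0:
        raise GlycanError("window must be positive")
    masses, comps = _composition_grid(tuple(bounds), adduct, permethylated)
    lo = np.searchsorted(masses, mz - window / 2.0, side="left")
    hi = np.searchsorted(masses, mz + window / 2.0, side="right")
    return sorted(comps[lo:hi])


def classify(
    c: GlycanComposition, panel: "GlycanPanel | None" = None
) -> tuple[str, int]:
    """Structural class and antenna count of a composition.

    When *panel* is given and contains the analyte, the fixture assignment
    wins; otherwise the composition rule applies: hexnac=2 & hex>=5 is
    oligomannose, hexnac=3 & hex>=5 & neuac<=1 is hybrid, anything else is
    complex with antennae = min(hexnac - 2, 4).  Bisecting GlcNAc cannot be
    told apart from an antenna by composition alone and is ignored.
    """
    if panel is not None and c.label in panel.table.index:
        row = panel.table.loc[c.label]
        return str(row["class"]), int(row["antennae"])
    if c.hexnac == 2 and c.hex >= 5:
        return "oligomannose", 0
    if c.hexnac == 3 and c.hex >= 5 and c.neuac <= 1:
        return "hybrid", 1
    return "complex", min(c.hexnac - 2, 4)


_PANEL_CLASSES = ("oligomannose", "hybrid", "complex")


class GlycanPanel:
    """Ordered analyte panel with classes, antennae and GLYCOV membership.

    Wraps a table indexed by canonical analyte label with columns
    hex/hexnac/fuc/neuac/class/antennae/in_glycov_numerator/
    in_glycov_denominator and (optionally) reference_intensity.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "analyte_label" in table.columns:
            labels = [parse_composition(t).label for t in table["analyte_label"]]
            table.index = pd.Index(labels, name="analyte_label")
            table = table.drop(columns=["analyte_label"])
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].tolist()
            raise GlycanError(f"duplicate panel analytes: {dups}")
        bad = set(table["class"]) - set(_PANEL_CLASSES)
        if bad:
            raise GlycanError(f"unknown glycan classes: {sorted(bad)}")
        # validate compositions against their labels
        for label, row in table.iterrows():
            c = GlycanComposition(
                int(row["hexnac"]), int(row["hex"]), int(row["fuc"]), int(row["neuac"])
            )
            if c.label != label:
                raise GlycanError(f"panel row {label} disagrees with counts {c.label}")
        self.table = table

    @classmethod
    def from_csv(cls, path) -> "GlycanPanel":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def default(cls) -> "GlycanPanel":
        with resources.files("glypre.data").joinpath("panel.csv").open() as fh:
            return cls(pd.read_csv(fh, comment="#"))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return list(self.table.index)

    @property
    def compositions(self) -> list[GlycanComposition]:
        return [
            GlycanComposition(int(r["hexnac"]), int(r["hex"]), int(r["fuc"]), int(r["neuac"]))
            for _, r in self.table.iterrows()
        ]

    def composition(self, label: str) -> GlycanComposition:
        r = self.table.loc[label]
        return GlycanComposition(int(r["hexnac"]), int(r["hex"]), int(r["fuc"]), int(r["neuac"]))

    @property
    def glycov_numerator(self) -> list[str]:
        return list(self.table.index[self.table["in_glycov_numerator"] == 1])

    @property
    def glycov_denominator(self) -> list[str]:
        return list(self.table.index[self.table["in_glycov_denominator"] == 1])

    def reference_profile(self) -> pd.Series:
        """Reference median relative intensities, normalized to sum 1."""
        if "reference_intensity" not in self.table.columns:
            raise GlycanError("panel fixture has no reference_intensity column")
        return normalize_profile(self.table["reference_intensity"].astype(float))

    def desialylated_labels(self) -> pd.Series:
        """Per-analyte label after sialic acid removal (S dropped, core kept)."""
        out = {}
        for label in self.table.index:
            c = self.composition(label)
            out[label] = GlycanComposition(c.hexnac, c.hex, c.fuc, 0).label
        return pd.Series(out, name="desialylated")


def normalize_profile(p: Mapping[str, float] | pd.Series) -> pd.Series:
    """Rescale intensities to sum 1; rejects negatives and zero totals."""
    s = pd.Series(p, dtype=float)
    if (s < 0).any():
        raise GlycanError("profile has negative intensities")
    total = float(s.sum())
    if not np.isfinite(total) or total <= 0:
        raise GlycanError("profile total is zero or non-finite; cannot normalize")
    return s / total


def _check_normalized(p: pd.Series) -> None:
    if abs(float(p.sum()) - 1.0) > 1e-6:
        raise GlycanError(f"profile is not normalized (sum={float(p.sum()):.6g})")


@dataclass(frozen=True)
class TraitVector:
    """Derived glycome traits as fractions of the total profile."""

    complex: float
    oligomannose: float
    hybrid: float
    monoantennary: float
    diantennary: float
    triantennary: float
    tetraantennary: float
    fucosylation: float
    sialylation: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def traits(p: Mapping[str, float] | pd.Series, panel: GlycanPanel | None = None) -> TraitVector:
    """Class, antennarity (within complex), fucosylation and sialylation traits.

    The profile must be normalized; every panel analyte absent from the
    profile is treated as 0, but analytes in the profile missing from the
    panel are an error.
    """
    panel = panel or GlycanPanel.default()
    s = pd.Series(p, dtype=float)
    _check_normalized(s)
    unknown = set(s.index) - set(panel.labels)
    if unknown:
        raise GlycanError(f"profile analytes not in panel: {sorted(unknown)}")
    s = s.reindex(panel.labels, fill_value=0.0)
    t = panel.table
    cls = t["class"]
    is_complex = (cls == "complex").to_numpy()
    vals = s.to_numpy()

    def frac(mask) -> float:
        return float(vals[np.asarray(mask)].sum())

    ant = t["antennae"].to_numpy()
    return TraitVector(
        complex=frac(is_complex),
        oligomannose=frac((cls == "oligomannose").to_numpy()),
        hybrid=frac((cls == "hybrid").to_numpy()),
        monoantennary=frac(is_complex & (ant == 1)),
        diantennary=frac(is_complex & (ant == 2)),
        triantennary=frac(is_complex & (ant == 3)),
        tetraantennary=frac(is_complex & (ant == 4)),
        fucosylation=frac((t["fuc"] >= 1).to_numpy()),
        sialylation=frac((t["neuac"] >= 1).to_numpy()),
    )


def glycov(p: Mapping[str, float] | pd.Series, panel: GlycanPanel | None = None) -> float:
    """GLYCOV ovarian-cancer index of a glycome profile.

    mean relative intensity of the seven sialylated high-mass analytes over
    the mean of the four oligomannose analytes (evaluated as
    (sum numerators)/7 * 4/(sum denominators), the printed form).  Scale
    invariant, so the profile need not be normalized.
    """
    panel = panel or GlycanPanel.default()
    s = pd.Series(p, dtype=float)
    num_labels, den_labels = panel.glycov_numerator, panel.glycov_denominator
    for label in (*num_labels, *den_labels):
        if label not in s.index:
            raise GlycanError(f"GLYCOV analyte {label} missing from profile")
    num = float(s[num_labels].sum())
    den = float(s[den_labels].sum())
    if den <= 0:
        raise UndefinedScoreError("GLYCOV undefined: oligomannose denominator sum is zero")
    return (num / len(num_labels)) * len(den_labels) / den


# The nine recalibration compositions, as printed (H#N# dialect).
DEFAULT_CALIBRANTS: tuple[GlycanComposition, ...] = tuple(
    parse_composition(t)
    for t in (
        "H3N4F1",
        "H4N4F1",
        "H5N4F1",
        "H5N4S1",
        "H5N5F1S1",
        "H5N4S2",
        "H6N5S3",
        "H6N5F1S3",
        "H7N6S4",
    )
)
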
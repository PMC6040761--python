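"""Composition parsing, mass calculus, classification, traits and GLYCOV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glypre.glycans import (
    ATOMIC_MASS,
    DEFAULT_CALIBRANTS,
    ELECTRON_MASS,
    PERMETHYLATED_REDUCING_END_INCREMENT,
    PERMETHYLATED_RESIDUE_INCREMENTS,
    ElementalFormula,
    GlycanComposition,
    GlycanDomainError,
    GlycanError,
    GlycanParseError,
    UndefinedScoreError,
    classify,
    decompose_mz,
    elemental_formula,
    formula_mass,
    glycov,
    methylation_sites,
    mono_mass,
    normalize_profile,
    parse_composition,
    traits,
)

# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "label, expected",
    [
        ("H5N4S2", (4, 5, 0, 2)),
        ("N4H5S2", (4, 5, 0, 2)),
        ("N2H5", (2, 5, 0, 0)),
        ("H5N2", (2, 5, 0, 0)),
        ("H3N4F1", (4, 3, 1, 0)),
        ("H6N5F1S3", (5, 6, 1, 3)),
        ("N6H7S4F2", (6, 7, 2, 4)),  # S-before-F dialect
    ],
)
def test_parse_both_dialects(label, expected):
    c = parse_composition(label)
    assert (c.hexnac, c.hex, c.fuc, c.neuac) == expected


@pytest.mark.parametrize("bad", ["", "abc", "H5N4X2", "N4 H5", "H5N4F", "N4N4H5"])
def test_parse_malformed_labels(bad):
    with pytest.raises(GlycanParseError):
        parse_composition(bad)


@pytest.mark.parametrize("bad", ["N2H2", "N1H5", "H3N1", "F1S1"])
def test_parse_core_violations(bad):
    with pytest.raises(GlycanDomainError):
        parse_composition(bad)


composition_strategy = st.builds(
    GlycanComposition,
    hexnac=st.integers(2, 8),
    hex=st.integers(3, 12),
    fuc=st.integers(0, 5),
    neuac=st.integers(0, 5),
)


@settings(max_examples=200, derandomize=True)
@given(composition_strategy)
def test_parse_render_roundtrip(c):
    assert parse_composition(c.label) == c
    # the H-first dialect maps to the same composition
    alt = f"H{c.hex}N{c.hexnac}"
    if c.fuc:
        alt += f"F{c.fuc}"
    if c.neuac:
        alt += f"S{c.neuac}"
    assert parse_composition(alt) == c


# ---------------------------------------------------------------------------
# Elemental formulas and permethylation sites
# ---------------------------------------------------------------------------

def test_elemental_formula_core_pentasaccharide():
    # 3 Hex + 2 HexNAc + H2O, summed by hand:
    # C: 3*6+2*8=34, H: 3*10+2*13+2=58, N: 2, O: 3*5+2*5+1=26
    f = elemental_formula(parse_composition("N2H3"))
    assert (f.c, f.h, f.n, f.o) == (34, 58, 2, 26)


def test_methylation_site_count_core():
    # manual enumeration on the drawn N2H3 structure: 5 sites per free Hex,
    # 5 per free HexNAc (4 OH + NH), minus 2 per each of the 4 glycosidic
    # bonds = 15 + 10 - 8 = 17
    assert methylation_sites(parse_composition("N2H3")) == 17


@settings(max_examples=100, derandomize=True)
@given(composition_strategy)
def test_permethylation_adds_one_ch2_per_site(c):
    native = elemental_formula(c, permethylated=False)
    perm = elemental_formula(c, permethylated=True)
    sites = methylation_sites(c)
    assert perm.c - native.c == sites
    assert perm.h - native.h == 2 * sites
    assert (perm.n, perm.o) == (native.n, native.o)


def test_residue_increment_constants_match_formula_oracle():
    """The hand-copied building-block masses must agree with the formulas."""
    ch2 = ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["H"]
    net_sites = {"hex": 3, "hexnac": 3, "fuc": 2, "neuac": 5}
    residue = {
        "hex": ElementalFormula(6, 10, 0, 5),
        "hexnac": ElementalFormula(8, 13, 1, 5),
        "fuc": ElementalFormula(6, 10, 0, 4),
        "neuac": ElementalFormula(11, 17, 1, 8),
    }
    for name, inc in PERMETHYLATED_RESIDUE_INCREMENTS.items():
        oracle = formula_mass(residue[name]) + net_sites[name] * ch2
        assert inc == pytest.approx(oracle, abs=1e-3)
    water = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]
    assert PERMETHYLATED_REDUCING_END_INCREMENT == pytest.approx(water + 2 * ch2, abs=1e-3)


# ---------------------------------------------------------------------------
# Monoisotopic masses
# ---------------------------------------------------------------------------

# Independent atom-count oracle with its own masses (CODATA), deliberately
# duplicated from the implementation.
_ORACLE_MASS = {"C": 12.0, "H": 1.007825032, "N": 14.003074005, "O": 15.994914620}


def _oracle_sodiated_permethylated(c: GlycanComposition) -> float:
    atoms = {"C": 0, "H": 0, "N": 0, "O": 0}
    per_residue = {
        "hex": ((6, 10, 0, 5), c.hex),
        "hexnac": ((8, 13, 1, 5), c.hexnac),
        "fuc": ((6, 10, 0, 4), c.fuc),
        "neuac": ((11, 17, 1, 8), c.neuac),
    }
    for (nc, nh, nn, no), count in per_residue.values():
        atoms["C"] += nc * count
        atoms["H"] += nh * count
        atoms["N"] += nn * count
        atoms["O"] += no * count
    atoms["H"] += 2
    atoms["O"] += 1
    sites = 5 * c.hex + 5 * c.hexnac + 4 * c.fuc + 7 * c.neuac - 2 * (c.residues - 1)
    atoms["C"] += sites
    atoms["H"] += 2 * sites
    m = sum(_ORACLE_MASS[k] * v for k, v in atoms.items())
    return m + 22.989769281 - 0.000548580


def test_mono_mass_matches_atom_count_oracle(panel):
    for c in panel.compositions:
        assert mono_mass(c) == pytest.approx(_oracle_sodiated_permethylated(c), abs=1e-3)


def test_mono_mass_literature_anchor():
    # permethylated disialylated biantennary glycan, sodiated
    assert mono_mass(parse_composition("H5N4S2")) == pytest.approx(2792.38, abs=0.01)


def test_mono_mass_residue_additivity():
    """Adding one NeuAc shifts the mass by the same increment everywhere."""
    inc = None
    for base in ("N4H5", "N5H6F1", "N2H5"):
        c0 = parse_composition(base)
        c1 = GlycanComposition(c0.hexnac, c0.hex, c0.fuc, c0.neuac + 1)
        d = mono_mass(c1) - mono_mass(c0)
        if inc is None:
            inc = d
        assert d == pytest.approx(inc, abs=1e-9)
    assert inc == pytest.approx(PERMETHYLATED_RESIDUE_INCREMENTS["neuac"], abs=1e-3)


@settings(max_examples=100, derandomize=True)
@given(composition_strategy, st.sampled_from(["hexnac", "hex", "fuc", "neuac"]))
def test_mono_mass_strictly_increases_with_counts(c, field):
    kwargs = dict(hexnac=c.hexnac, hex=c.hex, fuc=c.fuc, neuac=c.neuac)
    kwargs[field] += 1
    assert mono_mass(GlycanComposition(**kwargs)) > mono_mass(c)


def test_mono_mass_unknown_adduct():
    with pytest.raises(GlycanError):
        mono_mass(parse_composition("N2H5"), adduct="K")


def test_panel_masses_within_acquisition_range(panel):
    masses = [mono_mass(c) for c in panel.compositions]
    assert min(masses) >= 1000 and max(masses) <= 5000


# ---------------------------------------------------------------------------
# m/z decomposition
# ---------------------------------------------------------------------------

def _oracle_decompose(mz, window=0.49, bounds=(12, 8, 5, 5)):
    hmax, nmax, fmax, smax = bounds
    out = []
    for n in range(2, nmax + 1):
        for h in range(3, hmax + 1):
            for f in range(fmax + 1):
                for s in range(smax + 1):
                    c = GlycanComposition(n, h, f, s)
                    if abs(_oracle_sodiated_permethylated(c) - mz) <= window / 2:
                        out.append(c)
    return sorted(out)


def test_decompose_round_trip(panel):
    for c in panel.compositions:
        assert c in decompose_mz(mono_mass(c))


def test_decompose_below_panel_masses_is_empty():
    assert decompose_mz(500.0) == []


def test_decompose_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for mz in rng.uniform(1000.0, 5000.0, size=100):
        assert decompose_mz(float(mz)) == _oracle_decompose(float(mz))


def test_decompose_rejects_bad_window():
    with pytest.raises(GlycanError):
        decompose_mz(2000.0, window=0.0)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "label, cls, antennae",
    [
        ("N2H6", "oligomannose", 0),
        ("N4H5S2", "complex", 2),
        ("H5N4S2", "complex", 2),
        ("N3H5S1", "hybrid", 1),
        ("N3H7", "hybrid", 1),      # rule fallback, not in panel
        ("N7H8", "complex", 4),     # antennae capped at 4
    ],
)
def test_classify(panel, label, cls, antennae):
    assert classify(parse_composition(label), panel) == (cls, antennae)


def test_panel_class_counts_match_reported_groups(panel):
    t = panel.table
    assert (t["class"] == "oligomannose").sum() == 4
    assert ((t["class"] == "complex") & (t["fuc"] >= 1) & (t["neuac"] == 0)).sum() == 7
    assert ((t["class"] == "complex") & (t["fuc"] >= 1) & (t["neuac"] >= 1)).sum() == 14
    assert len(t) == 46


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def test_traits_all_mass_on_oligomannose(panel):
    p = pd.Series(0.0, index=panel.labels)
    p["N2H5"] = 1.0
    t = traits(p, panel)
    assert t.oligomannose == 1.0 and t.complex == 0.0


def test_traits_uniform_profile_counts_classes(panel):
    p = pd.Series(1.0 / 46, index=panel.labels)
    t = traits(p, panel)
    counts = panel.table["class"].value_counts()
    assert t.complex == pytest.approx(counts["complex"] / 46, abs=1e-12)
    assert t.oligomannose == pytest.approx(counts["oligomannose"] / 46, abs=1e-12)
    assert t.hybrid == pytest.approx(counts["hybrid"] / 46, abs=1e-12)


def test_traits_match_independent_loop_and_conserve(panel, rng):
    raw = rng.dirichlet(np.ones(46))
    p = pd.Series(raw, index=panel.labels)
    t = traits(p, panel)
    # independent per-analyte summation
    acc = {"complex": 0.0, "oligomannose": 0.0, "hybrid": 0.0,
           "fuc": 0.0, "sia": 0.0, 1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
    for label in panel.labels:
        row = panel.table.loc[label]
        acc[row["class"]] += p[label]
        if row["fuc"] >= 1:
            acc["fuc"] += p[label]
        if row["neuac"] >= 1:
            acc["sia"] += p[label]
        if row["class"] == "complex":
            acc[int(row["antennae"])] += p[label]
    assert t.complex == pytest.approx(acc["complex"], abs=1e-12)
    assert t.fucosylation == pytest.approx(acc["fuc"], abs=1e-12)
    assert t.sialylation == pytest.approx(acc["sia"], abs=1e-12)
    for k, v in zip((1, 2, 3, 4), (t.monoantennary, t.diantennary,
                                   t.triantennary, t.tetraantennary)):
        assert v == pytest.approx(acc[k], abs=1e-12)
    assert t.complex + t.oligomannose + t.hybrid == pytest.approx(1.0, abs=1e-9)
    ant_sum = t.monoantennary + t.diantennary + t.triantennary + t.tetraantennary
    assert ant_sum == pytest.approx(t.complex, abs=1e-9)


def test_traits_rejects_unnormalized(panel):
    p = pd.Series(2.0 / 46, index=panel.labels)
    with pytest.raises(GlycanError):
        traits(p, panel)


# ---------------------------------------------------------------------------
# GLYCOV
# ---------------------------------------------------------------------------

def test_glycov_equal_intensities_is_one(panel):
    members = panel.glycov_numerator + panel.glycov_denominator
    assert len(panel.glycov_numerator) == 7 and len(panel.glycov_denominator) == 4
    p = pd.Series(0.05, index=members)
    assert glycov(p, panel) == pytest.approx(1.0, abs=1e-12)


def test_glycov_zero_numerators(panel):
    p = pd.Series(0.0, index=panel.glycov_numerator + panel.glycov_denominator)
    p[panel.glycov_denominator] = 0.02
    assert glycov(p, panel) == 0.0


def test_glycov_hand_evaluated_example(panel):
    # numerators 0.005 each, denominators 0.035 each:
    # (7*0.005)/7 * 4/(4*0.035) = 0.005/0.035 = 1/7
    p = pd.Series(0.005, index=panel.glycov_numerator)
    p = pd.concat([p, pd.Series(0.035, index=panel.glycov_denominator)])
    assert glycov(p, panel) == pytest.approx(1.0 / 7.0, abs=1e-12)


def test_glycov_scale_invariance(panel, rng):
    p = pd.Series(rng.uniform(0.001, 0.1, size=46), index=panel.labels)
    base = glycov(p, panel)
    for k in (0.1, 3.0, 1e4):
        assert glycov(k * p, panel) == pytest.approx(base, rel=1e-12)


def test_glycov_zero_denominator_error(panel):
    p = pd.Series(0.01, index=panel.labels)
    p[panel.glycov_denominator] = 0.0
    with pytest.raises(UndefinedScoreError):
        glycov(p, panel)


def test_glycov_missing_analyte_named(panel):
    p = pd.Series(0.01, index=[l for l in panel.labels if l != "N2H7"])
    with pytest.raises(GlycanError, match="N2H7"):
        glycov(p, panel)


def test_calibrants_are_panel_members(panel):
    for c in DEFAULT_CALIBRANTS:
        assert c.label in panel.labels


def test_normalize_profile_errors():
    with pytest.raises(GlycanError):
        normalize_profile(pd.Series([0.0, 0.0]))
    with pytest.raises(GlycanError):
        normalize_profile(pd.Series([1.0, -0.1]))
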
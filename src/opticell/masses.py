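"""Monoisotopic ion masses for the lipid and pigment species used as class markers.

Galactolipids (MGDG, DGDG) and phosphatidylcholines (PC) are denoted by the
total acyl carbon:double-bond count (e.g. ``34:7``) and observed as ammonium
adducts [M+NH4]+, the usual positive-mode ESI adduct for neutral glycerolipids.
Photosynthetic pigments (chlorophyll a/b, pyropheophytin a) are observed
protonated, [M+H]+.

All m/z values are computed at call time from elemental formulas; nothing is
hard-coded.
"""

from __future__ import annotations

from pyteomics import mass as _ptmass

# Chemical formula templates; c = total acyl carbons, d = total double bonds.
# Derived from the glycerolipid backbone + headgroup with two esterified acyl
# chains: each double bond removes two hydrogens.


def mgdg_formula(c: int, d: int) -> str:
    """Monogalactosyldiacylglycerol C(9+c) H(14+2c-2d) O10."""
    return f"C{9 + c}H{14 + 2 * c - 2 * d}O10"


def dgdg_formula(c: int, d: int) -> str:
    """Digalactosyldiacylglycerol C(15+c) H(24+2c-2d) O15."""
    return f"C{15 + c}H{24 + 2 * c - 2 * d}O15"


def pc_formula(c: int, d: int) -> str:
    """Phosphatidylcholine C(8+c) H(16+2c-2d) N O8 P."""
    return f"C{8 + c}H{16 + 2 * c - 2 * d}NO8P"


PIGMENT_FORMULAS = {
    "chlorophyll a": "C55H72MgN4O5",
    "chlorophyll b": "C55H70MgN4O6",
    # pheophytin a minus the C-13(2) carbomethoxy group
    "pyropheophytin a": "C53H72N4O3",
}


def protonated_mz(formula: str) -> float:
    """m/z of [M+H]+ for a neutral formula."""
    return _ptmass.calculate_mass(formula=formula, charge=1)


def ammonium_adduct_mz(formula: str) -> float:
    """m/z of [M+NH4]+ for a neutral formula (add NH3, then protonate)."""
    return _ptmass.calculate_mass(formula=formula + "NH3", charge=1)


def lipid_mz(kind: str, c: int, d: int) -> float:
    """[M+NH4]+ m/z for an MGDG / DGDG / PC lipid given acyl carbons:double bonds."""
    builders = {"MGDG": mgdg_formula, "DGDG": dgdg_formula, "PC": pc_formula}
    try:
        formula = builders[kind.upper()](c, d)
    except KeyError:
        raise ValueError(f"unknown lipid class {kind!r}; expected MGDG, DGDG or PC")
    return ammonium_adduct_mz(formula)


def pigment_mz(name: str) -> float:
    """[M+H]+ m/z for a named photosynthetic pigment."""
    try:
        formula = PIGMENT_FORMULAS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown pigment {name!r}; known: {sorted(PIGMENT_FORMULAS)}"
        )
    return protonated_mz(formula)
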
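"""Monoisotopic and nominal mass arithmetic for sodiated glycan ions.

All observable quantities in unit-resolution ion-trap CID are nominal
(integer) m/z values of singly charged sodium adducts; this module keeps the
underlying arithmetic exact (monoisotopic, electron-corrected) and rounds
only at the reporting boundary.  Isotope labels are carried inside elemental
compositions using pyteomics' ``O[18]`` convention, so a heavy oxygen shifts
every mass containing it by exactly m(18O) - m(16O).
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Tuple

from pyteomics import mass as _pmass

if TYPE_CHECKING:  # pragma: no cover
    from .glycans import Glycan

Composition = _pmass.Composition

#: Token used for heavy oxygen inside compositions.
O18 = "O[18]"

_NIST = _pmass.nist_mass


class ElementMassTable:
    """CODATA/IUPAC monoisotopic masses used throughout the package."""

    H: float = _NIST["H"][1][0]
    C: float = _NIST["C"][12][0]
    N: float = _NIST["N"][14][0]
    O: float = _NIST["O"][16][0]
    O18: float = _NIST["O"][18][0]
    Na: float = _NIST["Na"][23][0]
    electron: float = 0.000548579909  # CODATA electron mass, Da

    #: mass shift introduced by a single 18O label (~2.0042 Da)
    O18_SHIFT: float = O18 - O


#: supported singly charged adducts -> neutral adduct mass
ADDUCT_MASS = {"Na+": ElementMassTable.Na, "H+": ElementMassTable.H}


def composition(formula: str = "", **kwargs) -> Composition:
    """Build an elemental composition (thin wrapper over pyteomics)."""
    return Composition(formula=formula, **kwargs)


def composition_mass(comp: Composition) -> float:
    """Monoisotopic mass of an elemental composition in Da."""
    return _pmass.calculate_mass(composition=comp)


def nominal(mz: float) -> int:
    """Nominal (unit-resolution) mass: nearest integer of the monoisotopic value."""
    return int(round(mz))


def neutral_mass(g: "Glycan") -> float:
    """Monoisotopic neutral mass of a glycan in Da (labels included)."""
    return composition_mass(g.neutral_composition())


def precursor_mz(g: "Glycan", adduct: str | None = None) -> Tuple[float, int]:
    """(monoisotopic, nominal) m/z of the singly charged adduct ion."""
    adduct = adduct or g.adduct
    return ion_mz(g.neutral_composition(), adduct)


def ion_mz(neutral_comp: Composition, adduct: str = "Na+") -> Tuple[float, int]:
    """m/z of a singly charged cation formed by adduction of ``adduct``.

    The electron mass is subtracted: correct at the 1e-3 Da level even though
    nominal values are insensitive to it.
    """
    try:
        am = ADDUCT_MASS[adduct]
    except KeyError:
        raise ValueError(f"unsupported adduct {adduct!r}") from None
    mono = composition_mass(neutral_comp) + am - ElementMassTable.electron
    return mono, nominal(mono)


def loss_mass(comp: Composition) -> Tuple[float, int]:
    """(monoisotopic, nominal) mass of a neutral-loss composition."""
    if any(v < 0 for v in comp.values()):
        raise ValueError("neutral-loss composition must be non-negative")
    mono = composition_mass(comp)
    return mono, nominal(mono)


def label_count(comp: Composition) -> int:
    """Number of 18O atoms in a composition."""
    return comp.get(O18, 0)
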
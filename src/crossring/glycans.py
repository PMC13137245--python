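"""Data model and parser for sodiated (oligo)saccharides with isotope labels.

Glycans are written in a minimal condensed dialect: residue tokens joined by
anomeric configuration + linkage (``Manb1-2Manb``), branches in square
brackets preceding their parent (``Mana1-6[Mana1-3]GlcNAcb``), and optional
reducing-end suffixes ``-OMe`` (methyl glycoside) and ``-18O1`` (heavy oxygen
at O1).  The rightmost residue is the reducing end.  Unicode strings in the
``GlcNAcβ-(1→2)-Man`` style are normalised and accepted verbatim.

Stereochemistry is carried as a name tag only: Glc, Man and Gal are
mass-identical hexoses and the fragmentation rules depend only on the
carbonyl position and the substitution pattern, not on the epimer.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

from . import masses
from .masses import Composition, O18

__all__ = [
    "Monosaccharide",
    "Linkage",
    "Glycan",
    "GlycanError",
    "parse_glycan",
    "serialize_glycan",
    "residue_formula",
]


class GlycanError(ValueError):
    """Raised for malformed glycan strings or invalid structures."""


#: residue token -> (carbon count, carbonyl position, substituents)
_RESIDUE_DEFS: Dict[str, Tuple[int, int, Dict[int, str]]] = {
    "Glc": (6, 1, {}),
    "Man": (6, 1, {}),
    "Gal": (6, 1, {}),
    "Fru": (6, 2, {}),
    "GlcNAc": (6, 1, {2: "NAc"}),
    "GalNAc": (6, 1, {2: "NAc"}),
}

#: composition deltas of substituents relative to a plain hydroxyl position
_SUBSTITUENT_DELTA = {
    "NAc": Composition(formula="C2H3N"),  # OH -> NH-C(=O)-CH3 (O count unchanged)
    "OMe": Composition(formula="CH2"),  # OH -> OCH3
}

_HEXOSE_FREE = Composition(formula="C6H12O6")
_H2O = Composition(formula="H2O")


@dataclass
class Monosaccharide:
    """One residue: a pyranose ring with numbered carbons C1..C6.

    ``oxygen_labels`` maps oxygen position -> isotope token (only ``"18O"`` is
    meaningful here); ``substituents`` maps position -> token (``NAc``,
    ``OMe``).  Children attach through a glycosidic bond at one of this
    residue's oxygens (recorded on the :class:`Linkage` edge).
    """

    name: str
    anomeric_config: str = "none"  # "a" | "b" | "none"
    oxygen_labels: Dict[int, str] = field(default_factory=dict)
    extra_substituents: Dict[int, str] = field(default_factory=dict)
    children: List[Tuple["Linkage", "Monosaccharide"]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.name not in _RESIDUE_DEFS:
            raise GlycanError(f"unknown residue token {self.name!r}")
        for pos in list(self.oxygen_labels) + list(self.extra_substituents):
            if not 1 <= pos <= self.carbon_count:
                raise GlycanError(f"position {pos} out of range for {self.name}")

    @property
    def carbon_count(self) -> int:
        return _RESIDUE_DEFS[self.name][0]

    @property
    def carbonyl_position(self) -> int:
        """1 for aldoses, 2 for ketoses (= the anomeric carbon)."""
        return _RESIDUE_DEFS[self.name][1]

    @property
    def substituents(self) -> Dict[int, str]:
        subs = dict(_RESIDUE_DEFS[self.name][2])
        subs.update(self.extra_substituents)
        return subs

    @property
    def attachment_positions(self) -> frozenset:
        """Oxygen positions bearing glycosidic links to child residues."""
        return frozenset(l.parent_oxygen_position for l, _ in self.children)

    def iter_subtree(self) -> Iterator["Monosaccharide"]:
        yield self
        for _, child in self.children:
            yield from child.iter_subtree()


@dataclass(frozen=True)
class Linkage:
    """Glycosidic bond: child's anomeric carbon -> parent oxygen position."""

    child_anomeric_carbon: int
    parent_oxygen_position: int
    anomeric_config: str = "none"

    def __post_init__(self) -> None:
        if self.parent_oxygen_position not in (2, 3, 4, 6):
            raise GlycanError(
                f"invalid linkage position {self.parent_oxygen_position}"
            )


@dataclass
class Glycan:
    """A rooted residue tree; the root is the reducing-end residue."""

    root: Monosaccharide
    adduct: str = "Na+"

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        seen = set()
        for r in self.root.iter_subtree():
            if id(r) in seen:
                raise GlycanError("cyclic residue reference")
            seen.add(id(r))
            for link, child in r.children:
                if link.child_anomeric_carbon != child.carbonyl_position:
                    raise GlycanError(
                        "child must link through its anomeric carbon"
                    )
                if link.parent_oxygen_position in r.oxygen_labels:
                    raise GlycanError("label on a glycosylated oxygen")
            for pos, sub in r.substituents.items():
                if sub == "OMe" and pos in r.attachment_positions:
                    raise GlycanError(
                        "a position may not carry both a glycosidic link and OMe"
                    )

    @property
    def residues(self) -> List[Monosaccharide]:
        return list(self.root.iter_subtree())

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def reducing_end_free(self) -> bool:
        """True if the anomeric oxygen of the root is free to ring-open."""
        r = self.root
        pos = r.carbonyl_position
        return (
            pos not in r.substituents
            and pos not in r.attachment_positions
        )

    # -- composition -------------------------------------------------------
    def neutral_composition(self) -> Composition:
        comp = Composition()
        for r in self.root.iter_subtree():
            comp += residue_formula(r, as_residue=True)
        comp += _H2O
        return comp

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(r: Monosaccharide) -> dict:
            return {
                "name": r.name,
                "anomeric": r.anomeric_config,
                "labels": {str(k): v for k, v in r.oxygen_labels.items()},
                "substituents": {str(k): v for k, v in r.extra_substituents.items()},
                "children": [
                    {
                        "linkage": [l.child_anomeric_carbon, l.parent_oxygen_position,
                                    l.anomeric_config],
                        "residue": enc(c),
                    }
                    for l, c in r.children
                ],
            }

        return {"adduct": self.adduct, "root": enc(self.root)}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "Glycan":
        def dec(node: dict) -> Monosaccharide:
            r = Monosaccharide(
                name=node["name"],
                anomeric_config=node.get("anomeric", "none"),
                oxygen_labels={int(k): v for k, v in node.get("labels", {}).items()},
                extra_substituents={
                    int(k): v for k, v in node.get("substituents", {}).items()
                },
            )
            for ch in node.get("children", []):
                ca, po, ac = ch["linkage"]
                r.children.append((Linkage(ca, po, ac), dec(ch["residue"])))
            return r

        return cls(root=dec(d["root"]), adduct=d.get("adduct", "Na+"))


def residue_formula(m: Monosaccharide, as_residue: bool = False) -> Composition:
    """Elemental composition of one residue.

    ``as_residue=True`` gives the condensed (dehydrated) composition, e.g.
    C6H10O5 for a hexose and C8H13NO5 for a HexNAc; otherwise the free
    monosaccharide (hexose C6H12O6).  Isotope labels replace one 16O by 18O.
    """
    comp = Composition(_HEXOSE_FREE)
    for sub in m.substituents.values():
        try:
            comp += _SUBSTITUENT_DELTA[sub]
        except KeyError:
            raise GlycanError(f"unsupported substituent {sub!r}") from None
    for pos, iso in m.oxygen_labels.items():
        if iso not in ("18O", "O18"):
            raise GlycanError(f"unsupported isotope token {iso!r}")
        comp["O"] -= 1
        comp[O18] += 1
        if comp["O"] < 0:
            raise GlycanError("more labels than oxygens")
    if as_residue:
        comp -= _H2O
    return comp


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_UNICODE_MAP = {"β": "b", "α": "a", "→": "-", "‑": "-"}

_SUFFIX_RE = re.compile(r"(-OMe|-18O(\d))$")
_LINK_RE = re.compile(r"([12])-([1-9])$")
# longest token first so 'GlcNAc' wins over 'Glc'
_NAMES = sorted(_RESIDUE_DEFS, key=len, reverse=True)
_UNIT_RE = re.compile(
    r"(" + "|".join(_NAMES) + r")([ab])?$"
)


def _normalise(text: str) -> str:
    for k, v in _UNICODE_MAP.items():
        text = text.replace(k, v)
    # "GlcNAcb-(1-2)-Man" -> "GlcNAcb1-2Man"
    text = re.sub(r"-?\((\d)-(\d)\)-?", r"\1-\2", text)
    text = text.replace("-[", "[").replace("]-", "]")
    return text.replace(" ", "")


def _parse_subtree(s: str) -> Monosaccharide:
    """Parse a (sub)glycan string whose rightmost unit is the local root."""
    m = _UNIT_RE.search(s)
    if not m:
        raise GlycanError(f"cannot parse residue at end of {s!r}")
    root = Monosaccharide(name=m.group(1), anomeric_config=m.group(2) or "none")
    rest = s[: m.start()]
    # consume branch/chain segments right-to-left; each attaches to `root`
    while rest:
        if rest.endswith("]"):
            depth, i = 0, len(rest) - 1
            while i >= 0:
                if rest[i] == "]":
                    depth += 1
                elif rest[i] == "[":
                    depth -= 1
                    if depth == 0:
                        break
                i -= 1
            if depth != 0:
                raise GlycanError(f"unbalanced brackets in {rest!r}")
            segment, rest = rest[i + 1 : -1], rest[:i]
        else:
            segment, rest = rest, ""
        lm = _LINK_RE.search(segment)
        if not lm:
            raise GlycanError(f"missing linkage before {root.name} in {segment!r}")
        child = _parse_subtree(segment[: lm.start()])
        link = Linkage(
            child_anomeric_carbon=int(lm.group(1)),
            parent_oxygen_position=int(lm.group(2)),
            anomeric_config=child.anomeric_config,
        )
        if link.child_anomeric_carbon != child.carbonyl_position:
            raise GlycanError("linkage must start at the child's anomeric carbon")
        if link.parent_oxygen_position in root.attachment_positions:
            raise GlycanError(
                f"duplicate linkage at O{link.parent_oxygen_position} of {root.name}"
            )
        root.children.append((link, child))
    # restore left-to-right order of branches as written
    root.children.reverse()
    return root


def parse_glycan(text: str, adduct: str = "Na+") -> Glycan:
    """Parse a condensed glycan string; the rightmost residue is the reducing end."""
    s = _normalise(text)
    if not s:
        raise GlycanError("empty glycan string")
    labels: Dict[int, str] = {}
    substituents: Dict[int, str] = {}
    while True:
        m = _SUFFIX_RE.search(s)
        if not m:
            break
        if m.group(1) == "-OMe":
            substituents[1] = "OMe"
        else:
            labels[int(m.group(2))] = "18O"
        s = s[: m.start()]
    root = _parse_subtree(s)
    root.oxygen_labels.update(labels)
    root.extra_substituents.update(substituents)
    return Glycan(root=root, adduct=adduct)


def serialize_glycan(g: Glycan) -> str:
    """Inverse of :func:`parse_glycan` on the supported grammar."""

    def ser(r: Monosaccharide) -> str:
        parts = []
        chain_parts = []
        for i, (link, child) in enumerate(r.children):
            seg = ser(child) + f"{link.child_anomeric_carbon}-{link.parent_oxygen_position}"
            chain_parts.append(seg)
        if chain_parts:
            # first child written as the linear chain, the rest bracketed
            parts.append(chain_parts[0])
            for seg in chain_parts[1:]:
                parts.append(f"[{seg}]")
        anomer = r.anomeric_config if r.anomeric_config in ("a", "b") else ""
        return "".join(parts) + r.name + anomer

    s = ser(g.root)
    if g.root.extra_substituents.get(1) == "OMe":
        s += "-OMe"
    for pos in sorted(g.root.oxygen_labels):
        s += f"-18O{pos}"
    return s
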
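"""Cross-ring dissociation reaction network for sodiated glycans.

The mechanism implemented here describes collision-induced cross-ring
fragmentation of singly charged [M+Na]+ hexose (oligo)saccharides as a
stepwise sequence on the reducing-end residue:

1. ring opening (``RO``): hydrogen transfer from the anomeric oxygen to O5
   with cleavage of the O5-C1 bond, yielding the open-chain carbonyl form
   (carbonyl at C1 for aldoses, C2 for ketoses);
2. zero or more hydrogen shifts (``m_i_j``) relocating the carbonyl between
   carbons via H migration between oxygens (adjacent 1,2-shifts plus the
   long-range 1<->4, 1<->5, 1<->6 shifts);
3. a retro-aldol C-C cleavage (``c_k``) of the bond between C_k and C_{k+1},
   allowed only beta to the carbonyl (carbonyl at C_{k-1} or C_{k+2});
4. optional secondary dissociation: the retained piece re-enters steps 2-3.

Atom bookkeeping is composition-level: each chain carbon carries a CH2O unit
(modified by substituents, glycosyl branches, and 18O labels), so every
cleavage partitions the precursor exactly and heavy-oxygen labels are traced
without assuming tautomer structure.  Cross-ring chemistry of residues that
are *not* at the reducing end is far less favourable energetically; it is
represented by a small table of literature pathways (``RO1'``, ``RO2'``,
``c0',3'`` and follow-up migrations) with fixed neutral-loss compositions.

Transition-state barriers are consumed as bundled data (``data/barriers.csv``)
and are used only to classify pathways into major / minor / trace tiers;
nothing here computes energies.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import pandas as pd

from . import masses
from .glycans import Glycan, Monosaccharide, residue_formula
from .masses import Composition, O18

__all__ = [
    "NetworkConfig",
    "ChainState",
    "ReactionStep",
    "Pathway",
    "FragmentIon",
    "Barrier",
    "BarrierTable",
    "MechanismError",
    "ring_open",
    "apply_shift",
    "retro_aldol",
    "enumerate_pathways",
    "fragment_ion",
    "classify",
    "predict_spectrum",
    "dominant_losses",
    "load_barrier_table",
]

KB_KJ_PER_MOL_K = 0.008314462618

#: linkage-diagnostic dominant neutral losses (nominal Da) by parent oxygen
#: position of the reducing-end glycosidic bond
DOMINANT_LOSSES: Dict[int, FrozenSet[int]] = {
    2: frozenset({120}),
    3: frozenset({90}),
    4: frozenset({60}),
    6: frozenset({60, 90, 120}),
}


def dominant_losses(parent_oxygen_position: int) -> FrozenSet[int]:
    """Diagnostic dominant neutral losses for a reducing-end linkage."""
    return DOMINANT_LOSSES[parent_oxygen_position]


class MechanismError(ValueError):
    """A reaction step was applied outside its mechanistic preconditions."""


@dataclass(frozen=True)
class NetworkConfig:
    """Enumeration and classification settings.

    max_shifts: hydrogen shifts allowed per dissociation stage.
    secondary_depth: total dissociation stages (2 = one secondary cleavage).
    barrier_window: kJ/mol window above the best barrier within which a
        reducing-end pathway is still classified minor rather than trace.
    temperature: effective temperature (K) for the optional Boltzmann
        intensity weights; not a literature value, purely a reporting aid.
    """

    max_shifts: int = 2
    secondary_depth: int = 2
    barrier_window: float = 50.0
    temperature: float = 800.0


# ---------------------------------------------------------------------------
# chain state and elementary steps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainState:
    """Open- or closed-chain state of (a piece of) the reducing-end residue.

    ``carbons`` are absolute ring-carbon indices (C1..C6 numbering is kept
    through secondary dissociation so step labels stay comparable).
    ``attachments`` are oxygen positions carrying glycosidic links;
    ``blocked`` are oxygens with no exchangeable hydrogen (OMe, NAc).
    """

    carbons: Tuple[int, ...]
    form: str  # "cyclic" | "linear"
    carbonyl: int
    attachments: FrozenSet[int]
    blocked: FrozenSet[int]
    labels: FrozenSet[int]
    anomeric: int = 1

    def bonds(self) -> List[int]:
        """C-C bond indices k (bond between C_k and C_{k+1}) inside the piece."""
        return [k for k in self.carbons if k + 1 in self.carbons]


def chain_state(g: Glycan) -> ChainState:
    """Initial cyclic chain state of the reducing-end residue."""
    root = g.root
    blocked = frozenset(
        pos for pos, sub in root.substituents.items() if sub in ("OMe", "NAc")
    )
    return ChainState(
        carbons=tuple(range(1, root.carbon_count + 1)),
        form="cyclic",
        carbonyl=root.carbonyl_position,
        attachments=root.attachment_positions,
        blocked=blocked,
        labels=frozenset(root.oxygen_labels),
        anomeric=root.carbonyl_position,
    )


def ring_open(s: ChainState) -> ChainState:
    """Open the pyranose ring (H transfer from the anomeric O to O5).

    Only possible at a reducing end: the anomeric oxygen must be free (no
    methyl glycoside, no glycosidic link).  Labels are untouched — the
    hydrogen moves, the oxygen stays.
    """
    if s.form != "cyclic":
        raise MechanismError("ring already open")
    if s.anomeric in s.blocked or s.anomeric in s.attachments:
        raise MechanismError("no reducing-end ring opening: anomeric oxygen blocked")
    return replace(s, form="linear", carbonyl=s.anomeric)


def _shift_allowed(i: int, j: int) -> bool:
    if i == j:
        return False
    if abs(i - j) == 1:
        return True
    return {i, j} in ({1, 4}, {1, 5}, {1, 6})


def apply_shift(s: ChainState, i: int, j: int) -> ChainState:
    """Relocate the carbonyl from C_i to C_j by hydrogen migration O_j -> O_i.

    Requires the linear form, the carbonyl at ``i``, an (i, j) pair in the
    allowed shift set, and an exchangeable hydrogen on O_j — i.e. O_j must
    not be glycosylated or otherwise blocked.
    """
    if s.form != "linear":
        raise MechanismError("hydrogen shifts require the open-chain form")
    if s.carbonyl != i:
        raise MechanismError(f"carbonyl is at C{s.carbonyl}, not C{i}")
    if j not in s.carbons:
        raise MechanismError(f"C{j} not present in this chain piece")
    if not _shift_allowed(i, j):
        raise MechanismError(f"({i}->{j}) is not an allowed hydrogen shift")
    if j in s.attachments or j in s.blocked:
        raise MechanismError(f"O{j} carries no exchangeable hydrogen")
    return replace(s, carbonyl=j)


def retro_aldol(s: ChainState, k: int) -> Tuple[Tuple[int, ...], Tuple[int, ...]]:
    """Cleave the C_k - C_{k+1} bond beta to the carbonyl.

    Allowed only when the carbonyl sits at C_{k-1} or C_{k+2} (the
    beta-cleavage rule).  Returns the two carbon partitions (lower, upper);
    hydrogen reassignment is composition-level, so both pieces are
    closed-shell CH2O-multiples (plus any substituents they carry).
    """
    if s.form != "linear":
        raise MechanismError("retro-aldol requires the open-chain form")
    if k not in s.carbons or k + 1 not in s.carbons:
        raise MechanismError(f"bond {k} not present in this chain piece")
    if s.carbonyl not in (k - 1, k + 2):
        raise MechanismError(
            f"not a retro-aldol-accessible bond: carbonyl at C{s.carbonyl}, bond {k}"
        )
    low = tuple(c for c in s.carbons if c <= k)
    high = tuple(c for c in s.carbons if c > k)
    return low, high


# ---------------------------------------------------------------------------
# composition bookkeeping
# ---------------------------------------------------------------------------


def carbon_units(g: Glycan) -> Dict[int, Composition]:
    """Per-carbon elemental units of the reducing-end chain.

    Each carbon C_i owns its oxygen O_i and hydrogens as a CH2O unit;
    substituents modify the unit in place and a glycosyl branch at O_i adds
    the whole condensed subtree composition.  The units sum exactly to the
    glycan's neutral composition.
    """
    root = g.root
    units: Dict[int, Composition] = {}
    links = {l.parent_oxygen_position: child for l, child in root.children}
    for i in range(1, root.carbon_count + 1):
        u = Composition(formula="CH2O")
        sub = root.substituents.get(i)
        if sub == "NAc":
            u += Composition(formula="C2H3N")
        elif sub == "OMe":
            u += Composition(formula="CH2")
        elif sub is not None:
            raise MechanismError(f"unsupported substituent {sub!r}")
        if i in root.oxygen_labels:
            u["O"] -= 1
            u[O18] += 1
        if i in links:
            for res in links[i].iter_subtree():
                u += residue_formula(res, as_residue=True)
        units[i] = u
    return units


def _sum_units(units: Dict[int, Composition], carbons: Sequence[int]) -> Composition:
    total = Composition()
    for c in carbons:
        total += units[c]
    return total


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionStep:
    kind: str  # "RO" | "shift" | "cleave" | "table"
    i: int = 0
    j: int = 0
    stage: int = 1
    name: str = ""

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        if self.kind == "RO":
            return "RO"
        if self.kind == "shift":
            return f"m{self.i}_{self.j}"
        if self.kind == "cleave":
            return f"c{self.i}"
        return self.kind

    def barrier_keys(self) -> Tuple[str, ...]:
        """Lookup keys for the barrier table (shift keys are symmetric)."""
        if self.kind == "shift":
            return (f"m{self.i}_{self.j}", f"m{self.j}_{self.i}")
        return (self.label,)


@dataclass
class Pathway:
    """An ordered reaction sequence ending in one observable fragment ion."""

    steps: Tuple[ReactionStep, ...]
    site: str  # "reducing" | "non_reducing"
    retained_carbons: Tuple[int, ...] = ()
    secondary_depth: int = 1
    rate_limiting_barrier: Optional[float] = None
    barrier_rank: Optional[int] = None
    barrier_is_sentinel: bool = False

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def label(self) -> str:
        parts: List[str] = []
        cleaved: List[int] = []
        for st in self.steps:
            if st.kind == "cleave":
                cleaved.append(st.i)
                parts.append("c" + ",".join(str(c) for c in cleaved))
            else:
                parts.append(st.label)
        return "->".join(parts)


@dataclass
class FragmentIon:
    """One predicted fragment: the charge-retaining partition of a pathway."""

    mz_monoisotopic: float
    mz_nominal: int
    neutral_loss_monoisotopic: float
    neutral_loss_nominal: int
    retained_atoms: Composition
    lost_atoms: Composition
    label_retained: bool
    pathway: Pathway
    tier: str = "unclassified"  # "major" | "minor" | "trace"
    retained: bool = True
    annotation: str = ""  # Domon-Costello style metadata, cosmetic only


# ---------------------------------------------------------------------------
# barrier table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Barrier:
    value: Optional[float]  # kJ/mol, None if not reported numerically
    ordering: Optional[int]  # per-species ordinal rank (1 = lowest barrier)
    sentinel: bool = False  # True for "more than 300 kJ/mol"
    provenance: str = ""


class BarrierTable:
    """Bundled transition-state barrier data keyed by (species, step label).

    Species keys collapse mass-identical epimers (Glc/Man/Gal -> the Man
    model systems).  Where only an ordering of barriers is reported, entries
    carry an ordinal rank and no value; classification then works on ranks.
    """

    def __init__(self, frame: pd.DataFrame, version: str = ""):
        self.frame = frame
        self.version = version
        self._index: Dict[Tuple[str, str], Barrier] = {}
        for row in frame.itertuples(index=False):
            val = None if pd.isna(row.barrier_kJ_mol) else float(row.barrier_kJ_mol)
            order = None if pd.isna(row.ordering) else int(row.ordering)
            self._index[(row.species, row.step)] = Barrier(
                value=val,
                ordering=order,
                sentinel=bool(row.sentinel_gt300),
                provenance=str(row.provenance),
            )

    def lookup(self, species: str, step: ReactionStep) -> Optional[Barrier]:
        for key in step.barrier_keys():
            b = self._index.get((species, key))
            if b is not None:
                return b
        return None

    def has_species(self, species: str) -> bool:
        return any(s == species for s, _ in self._index)

    def accessibility_rank(self, species: str, step: ReactionStep) -> Optional[int]:
        """Relative reactant-state abundance rank (1 = most accessible).

        The reported candidate-count ordering tracks the barrier ordering for
        every species studied, so the ordinal column doubles as the
        accessibility class.
        """
        b = self.lookup(species, step)
        return b.ordering if b else None


def _data_text(name: str) -> str:
    return resources.files("crossring.data").joinpath(name).read_text()


def load_barrier_table() -> BarrierTable:
    """Load the bundled barrier table; its version is a content hash."""
    text = _data_text("barriers.csv")
    frame = pd.read_csv(
        resources.files("crossring.data").joinpath("barriers.csv")
    )
    version = hashlib.sha256(text.encode()).hexdigest()[:12]
    return BarrierTable(frame, version=version)


def _load_nonreducing_rows() -> List[Tuple[Tuple[str, ...], str]]:
    frame = pd.read_csv(
        resources.files("crossring.data").joinpath("nonreducing_pathways.csv")
    )
    return [
        (tuple(str(r.steps).split(">")), str(r.loss_formula))
        for r in frame.itertuples(index=False)
    ]


_HEXNAC = {"GlcNAc", "GalNAc"}


def species_key(g: Glycan) -> str:
    """Barrier-table species key; epimeric hexoses collapse onto Man/GlcNAc."""

    def base(name: str) -> str:
        return "GlcNAc" if name in _HEXNAC else "Man"

    if g.n_residues == 1:
        return "Hex-OMe" if g.root.substituents.get(1) == "OMe" else "Hex"
    if g.n_residues == 2:
        link, child = g.root.children[0]
        return f"{base(child.name)}1-{link.parent_oxygen_position}{base(g.root.name)}"
    return "oligomer"


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _retention(
    g: Glycan, state: ChainState, low: Tuple[int, ...], high: Tuple[int, ...]
) -> Optional[Tuple[Tuple[int, ...], Tuple[int, ...]]]:
    """(retained, lost) partition, or None if the cleavage strands no piece.

    Oligomers retain the partition carrying the glycosidic link(s) (the
    sodium stays with the larger, link-bearing moiety); free monosaccharides
    lose the piece containing the chain head (the lowest-numbered carbon,
    i.e. the original anomeric side).
    """
    att = state.attachments
    if att:
        in_low = any(a in low for a in att)
        in_high = any(a in high for a in att)
        if in_low and in_high:
            return None
        return (low, high) if in_low else (high, low)
    head = min(state.carbons)
    return (high, low) if head in low else (low, high)


def _explore(
    g: Glycan,
    cfg: NetworkConfig,
    state: ChainState,
    steps: Tuple[ReactionStep, ...],
    stage: int,
    shifts_used: int,
    visited: FrozenSet[int],
    out: List[Pathway],
) -> None:
    for k in state.bonds():
        try:
            low, high = retro_aldol(state, k)
        except MechanismError:
            continue
        parts = _retention(g, state, low, high)
        if parts is None:
            continue
        retained, _lost = parts
        new_steps = steps + (ReactionStep("cleave", i=k, stage=stage),)
        out.append(
            Pathway(steps=new_steps, site="reducing",
                    retained_carbons=retained, secondary_depth=stage)
        )
        if stage < cfg.secondary_depth and len(retained) >= 2:
            # carbonyl re-evaluation: keep it if retained, else it moves to
            # the piece carbon adjacent to the cleaved bond (enol carbon)
            if state.carbonyl in retained:
                carbonyl = state.carbonyl
            else:
                carbonyl = k if k in retained else k + 1
            piece = ChainState(
                carbons=retained,
                form="linear",
                carbonyl=carbonyl,
                attachments=frozenset(a for a in state.attachments if a in retained),
                blocked=frozenset(b for b in state.blocked if b in retained),
                labels=frozenset(l for l in state.labels if l in retained),
                anomeric=state.anomeric,
            )
            _explore(g, cfg, piece, new_steps, stage + 1, 0,
                     frozenset({carbonyl}), out)
    if shifts_used < cfg.max_shifts:
        for j in sorted(state.carbons):
            if j in visited:
                continue
            try:
                shifted = apply_shift(state, state.carbonyl, j)
            except MechanismError:
                continue
            _explore(
                g, cfg, shifted,
                steps + (ReactionStep("shift", i=state.carbonyl, j=j, stage=stage),),
                stage, shifts_used + 1, visited | {j}, out,
            )


def _nonreducing_pathways(g: Glycan, cfg: NetworkConfig) -> List[Pathway]:
    """Table-driven cross-ring pathways of residues not at the reducing end.

    Only plain hexose residues are covered by the table; the methyl
    glycoside of a free hexose is the monosaccharide model of the same
    situation and uses the same loss catalogue.
    """
    if g.n_residues == 1:
        applicable = not g.reducing_end_free()
    else:
        applicable = any(
            not r.substituents and r is not g.root for r in g.root.iter_subtree()
        )
    if not applicable:
        return []
    out = []
    for step_names, _formula in _load_nonreducing_rows():
        steps = tuple(
            ReactionStep("table", stage=1, name=n) for n in step_names
        )
        out.append(Pathway(steps=steps, site="non_reducing", retained_carbons=()))
    return out


_NONREDUCING_LOSSES = {tuple(s): f for s, f in _load_nonreducing_rows()}


def enumerate_pathways(
    g: Glycan,
    cfg: NetworkConfig | None = None,
    table: BarrierTable | None = None,
) -> List[Pathway]:
    """Exhaustively enumerate cross-ring pathways for one glycan.

    Reducing-end pathways are RO -> shift* -> cleave sequences (with
    secondary re-entry of the retained piece); non-reducing-end pathways come
    from the bundled table.  Each pathway carries its rate-limiting barrier
    where the barrier table covers its steps.
    """
    cfg = cfg or NetworkConfig()
    table = table or load_barrier_table()
    out: List[Pathway] = []
    state = chain_state(g)
    try:
        opened = ring_open(state)
    except MechanismError:
        opened = None
    if opened is not None:
        _explore(
            g, cfg, opened, (ReactionStep("RO"),), 1, 0,
            frozenset({opened.carbonyl}), out,
        )
    out.extend(_nonreducing_pathways(g, cfg))
    species = species_key(g)
    for p in out:
        _attach_barrier(p, species, table)
    return out


def _attach_barrier(p: Pathway, species: str, table: BarrierTable) -> None:
    values, ranks, sentinel = [], [], False
    for st in p.steps:
        b = table.lookup(species, st)
        if b is None:
            continue
        if b.sentinel:
            sentinel = True
        if b.value is not None:
            values.append(b.value)
        if b.ordering is not None:
            ranks.append(b.ordering)
    p.rate_limiting_barrier = max(values) if values else None
    p.barrier_rank = max(ranks) if ranks else None
    p.barrier_is_sentinel = sentinel


# ---------------------------------------------------------------------------
# fragments and classification
# ---------------------------------------------------------------------------


def fragment_ion(p: Pathway, g: Glycan) -> FragmentIon:
    """Materialise the observable ion of one pathway.

    The retained and lost partitions always sum exactly to the precursor
    composition; the ion m/z is the retained neutral plus the adduct minus
    one electron mass.
    """
    precursor = g.neutral_composition()
    if p.site == "reducing":
        units = carbon_units(g)
        retained = _sum_units(units, p.retained_carbons)
    else:
        key = tuple(st.label for st in p.steps)
        retained = precursor - Composition(formula=_NONREDUCING_LOSSES[key])
    lost = precursor - retained
    mono, nom = masses.ion_mz(retained, g.adduct)
    loss_mono, loss_nom = masses.loss_mass(lost)
    annotation = ""
    if p.site == "reducing" and p.secondary_depth == 1:
        cleaves = [st.i for st in p.steps if st.kind == "cleave"]
        if cleaves:
            annotation = f"0,{cleaves[0]}A"
    return FragmentIon(
        mz_monoisotopic=mono,
        mz_nominal=nom,
        neutral_loss_monoisotopic=loss_mono,
        neutral_loss_nominal=loss_nom,
        retained_atoms=retained,
        lost_atoms=lost,
        label_retained=masses.label_count(lost) == 0
        and masses.label_count(precursor) > 0,
        pathway=p,
        annotation=annotation,
    )


def _root_linkage_position(g: Glycan) -> Optional[int]:
    if g.root.children:
        return g.root.children[0][0].parent_oxygen_position
    return None


def classify(
    pathways: Sequence[Pathway],
    g: Glycan,
    cfg: NetworkConfig | None = None,
    table: BarrierTable | None = None,
) -> Dict[int, str]:
    """Assign a tier (major/minor/trace) to each pathway (by list index).

    Major: the reducing-end primary pathway with the lowest rate-limiting
    barrier (by the per-species barrier ordering), ties broken by fewer
    steps then lexicographic label.  Minor: other reducing-end pathways
    within the barrier window of the major (or whose barriers are unranked),
    and all secondary products.  Trace: non-reducing-end pathways and
    reducing-end pathways beyond the window.

    For species without any barrier data (e.g. the 1->6 linkage) the
    linkage-diagnostic dominant-loss catalogue decides the major tier(s).
    """
    cfg = cfg or NetworkConfig()
    table = table or load_barrier_table()
    tiers: Dict[int, str] = {}
    primaries = [
        (i, p) for i, p in enumerate(pathways)
        if p.site == "reducing" and p.secondary_depth == 1
    ]
    ranked = [(i, p) for i, p in primaries if p.barrier_rank is not None]

    major_idx: set = set()
    if ranked:
        key = lambda ip: (ip[1].barrier_rank, ip[1].n_steps, ip[1].label)
        major_idx = {min(ranked, key=key)[0]}
    elif primaries:
        # no barrier data for this species: fall back to the diagnostic map
        pos = _root_linkage_position(g)
        wanted = DOMINANT_LOSSES.get(pos, frozenset()) if pos else frozenset()
        by_loss: Dict[int, Tuple[int, Pathway]] = {}
        if wanted:
            for i, p in primaries:
                ion = fragment_ion(p, g)
                loss = ion.neutral_loss_nominal
                # compare at the unlabeled scale: a label adds exactly +2
                base_loss = loss - 2 * masses.label_count(ion.lost_atoms)
                if base_loss in wanted:
                    cur = by_loss.get(base_loss)
                    if cur is None or (p.n_steps, p.label) < (
                        cur[1].n_steps, cur[1].label
                    ):
                        by_loss[base_loss] = (i, p)
            major_idx = {i for i, _ in by_loss.values()}

    major_barrier = None
    for i in major_idx:
        if pathways[i].rate_limiting_barrier is not None:
            major_barrier = pathways[i].rate_limiting_barrier

    for i, p in enumerate(pathways):
        if i in major_idx:
            tiers[i] = "major"
        elif p.site != "reducing" or p.barrier_is_sentinel:
            tiers[i] = "trace"
        elif p.secondary_depth > 1:
            tiers[i] = "minor"
        elif (
            major_barrier is not None
            and p.rate_limiting_barrier is not None
            and p.rate_limiting_barrier > major_barrier + cfg.barrier_window
        ):
            tiers[i] = "trace"
        else:
            tiers[i] = "minor"
    return tiers


_TIER_ORDER = {"major": 0, "minor": 1, "trace": 2}
_TIER_WEIGHT = {"major": 1.0, "minor": 0.05, "trace": 0.01}


@dataclass
class TheoreticalPeak:
    """All pathways converging on one nominal fragment m/z."""

    mz_nominal: int
    mz_monoisotopic: float
    neutral_loss_nominal: int
    tier: str
    label_retained: bool
    weight: float
    ions: List[FragmentIon] = field(default_factory=list)

    @property
    def pathway_labels(self) -> List[str]:
        return [ion.pathway.label for ion in self.ions]

    @property
    def ambiguous(self) -> bool:
        return len(self.ions) > 1


@dataclass
class TheoreticalSpectrum:
    glycan: Glycan
    precursor_mz: float
    precursor_nominal: int
    peaks: List[TheoreticalPeak]

    def peak(self, mz_nominal: int) -> Optional[TheoreticalPeak]:
        for p in self.peaks:
            if p.mz_nominal == mz_nominal:
                return p
        return None

    @property
    def nominal_mzs(self) -> List[int]:
        return [p.mz_nominal for p in self.peaks]


def _boltzmann_weight(
    ion: FragmentIon, cfg: NetworkConfig, species: str, table: BarrierTable
) -> float:
    """Optional relative weight ~ accessibility / rank * exp(-E/kT).

    Purely ordinal reporting aid (the underlying study gives no intensity
    model); used only to order peaks, never asserted quantitatively.
    """
    p = ion.pathway
    if p.rate_limiting_barrier is None:
        return _TIER_WEIGHT[ion.tier]
    rank = p.barrier_rank or 1
    kt = KB_KJ_PER_MOL_K * cfg.temperature
    return math.exp(-p.rate_limiting_barrier / kt) / rank


def predict_spectrum(
    g: Glycan,
    cfg: NetworkConfig | None = None,
    table: BarrierTable | None = None,
) -> TheoreticalSpectrum:
    """Theoretical cross-ring peak list with tiers and pathway annotations."""
    cfg = cfg or NetworkConfig()
    table = table or load_barrier_table()
    pathways = enumerate_pathways(g, cfg, table)
    tiers = classify(pathways, g, cfg, table)
    species = species_key(g)
    ions = []
    for i, p in enumerate(pathways):
        ion = fragment_ion(p, g)
        ion.tier = tiers[i]
        ions.append(ion)
    grouped: Dict[int, List[FragmentIon]] = {}
    for ion in ions:
        grouped.setdefault(ion.mz_nominal, []).append(ion)
    peaks = []
    for mz_nom in sorted(grouped):
        group = sorted(
            grouped[mz_nom],
            key=lambda io: (_TIER_ORDER[io.tier], io.pathway.n_steps, io.pathway.label),
        )
        best = group[0]
        weight = max(_boltzmann_weight(io, cfg, species, table) for io in group)
        peaks.append(
            TheoreticalPeak(
                mz_nominal=mz_nom,
                mz_monoisotopic=best.mz_monoisotopic,
                neutral_loss_nominal=best.neutral_loss_nominal,
                tier=best.tier,
                label_retained=best.label_retained,
                weight=weight,
                ions=group,
            )
        )
    mono, nom = masses.precursor_mz(g)
    return TheoreticalSpectrum(
        glycan=g, precursor_mz=mono, precursor_nominal=nom, peaks=peaks
    )
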
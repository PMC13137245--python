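"""Reaction-network enumeration, atom partitioning and tier classification."""

import pytest

from crossring import (
    MechanismError,
    NetworkConfig,
    apply_shift,
    dominant_losses,
    enumerate_pathways,
    fragment_ion,
    parse_glycan,
    predict_spectrum,
    retro_aldol,
    ring_open,
)
from crossring.masses import Composition, label_count
from crossring.network import chain_state, carbon_units, classify, species_key


def open_chain(text):
    return ring_open(chain_state(parse_glycan(text)))


# ---------------------------------------------------------------------------
# elementary steps
# ---------------------------------------------------------------------------


def test_ring_open_aldose_and_ketose():
    assert open_chain("Glcb").carbonyl == 1
    assert open_chain("Fru").carbonyl == 2


def test_ring_open_blocked_for_methyl_glycoside():
    with pytest.raises(MechanismError, match="no reducing-end ring opening"):
        ring_open(chain_state(parse_glycan("Manb-OMe")))


def test_shift_moves_carbonyl_and_rejects_disallowed_pairs():
    s = open_chain("Glcb")
    assert apply_shift(s, 1, 2).carbonyl == 2
    assert apply_shift(s, 1, 5).carbonyl == 5
    with pytest.raises(MechanismError):
        apply_shift(s, 1, 3)  # 1,3 is not in the allowed shift set
    with pytest.raises(MechanismError):
        apply_shift(apply_shift(s, 1, 2), 2, 5)  # 2->5 never allowed


def test_shift_onto_glycosylated_oxygen_is_blocked():
    """The H donor of a shift is the destination oxygen: no H when linked."""
    s = open_chain("Manb1-2Manb")
    with pytest.raises(MechanismError, match="no exchangeable hydrogen"):
        apply_shift(s, 1, 2)
    s4 = open_chain("Manb1-4Manb")
    with pytest.raises(MechanismError):
        apply_shift(s4, 1, 4)
    assert apply_shift(s4, 1, 5).carbonyl == 5


def test_retro_aldol_partitions_and_beta_rule():
    s = open_chain("Glcb")
    low, high = retro_aldol(s, 2)
    assert low == (1, 2) and high == (3, 4, 5, 6)
    units = carbon_units(parse_glycan("Glcb"))
    comp_low = sum((units[c] for c in low), Composition())
    comp_high = sum((units[c] for c in high), Composition())
    assert comp_low == Composition(formula="C2H4O2")
    assert comp_high == Composition(formula="C4H8O4")
    with pytest.raises(MechanismError, match="retro-aldol"):
        retro_aldol(s, 4)  # carbonyl at C1 is not beta to the C4-C5 bond


def test_c6_single_carbon_loss():
    s = apply_shift(open_chain("Glcb"), 1, 4)
    low, high = retro_aldol(s, 5)
    assert high == (6,)


# ---------------------------------------------------------------------------
# enumeration against an independent brute-force oracle
# ---------------------------------------------------------------------------


def _oracle_single_hexose(max_shifts):
    """All (shift sequence, cleavage) combinations allowed by the rules.

    Independent re-derivation: shifts are adjacent moves or 1<->4/5/6
    exchanges that never revisit a carbon; a cleavage of bond k requires the
    carbonyl at k-1 or k+2.
    """

    def allowed(i, j):
        return abs(i - j) == 1 or {i, j} in ({1, 4}, {1, 5}, {1, 6})

    results = set()
    stack = [((), 1, frozenset({1}))]
    while stack:
        shifts, carbonyl, seen = stack.pop()
        for k in range(1, 6):
            if carbonyl in (k - 1, k + 2):
                results.add((shifts, k))
        if len(shifts) < max_shifts:
            for j in range(1, 7):
                if j not in seen and allowed(carbonyl, j):
                    stack.append((shifts + ((carbonyl, j),), j, seen | {j}))
    return results


@pytest.mark.parametrize("max_shifts", [0, 1, 2, 3])
def test_enumeration_matches_brute_force(max_shifts):
    g = parse_glycan("Glcb")
    cfg = NetworkConfig(max_shifts=max_shifts, secondary_depth=1)
    got = set()
    for p in enumerate_pathways(g, cfg):
        if p.site != "reducing":
            continue
        shifts = tuple((s.i, s.j) for s in p.steps if s.kind == "shift")
        (cleave,) = [s.i for s in p.steps if s.kind == "cleave"]
        got.add((shifts, cleave))
    assert got == _oracle_single_hexose(max_shifts)


def test_blocking_o1_removes_exactly_the_reducing_pathways():
    free = enumerate_pathways(parse_glycan("Manb"))
    blocked = enumerate_pathways(parse_glycan("Manb-OMe"))
    assert free and all(p.site == "reducing" for p in free)
    assert blocked and all(p.site == "non_reducing" for p in blocked)


def test_methyl_mannose_nonreducing_barriers(barrier_table):
    pathways = enumerate_pathways(parse_glycan("Manb-OMe"))
    assert pathways
    barriers = [
        p.rate_limiting_barrier for p in pathways
        if p.rate_limiting_barrier is not None
    ]
    assert barriers and min(barriers) == 231


# ---------------------------------------------------------------------------
# mass and label conservation
# ---------------------------------------------------------------------------

ALL_SPECIES = [
    "Glcb", "Fru", "Manb-OMe",
    "Manb1-2Manb", "Manb1-3Manb", "Manb1-4Manb", "Manb1-6Manb",
    "Manb1-2Manb-18O1", "Manb1-3Manb-18O1", "Manb1-4Manb-18O1",
    "GlcNAcb1-2Man",
]


@pytest.mark.parametrize("text", ALL_SPECIES)
def test_mass_conservation_on_every_pathway(text):
    g = parse_glycan(text)
    precursor = g.neutral_composition()
    for p in enumerate_pathways(g):
        ion = fragment_ion(p, g)
        assert ion.retained_atoms + ion.lost_atoms == precursor
        from crossring.masses import composition_mass

        total = composition_mass(ion.retained_atoms) + composition_mass(
            ion.lost_atoms
        )
        assert total == pytest.approx(composition_mass(precursor), abs=1e-4)


@pytest.mark.parametrize("text", ["Manb1-2Manb-18O1", "Manb1-4Manb-18O1"])
def test_label_conservation(text):
    """Exactly one 18O across each partition; retained flag is its complement."""
    g = parse_glycan(text)
    for p in enumerate_pathways(g):
        ion = fragment_ion(p, g)
        n_lost = label_count(ion.lost_atoms)
        n_kept = label_count(ion.retained_atoms)
        assert n_lost + n_kept == 1
        assert ion.label_retained == (n_lost == 0)


# ---------------------------------------------------------------------------
# printed fragment catalogues and classification
# ---------------------------------------------------------------------------


def _peaks(text):
    return predict_spectrum(parse_glycan(text))


def test_labeled_man12_catalogue():
    pred = _peaks("Manb1-2Manb-18O1")
    major = [p.mz_nominal for p in pred.peaks if p.tier == "major"]
    assert major == [247]
    assert pred.peak(247).label_retained
    assert set(pred.nominal_mzs) >= {245, 275, 277, 305, 307, 337}
    losses = {p.mz_nominal: p.neutral_loss_nominal for p in pred.peaks}
    assert {losses[m] for m in (245, 275, 277, 305, 307, 337)} == {
        122, 92, 90, 62, 60, 30,
    }


def test_labeled_man14_catalogue():
    pred = _peaks("Manb1-4Manb-18O1")
    assert [p.mz_nominal for p in pred.peaks if p.tier == "major"] == [305]
    losses = {p.mz_nominal: p.neutral_loss_nominal for p in pred.peaks}
    assert losses[305] == 62 and losses[307] == 60 and losses[335] == 32
    # the label leaves with C1 in the 62- and 32-Da losses, stays in the 60-Da one
    assert not pred.peak(305).label_retained
    assert pred.peak(307).label_retained
    assert not pred.peak(335).label_retained
    # fragments assigned to the residue NOT at the reducing end are trace
    for mz in (247, 277, 337):
        assert pred.peak(mz).tier == "trace"


def test_labeled_man13_major_and_nonreducing_247():
    pred = _peaks("Manb1-3Manb-18O1")
    assert [p.mz_nominal for p in pred.peaks if p.tier == "major"] == [277]
    assert pred.peak(247).tier == "trace"  # not a reducing-end product


def test_glcnac_man_catalogue():
    pred = _peaks("GlcNAcb1-2Man")
    assert pred.precursor_nominal == 406
    assert [p.mz_nominal for p in pred.peaks if p.tier == "major"] == [286]
    assert pred.peak(316).tier == "minor"
    assert pred.peak(346).tier == "minor"
    m16 = [
        ion for ion in pred.peak(346).ions
        for s in ion.pathway.steps
        if s.kind == "shift" and (s.i, s.j) == (1, 6)
    ]
    assert m16  # 346 arises from the 1->6 hydrogen shift route


def test_glucose_secondary_dissociation():
    pred = _peaks("Glcb")
    peak = pred.peak(83)
    assert peak is not None and peak.tier == "minor"
    two_stage = [
        ion for ion in peak.ions if ion.pathway.secondary_depth == 2
    ]
    assert two_stage and two_stage[0].neutral_loss_nominal == 120


def test_ketose_dominant_loss():
    pred = _peaks("Fru")
    (major,) = [p for p in pred.peaks if p.tier == "major"]
    assert major.neutral_loss_nominal == 90


@pytest.mark.parametrize(
    "pos,expected", [(2, {120}), (3, {90}), (4, {60}), (6, {60, 90, 120})]
)
def test_linkage_dominant_loss_map(pos, expected):
    """Predicted major-tier losses reproduce the diagnostic catalogue."""
    assert dominant_losses(pos) == frozenset(expected)
    pred = _peaks(f"Manb1-{pos}Manb")
    got = {p.neutral_loss_nominal for p in pred.peaks if p.tier == "major"}
    assert got == expected


def test_classification_tie_break_prefers_fewer_steps():
    """With equal barriers the direct cleavage outranks shift-first routes."""
    g = parse_glycan("Glcb")
    pathways = enumerate_pathways(g)
    tiers = classify(pathways, g)
    majors = [p for i, p in enumerate(pathways) if tiers[i] == "major"]
    assert len(majors) == 1
    assert majors[0].label == "RO->c2"


def test_species_keys_collapse_epimers():
    assert species_key(parse_glycan("Glcb1-2Galb")) == "Man1-2Man"
    assert species_key(parse_glycan("Glcb")) == "Hex"
    assert species_key(parse_glycan("Manb-OMe")) == "Hex-OMe"


def test_barrier_table_versioned(barrier_table):
    from crossring.network import ReactionStep

    assert len(barrier_table.version) == 12
    b = barrier_table.lookup("Man1-2Man", ReactionStep("cleave", i=2))
    assert b.value == 152 and b.ordering == 1
    # symmetric shift lookup: m4_1 resolves to the m1_4 entry
    b2 = barrier_table.lookup("Man1-2Man", ReactionStep("shift", i=4, j=1))
    assert b2 is not None and b2.value == 161
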
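# Methods

## Scope and model

`crossring` models cross-ring dissociation of singly charged sodium adducts
of hexose (oligo)saccharides under low-energy CID as a discrete reaction
network on the reducing-end residue, with three kinds of elementary step:

1. **Ring opening (RO).** Hydrogen transfer from the anomeric oxygen (O1
   for aldoses, O2 for ketoses) to the ring oxygen O5 with cleavage of the
   O5–C1 (O5–C2) bond. Preconditions: cyclic form and a free anomeric
   oxygen — a methyl glycoside or a residue glycosylated at the anomeric
   position cannot ring-open, which is what restricts the whole cascade to
   the reducing end.
2. **Hydrogen shifts (m_i_j).** Carbonyl relocation from C_i to C_j by H
   migration between the corresponding oxygens. The allowed set is the
   adjacent 1,2-shifts plus the long-range 1↔4, 1↔5 and 1↔6 exchanges.
   The migrating hydrogen comes from O_j, so a shift onto a glycosylated,
   O-methylated or N-acetylated position is forbidden; this single rule
   reproduces the per-linkage pathway sets (no m1_2 for a 1→2 linkage, no
   m1_4 for 1→4, and so on) without any per-species case logic.
3. **Retro-aldol cleavage (c_k).** C_k–C_{k+1} scission allowed β to the
   carbonyl: carbonyl at C_{k−1} or C_{k+2}. Cleavages are *not* restricted
   by oxygen blocking — observed minors such as the 62-Da loss of a 1→3
   disaccharide come from RO→c2 even though O3 is glycosylated; only their
   barriers differ.

**Secondary dissociation.** The retained piece of a cleavage re-enters the
shift/cleave stages (default depth 2, i.e. one secondary stage). Its
carbonyl is re-evaluated: kept if the piece contains it, otherwise placed on
the piece carbon adjacent to the cleaved bond (the enol carbon). This
reproduces, e.g., glucose 203→143→83 and the +32-Da label losses
(277→245, 307→275) of the labeled 1→2 disaccharide without special cases.

**Atom bookkeeping.** Each chain carbon owns a CH₂O unit (NAc: +C₂H₃N;
OMe: +CH₂; glycosyl branch: + the condensed subtree composition; ¹⁸O label:
O→¹⁸O). A cleavage partitions units exactly, so retained + lost equals the
precursor composition identically and label tracking is free. Hydrogen
reassignment at cleavage is composition-level only — only masses are
observable, so no tautomer structure is asserted.

**Charge retention.** For oligomers the observed ion is the partition
carrying the glycosidic link(s) to the rest of the molecule; for free
monosaccharides it is the partition opposite the chain head (lowest-numbered
carbon). The sodium position itself is not modeled; both partitions are kept
on the fragment record with a retained flag.

**Non-reducing-end chemistry** is energetically disfavoured and is included
as a fixed catalogue (RO1′, RO2′, c0′,3′ and follow-up migrations) with
tabulated neutral-loss compositions, applied when a plain hexose sits off
the reducing end (or as the whole story for a methyl glycoside). The
catalogue covers plain hexoses only; for GlcNAc-(1→2)-Man no non-reducing
pathways are emitted because no HexNAc data exist in the source tables.

## Barriers and tier classification

Transition-state barriers enter as bundled data
(`src/crossring/data/barriers.csv`, content-hash versioned, one provenance
note per entry; `">300 kJ/mol"` entries carry a sentinel flag). Where a
source reports only an ordering, entries carry an ordinal `ordering` and no
value; each species' `ordering` column is the classification key, built
from printed values where available and from the stated ordering otherwise.

- **major** — the primary reducing-end pathway with the lowest
  rate-limiting entry (ties: fewer steps, then lexicographic label);
- **minor** — other primary reducing-end pathways within 50 kJ/mol of the
  major (window checked only when both sides have numeric barriers;
  unranked reducing pathways default to minor), and all secondary products;
- **trace** — non-reducing-end pathways, sentinel barriers, and reducing
  pathways beyond the window.

For species with no barrier data at all (notably the 1→6 linkage) the
classifier falls back to the diagnostic dominant-loss catalogue
(1→2↦120, 1→3↦90, 1→4↦60, 1→6↦{60,90,120}), marking the minimal-step
pathway per diagnostic loss as major.

Optional peak weights (`exp(−E‡/k_B T_eff)/rank`, T_eff = 800 K by default)
are a reporting aid only: no quantitative intensity model exists for these
systems, and nothing downstream depends on the weights.

## Annotation and linkage calling

Peaks are matched to predicted monoisotopic m/z at an absolute tolerance
(default ±0.3 Da, matching a unit-resolution linear ion trap). Nominal
masses are `round(monoisotopic)`; the charge carried by Na⁺ is corrected
for the electron mass. Linkage scoring is rank-based and scale-invariant:
observed cross-ring peaks within 50% of the strongest one form the dominant
set, which is Jaccard-compared against each candidate's diagnostic losses
(labels are de-shifted by 2 Da per lost ¹⁸O first); a small bonus rewards
candidates whose full (major+minor+trace) catalogue explains the remaining
cross-ring peaks, so mechanism-explained minors never push the call toward
a mixture. A spectrum with no recognisable cross-ring peak returns an
explicit *uninformative* result rather than a guess.

## Conformer screening

Candidate criteria: Na within 2.5 Å of the H-donor or H-acceptor atom, and
donor–acceptor distance within 3–3.5 Å, the upper edge widening in 0.1-Å
steps (ceiling 5 Å) until a minimum candidate count (default 2000) is
reached; then a stable lowest-energy cut with index tie-break. The
donor–acceptor pair is explicit in the role map because some shifts
exchange hydrogen with carbon rather than oxygen.

Descriptors: Cremer–Pople puckering (ring order O5, C1…C5; standard phase
convention — θ/φ conventions vary between codes, so invariance tests pin
amplitude and θ, and φ only for generically puckered rings); Na–O
coordination number with the rational switching function
(1−(r/r₀)ⁿ)/(1−(r/r₀)ᵐ), defaults r₀ = 2.5 Å, n = 6, m = 12 — conventional
choices, not literature values; USR shape moments (mean, spread, cube-root
skew of distances to centroid / closest / farthest / farthest-from-farthest)
with similarity 1/(1 + mean |Δ|), deduplication threshold 0.97 (no
published threshold exists; configurable). Energies are read from the
ensemble file; an energy-callback hook lets users attach an evaluator —
none ships here.

## Synthetic data

The spectrum generator emits peaks at the predicted m/z with tier-scaled
intensities (100:5:1 major:minor:trace — a synthetic choice consistent with
"very low" minor intensities; no measured ratios exist), optional Gaussian
m/z jitter and intensity scatter, and uniform-random noise peaks kept > 1 Da
from any true peak so ground truth stays unambiguous at the default
tolerance. It does *not* emulate isotope envelopes, glycosidic (B/Y/C/Z)
ions, electronic noise floors or detector saturation, so passing tests show
correctness of the mechanism arithmetic and of the matching logic, not
robustness to real chromatographic backgrounds.

The ensemble generator plants an exact number of criterion-satisfying
frames (Na–donor in 1.9–2.45 Å, donor–acceptor in 3.02–3.48 Å) among
violators constructed to fail for any reachable window (Na far from both
partners, or donor–acceptor below 3 Å or above 5.2 Å); energies are
exponential (scale 20 kJ/mol). All randomness flows from one
`numpy.random.default_rng(seed)`; XYZ output uses fixed-point formatting,
so identical seeds give byte-identical files.

## Numerical choices and degenerate inputs

- Masses: NIST monoisotopic values via pyteomics; ¹⁸O−¹⁶O = 2.00425 Da;
  determinism to 1e-4 Da asserted in tests.
- Enumeration: per stage at most 2 hydrogen shifts by default (3 in the
  oracle-equivalence test), never revisiting a carbonyl position within a
  stage; exhaustive and deterministic, order-independent by construction.
- Planar rings return puckering amplitude 0 with θ = φ = 0 (angles are
  undefined there); collinear rings raise.
- Ties everywhere (energy cuts, classification, ranking) break by stable
  index or lexicographic label, so outputs are reproducible across runs.

## Known limitations

- Barriers are data, not physics: systems absent from the table fall back
  to the diagnostic-loss catalogue, and the per-entry value/ordering mix
  reflects exactly what the sources print (including one ordered triple
  whose per-reaction assignment follows sentence order).
- Only singly charged [M+Na]⁺ chemistry under low-energy CID; protonated /
  deprotonated ions and HCD/ETD/ECD are out of scope by design.
- Stereochemistry is a name tag (Glc ≡ Man ≡ Gal by mass); furanoses and
  multiply charged ions are not modeled.
- Branched reducing ends (two glycosidic bonds on the ring being cleaved)
  are enumerated only insofar as a cleavage never severs a link-bearing
  partition; no barrier data exist for them.
- The MS³ provenance of larger N-glycan precursors is bookkeeping only:
  the five-residue N-glycan string parses, but the package makes no claim
  about which cleavage yields which intermediate beyond mass arithmetic.
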
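"""Match experimental CID peak lists to predicted fragments; call the linkage.

Peak lists come in as two-column CSV (m/z, intensity) or MGF.  Matching is
nearest-neighbour within an absolute tolerance (default 0.3 Da — unit
resolution linear ion trap).  Linkage inference compares the observed
cross-ring neutral-loss pattern against the linkage-diagnostic dominant
losses (1->2: 120; 1->3: 90; 1->4: 60; 1->6: 60+90+120), using rank-based
intensity tiers only: minor peaks that the reducing-end mechanism explains do
not count against a candidate, so a spectrum with one dominant loss plus
small companion losses is called as a single linkage rather than a mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from pyteomics import mgf as _mgf

from .glycans import Glycan
from .masses import label_count, nominal
from .network import (
    BarrierTable,
    NetworkConfig,
    TheoreticalSpectrum,
    dominant_losses,
    predict_spectrum,
)

__all__ = [
    "PeakList",
    "Annotation",
    "AnnotationReport",
    "LinkageCall",
    "read_peaklist",
    "annotate",
    "infer_linkage",
]

DEFAULT_TOLERANCE = 0.3  # Da


class PeakListError(ValueError):
    """Malformed or empty peak-list input."""


@dataclass
class PeakList:
    """(m/z, intensity) pairs, ascending in m/z, with acquisition metadata."""

    mz: List[float]
    intensity: List[float]
    precursor_mz: Optional[float] = None
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise PeakListError("mz and intensity lengths differ")
        if any(i < 0 for i in self.intensity):
            raise PeakListError("negative intensity")
        order = sorted(range(len(self.mz)), key=lambda k: self.mz[k])
        self.mz = [self.mz[k] for k in order]
        self.intensity = [self.intensity[k] for k in order]

    def __len__(self) -> int:
        return len(self.mz)


def read_peaklist(path: str | Path, format: Optional[str] = None) -> PeakList:
    """Load a peak list from CSV (mz,intensity) or MGF (one spectrum block)."""
    path = Path(path)
    fmt = format or ("mgf" if path.suffix.lower() == ".mgf" else "csv")
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "mgf":
        return _read_mgf(path)
    raise PeakListError(f"unsupported peak-list format {fmt!r}")


def _read_csv(path: Path) -> PeakList:
    mzs, ints = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace("\t", ",").split(",") if p != ""]
            if lineno == 1 and parts and not _is_number(parts[0]):
                continue  # header row
            if len(parts) < 2 or not all(_is_number(p) for p in parts[:2]):
                raise PeakListError(f"{path}:{lineno}: malformed peak record {line!r}")
            mzs.append(float(parts[0]))
            ints.append(float(parts[1]))
    if not mzs:
        raise PeakListError(f"{path}: no peaks found")
    return PeakList(mz=mzs, intensity=ints, metadata={"source": str(path)})


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _read_mgf(path: Path) -> PeakList:
    with _mgf.MGF(str(path)) as reader:
        spectra = list(reader)
    if not spectra:
        raise PeakListError(f"{path}: no MGF spectrum block found")
    sp = spectra[0]
    pepmass = sp["params"].get("pepmass")
    precursor = float(pepmass[0]) if pepmass else None
    return PeakList(
        mz=[float(x) for x in sp["m/z array"]],
        intensity=[float(x) for x in sp["intensity array"]],
        precursor_mz=precursor,
        metadata={"source": str(path),
                  "title": str(sp["params"].get("title", ""))},
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass
class Annotation:
    peak_index: int
    mz: float
    intensity: float
    matched_mz: float
    mass_error: float
    tier: str
    pathway_labels: List[str]
    ambiguous: bool


@dataclass
class AnnotationReport:
    annotations: List[Annotation]
    unmatched: List[int]
    tolerance: float
    prediction: TheoreticalSpectrum

    def to_records(self) -> List[dict]:
        return [
            {
                "peak_index": a.peak_index,
                "mz": a.mz,
                "intensity": a.intensity,
                "matched_mz": a.matched_mz,
                "mass_error": a.mass_error,
                "tier": a.tier,
                "pathways": a.pathway_labels,
                "ambiguous": a.ambiguous,
            }
            for a in self.annotations
        ]


def annotate(
    pl: PeakList,
    g: Glycan,
    tol: float = DEFAULT_TOLERANCE,
    cfg: NetworkConfig | None = None,
    table: BarrierTable | None = None,
) -> AnnotationReport:
    """Match each peak to the nearest predicted fragment within ``tol`` Da."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    pred = predict_spectrum(g, cfg, table)
    annotations, unmatched = [], []
    for i, (mz, inten) in enumerate(zip(pl.mz, pl.intensity)):
        best = None
        for peak in pred.peaks:
            err = mz - peak.mz_monoisotopic
            if abs(err) <= tol and (best is None or abs(err) < abs(best[1])):
                best = (peak, err)
        if best is None:
            unmatched.append(i)
            continue
        peak, err = best
        annotations.append(
            Annotation(
                peak_index=i,
                mz=mz,
                intensity=inten,
                matched_mz=peak.mz_monoisotopic,
                mass_error=err,
                tier=peak.tier,
                pathway_labels=peak.pathway_labels,
                ambiguous=peak.ambiguous,
            )
        )
    return AnnotationReport(
        annotations=annotations, unmatched=unmatched, tolerance=tol, prediction=pred
    )


# ---------------------------------------------------------------------------
# linkage inference
# ---------------------------------------------------------------------------


@dataclass
class CandidateScore:
    glycan: Glycan
    linkage_position: int
    score: float
    dominant_agreement: float
    explained_fraction: float
    mixture_not_required: bool


@dataclass
class LinkageCall:
    ranking: List[CandidateScore]
    uninformative: bool
    observed_dominant_losses: List[int]

    @property
    def best(self) -> Optional[CandidateScore]:
        return self.ranking[0] if self.ranking else None


def infer_linkage(
    pl: PeakList,
    candidates: Sequence[Glycan],
    tol: float = DEFAULT_TOLERANCE,
    dominance_fraction: float = 0.5,
    cfg: NetworkConfig | None = None,
    table: BarrierTable | None = None,
) -> LinkageCall:
    """Rank linkage candidates by agreement with the observed loss pattern.

    Scores are rank/tier based and invariant to uniform intensity rescaling.
    With no recognisable cross-ring peak the call is flagged uninformative
    rather than guessed.
    """
    if not candidates:
        raise ValueError("at least one candidate glycan required")
    preds = [predict_spectrum(c, cfg, table) for c in candidates]
    precursor = pl.precursor_mz or preds[0].precursor_mz

    # observed cross-ring peaks: those matching any candidate's predictions
    matched: Dict[int, float] = {}  # peak index -> intensity
    for i, mz in enumerate(pl.mz):
        if any(
            abs(mz - peak.mz_monoisotopic) <= tol
            for pred in preds
            for peak in pred.peaks
        ):
            matched[i] = pl.intensity[i]
    if not matched:
        return LinkageCall(ranking=[], uninformative=True,
                           observed_dominant_losses=[])

    top = max(matched.values())
    dominant_idx = [i for i, v in matched.items() if v >= dominance_fraction * top]
    observed_dominant = sorted(
        {_nominal_loss(pl.mz[i], precursor, preds[0]) for i in dominant_idx}
    )

    ranking = []
    for cand, pred in zip(candidates, preds):
        pos = cand.root.children[0][0].parent_oxygen_position
        want = set(dominant_losses(pos))
        got = set(observed_dominant)
        jacc = len(want & got) / len(want | got) if want | got else 0.0
        explained = [
            i for i in matched
            if any(abs(pl.mz[i] - pk.mz_monoisotopic) <= tol for pk in pred.peaks)
        ]
        frac = len(explained) / len(matched)
        score = jacc + 0.1 * frac
        ranking.append(
            CandidateScore(
                glycan=cand,
                linkage_position=pos,
                score=score,
                dominant_agreement=jacc,
                explained_fraction=frac,
                mixture_not_required=frac == 1.0,
            )
        )
    ranking.sort(key=lambda c: (-c.score, c.linkage_position))
    return LinkageCall(
        ranking=ranking, uninformative=False,
        observed_dominant_losses=list(observed_dominant),
    )


def _nominal_loss(mz: float, precursor: float, pred: TheoreticalSpectrum) -> int:
    """Nominal neutral loss of an observed peak, de-shifted of isotope labels.

    Losses are compared on the unlabeled scale so that an 18O-labeled
    spectrum still maps onto the diagnostic 60/90/120 catalogue.
    """
    raw = nominal(precursor - mz)
    best = min(
        pred.peaks,
        key=lambda p: abs(p.mz_monoisotopic - mz),
        default=None,
    )
    if best is not None and abs(best.mz_monoisotopic - mz) <= 0.5:
        shift = 2 * label_count(best.ions[0].lost_atoms)
        return best.neutral_loss_nominal - shift
    return raw
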
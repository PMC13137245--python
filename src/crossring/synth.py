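"""Seeded synthetic-data generators with planted ground truth.

Two generators make every pipeline stage testable without any deposited
data: (a) conformer ensembles in which an exact, known number of frames
satisfies the geometric candidate criteria (Na-donor < 2.5 Å and
donor-acceptor inside 3-3.5 Å) while the rest violate at least one
criterion by construction, outside any reachable widening window; and (b)
unit-resolution CID peak lists whose peaks sit at the predicted fragment
m/z with tier-ordered intensities (major >> minor > trace) plus optional
jitter and uniform-random noise peaks kept more than 1 Da from any true
peak.  All randomness flows from a single integer seed.

The default tier intensity ratios (100:5:1) are synthetic — the mechanism
study reports only that minor fragments are of very low intensity — and the
noise defaults emulate a clean ion-trap spectrum, not chemical background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .annotate import PeakList
from .glycans import Glycan
from .network import BarrierTable, NetworkConfig, TheoreticalSpectrum, predict_spectrum
from .screen import AtomRoles, ConformerEnsemble

__all__ = [
    "EnsembleParams",
    "NoiseParams",
    "gen_ensemble",
    "gen_spectrum",
    "TIER_INTENSITY",
]

TIER_INTENSITY = {"major": 100.0, "minor": 5.0, "trace": 1.0}


@dataclass(frozen=True)
class EnsembleParams:
    """Geometry windows used to plant passing / failing conformers.

    Passing frames draw Na-donor from ``na_pass`` and donor-acceptor from
    ``dd_pass``; failing frames violate the sodium criterion, fall below the
    donor-acceptor window, or sit beyond the widening ceiling, so the
    planted count is recovered exactly for any dd_max <= dd_hard_max.
    """

    n_filler: int = 9  # carbon filler atoms besides Na, donor O, acceptor O
    box: float = 6.0  # Å, filler placement cube
    na_pass: Tuple[float, float] = (1.9, 2.45)
    na_fail: Tuple[float, float] = (2.6, 4.0)
    dd_pass: Tuple[float, float] = (3.02, 3.48)
    dd_fail_low: Tuple[float, float] = (1.6, 2.9)
    dd_fail_high: Tuple[float, float] = (5.2, 8.0)
    energy_scale: float = 20.0  # kJ/mol, exponential distribution

    def validate(self) -> None:
        if self.na_pass[1] >= 2.5 or self.na_fail[0] <= 2.5:
            raise ValueError("infeasible sodium-distance windows")
        if not (3.0 < self.dd_pass[0] and self.dd_pass[1] < 3.5):
            raise ValueError("infeasible donor-acceptor pass window")
        if self.dd_fail_low[1] >= 3.0 or self.dd_fail_high[0] <= 5.0:
            raise ValueError("infeasible donor-acceptor fail windows")


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def gen_ensemble(
    n: int,
    n_pass: int,
    seed: int,
    params: EnsembleParams = EnsembleParams(),
) -> Tuple[ConformerEnsemble, np.ndarray, AtomRoles]:
    """Generate a conformer ensemble with exactly ``n_pass`` planted candidates.

    Returns (ensemble, ground-truth labels, atom roles).  Bit-reproducible
    per seed; frame order is a seeded permutation so passing frames are not
    clustered at the front.
    """
    if n_pass > n:
        raise ValueError("n_pass may not exceed n")
    params.validate()
    rng = np.random.default_rng(seed)
    symbols = ["Na", "O", "O"] + ["C"] * params.n_filler
    labels = np.zeros(n, dtype=bool)
    labels[:n_pass] = True
    perm = rng.permutation(n)
    labels = labels[perm]

    frames = np.empty((n, 3 + params.n_filler, 3))
    fail_mode = 0
    for f in range(n):
        donor = rng.uniform(-1.0, 1.0, size=3)
        if labels[f]:
            dd = rng.uniform(*params.dd_pass)
            r_na = rng.uniform(*params.na_pass)
        else:
            fail_mode = (fail_mode + 1) % 3
            if fail_mode == 0:  # sodium too far, geometry window fine
                dd = rng.uniform(*params.dd_pass)
                r_na = rng.uniform(*params.na_fail)
            elif fail_mode == 1:  # donor-acceptor below the window
                dd = rng.uniform(*params.dd_fail_low)
                r_na = rng.uniform(*params.na_pass)
            else:  # donor-acceptor beyond any widening ceiling
                dd = rng.uniform(*params.dd_fail_high)
                r_na = rng.uniform(*params.na_fail)
        acceptor = donor + dd * _random_direction(rng)
        na = donor + r_na * _random_direction(rng)
        if not labels[f] and fail_mode != 1:
            # the sodium criterion accepts coordination to either partner:
            # a violating frame must keep Na away from the acceptor too
            while np.linalg.norm(na - acceptor) < 2.55:
                na = donor + r_na * _random_direction(rng)
        filler = rng.uniform(-params.box / 2, params.box / 2,
                             size=(params.n_filler, 3))
        frames[f, 0] = na
        frames[f, 1] = donor
        frames[f, 2] = acceptor
        frames[f, 3:] = filler
    energies = rng.exponential(params.energy_scale, size=n)
    ens = ConformerEnsemble(symbols=symbols, coords=frames, energies=energies)
    return ens, labels, AtomRoles(na=0, donor=1, acceptor=2)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseParams:
    n_noise_peaks: int = 0
    intensity_cv: float = 0.0  # relative intensity scatter
    mz_jitter: float = 0.0  # Da, gaussian m/z scatter
    noise_intensity: Tuple[float, float] = (0.2, 3.0)
    guard: float = 1.0  # Da, minimum distance of noise from any true peak


def gen_spectrum(
    g: Glycan,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    cfg: NetworkConfig | None = None,
    table: BarrierTable | None = None,
) -> Tuple[PeakList, List[dict], TheoreticalSpectrum]:
    """Simulate a CID peak list from the predicted fragment catalogue.

    Returns (peak list, ground-truth records, the prediction used).  With
    the default zero-noise parameters the peak set equals the predicted
    fragment m/z set exactly.
    """
    rng = np.random.default_rng(seed)
    pred = predict_spectrum(g, cfg, table)
    mzs: List[float] = []
    intensities: List[float] = []
    truth: List[dict] = []
    for peak in pred.peaks:
        base = TIER_INTENSITY[peak.tier]
        inten = base * max(
            1e-3, 1.0 + (noise.intensity_cv * rng.standard_normal()
                         if noise.intensity_cv else 0.0)
        )
        mz = peak.mz_monoisotopic + (
            noise.mz_jitter * rng.standard_normal() if noise.mz_jitter else 0.0
        )
        mzs.append(mz)
        intensities.append(inten)
        truth.append(
            {
                "mz": mz,
                "mz_theoretical": peak.mz_monoisotopic,
                "mz_nominal": peak.mz_nominal,
                "tier": peak.tier,
                "neutral_loss_nominal": peak.neutral_loss_nominal,
                "pathways": peak.pathway_labels,
                "is_noise": False,
            }
        )
    true_mzs = np.array([t["mz_theoretical"] for t in truth])
    lo, hi = 50.0, pred.precursor_mz - 2.0
    added = 0
    while added < noise.n_noise_peaks:
        mz = float(rng.uniform(lo, hi))
        if np.abs(true_mzs - mz).min() <= noise.guard:
            continue
        inten = float(rng.uniform(*noise.noise_intensity))
        mzs.append(mz)
        intensities.append(inten)
        truth.append({"mz": mz, "tier": None, "is_noise": True})
        added += 1
    pl = PeakList(
        mz=mzs,
        intensity=intensities,
        precursor_mz=pred.precursor_mz,
        metadata={"seed": str(seed), "synthetic": "true"},
    )
    truth.sort(key=lambda t: t["mz"])
    return pl, truth, pred
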
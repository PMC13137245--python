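"""Reactant-candidate screening on conformer ensembles.

A conformer is a candidate reactant for a hydrogen-transfer reaction when
(1) the sodium ion coordinates the H-donor or H-acceptor atom's oxygen at
less than 2.5 Å, and (2) the donor-acceptor distance lies in a 3-3.5 Å
window; when too few conformers qualify, the upper window edge is widened
stepwise until a minimum candidate count is reached, after which the
lowest-energy candidates are kept.  The module also provides the geometric
descriptors used as collective variables during the enhanced-sampling stage
(Cremer-Pople ring puckering, sodium-oxygen coordination numbers) and the
rotation-invariant USR shape moments used to deduplicate conformers.

Energies are read from the ensemble file (kJ/mol, relative); an optional
energy callback lets callers attach their own evaluator.  No electronic-
structure code is involved anywhere.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ConformerEnsemble",
    "CandidateCriteria",
    "AtomRoles",
    "ScreenReport",
    "read_xyz",
    "write_xyz",
    "puckering",
    "coordination_number",
    "select_candidates",
    "usr_descriptors",
    "usr_similarity",
    "dedup",
]


class EnsembleError(ValueError):
    """Malformed ensemble input or degenerate geometry."""


@dataclass
class ConformerEnsemble:
    """Element symbols + per-frame Cartesian coordinates (Å) + energies (kJ/mol)."""

    symbols: List[str]
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    energies: np.ndarray  # (n_frames,)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.symbols):
            raise EnsembleError("atom count differs from symbol count")
        if self.energies.shape != (self.coords.shape[0],):
            raise EnsembleError("one energy per frame required")
        if not np.all(np.isfinite(self.energies)):
            raise EnsembleError("energies must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]


_ENERGY_RE = re.compile(r"E\s*=\s*([-+0-9.eE]+)")


def read_xyz(path: str | Path) -> ConformerEnsemble:
    """Read a multi-frame XYZ file with ``E=<kJ/mol>`` on each comment line."""
    symbols: List[str] = []
    frames: List[List[List[float]]] = []
    energies: List[float] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise EnsembleError(f"{path}:{i + 1}: expected atom count") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _ENERGY_RE.search(comment)
        energies.append(float(m.group(1)) if m else 0.0)
        frame, frame_syms = [], []
        for j in range(natoms):
            parts = lines[i + 2 + j].split()
            frame_syms.append(parts[0])
            frame.append([float(x) for x in parts[1:4]])
        if not symbols:
            symbols = frame_syms
        elif frame_syms != symbols:
            raise EnsembleError(f"{path}: atom ordering changes between frames")
        frames.append(frame)
        i += 2 + natoms
    if not frames:
        raise EnsembleError(f"{path}: empty ensemble")
    return ConformerEnsemble(symbols, np.array(frames), np.array(energies))


def write_xyz(ens: ConformerEnsemble, path: str | Path) -> None:
    """Write a multi-frame XYZ file (deterministic fixed-point formatting)."""
    with open(path, "w") as fh:
        for f in range(len(ens)):
            fh.write(f"{len(ens.symbols)}\n")
            fh.write(f"E={ens.energies[f]:.6f} kJ/mol\n")
            for s, (x, y, z) in zip(ens.symbols, ens.coords[f]):
                fh.write(f"{s} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# geometric descriptors (collective variables)
# ---------------------------------------------------------------------------


def puckering(ring_coords: np.ndarray) -> Tuple[float, float, float]:
    """Cremer-Pople puckering (q in Å, theta and phi in degrees) of a 6-ring.

    Atoms must be given in the conventional ring order O5, C1, C2, C3, C4,
    C5.  Invariant under rigid motion; theta = 0/180 degrees for ideal
    chairs.  The standard phase convention is used (phi from the generalised
    ring-plane normal defined by the two weighted lattice vectors).
    """
    r = np.asarray(ring_coords, dtype=float)
    if r.shape != (6, 3):
        raise EnsembleError("puckering requires exactly 6 ring atoms")
    r = r - r.mean(axis=0)
    n = 6
    j = np.arange(n)
    rp = (r * np.sin(2 * np.pi * j / n)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / n)[:, None]).sum(axis=0)
    normal = np.cross(rp, rpp)
    nn = np.linalg.norm(normal)
    if nn < 1e-10:
        raise EnsembleError("degenerate (collinear) ring geometry")
    normal /= nn
    z = r @ normal
    q2c = math.sqrt(2.0 / n) * float((z * np.cos(4 * np.pi * j / n)).sum())
    q2s = -math.sqrt(2.0 / n) * float((z * np.sin(4 * np.pi * j / n)).sum())
    q3 = float(((-1.0) ** j * z).sum()) / math.sqrt(n)
    q2 = math.hypot(q2c, q2s)
    q = math.hypot(q2, q3)
    if q < 1e-10:
        return 0.0, 0.0, 0.0  # planar: amplitude zero, angles undefined
    theta = math.degrees(math.acos(max(-1.0, min(1.0, q3 / q))))
    phi = math.degrees(math.atan2(q2s, q2c)) % 360.0
    return q, theta, phi


def coordination_number(
    na_pos: np.ndarray,
    o_positions: np.ndarray,
    r0: float = 2.5,
    n: int = 6,
    m: int = 12,
) -> float:
    """Smooth Na-O coordination number via the rational switching function.

    Each oxygen contributes (1-(r/r0)^n)/(1-(r/r0)^m); the removable
    singularity at r = r0 is the limit n/m.  The (r0, n, m) defaults are
    conventional switching-function choices, not literature values.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if m <= n:
        raise ValueError("m must exceed n")
    na = np.asarray(na_pos, dtype=float)
    oxy = np.atleast_2d(np.asarray(o_positions, dtype=float))
    r = np.linalg.norm(oxy - na, axis=1) / r0
    out = 0.0
    for x in r:
        xn, xm = x**n, x**m
        if abs(xm - 1.0) < 1e-9:
            out += n / m
        else:
            out += (1.0 - xn) / (1.0 - xm)
    return float(out)


# ---------------------------------------------------------------------------
# USR shape descriptors
# ---------------------------------------------------------------------------


def _moments(d: np.ndarray) -> Tuple[float, float, float]:
    mu = float(d.mean())
    sigma = float(d.std())
    skew = float(((d - mu) ** 3).mean())
    return mu, sigma, math.copysign(abs(skew) ** (1.0 / 3.0), skew)


def usr_descriptors(coords: np.ndarray) -> np.ndarray:
    """12-component ultrafast-shape-recognition vector of an atom cloud.

    First three moments (mean, spread, cube-root skew) of the atomic
    distance distributions to four reference points: the centroid, the atom
    closest to it, the atom farthest from it, and the atom farthest from
    that one.  Invariant to rigid motion by construction.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[0] < 4:
        raise EnsembleError("USR descriptors require at least 4 atoms")
    ctd = x.mean(axis=0)
    d_ctd = np.linalg.norm(x - ctd, axis=1)
    cst = x[int(np.argmin(d_ctd))]
    fct = x[int(np.argmax(d_ctd))]
    d_fct = np.linalg.norm(x - fct, axis=1)
    ftf = x[int(np.argmax(d_fct))]
    out = []
    for ref in (ctd, cst, fct, ftf):
        out.extend(_moments(np.linalg.norm(x - ref, axis=1)))
    return np.array(out)


def usr_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Similarity in (0, 1]: 1 / (1 + mean absolute descriptor difference)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(1.0 / (1.0 + np.abs(a - b).mean()))


def dedup(
    coords: Sequence[np.ndarray],
    threshold: float = 0.97,
    energies: Optional[Sequence[float]] = None,
) -> List[int]:
    """Greedy keep-first-by-energy similarity pruning; returns kept indices.

    Structures are visited lowest-energy first (stable index tie-break); one
    is kept iff its USR similarity to every already-kept structure is below
    ``threshold``.  Deterministic for a given input.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    n = len(coords)
    if energies is None:
        order = list(range(n))
    else:
        order = sorted(range(n), key=lambda i: (energies[i], i))
    descs = [usr_descriptors(c) for c in coords]
    kept: List[int] = []
    for i in order:
        if all(usr_similarity(descs[i], descs[k]) < threshold for k in kept):
            kept.append(i)
    return kept


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateCriteria:
    """Geometric screening windows for hydrogen-transfer reactant candidates."""

    na_o_max: float = 2.5  # Å, Na+ coordination to donor/acceptor oxygen
    dd_min: float = 3.0  # Å, donor-acceptor lower edge
    dd_max: float = 3.5  # Å, donor-acceptor upper edge (adaptive)
    min_candidates: int = 2000
    widen_step: float = 0.1  # Å per widening iteration
    dd_hard_max: float = 5.0  # Å, absolute ceiling for widening

    def __post_init__(self) -> None:
        if not self.dd_min < self.dd_max <= self.dd_hard_max:
            raise ValueError("require dd_min < dd_max <= dd_hard_max")


@dataclass(frozen=True)
class AtomRoles:
    """Atom indices of the sodium ion and the H-donor / H-acceptor atoms.

    The donor-acceptor distance is measured between whatever atoms the
    reaction exchanges hydrogen between — O to O for the oxygen shifts, O to
    C for shifts onto carbon — so the role map makes the pair explicit.
    """

    na: int
    donor: int
    acceptor: int


@dataclass
class ScreenReport:
    selected: List[int]
    window_used: Tuple[float, float]
    iterations: List[Tuple[float, int]]  # (dd_max tried, passing count)
    widened: bool


def select_candidates(
    ens: ConformerEnsemble,
    roles: AtomRoles,
    criteria: CandidateCriteria = CandidateCriteria(),
    energy_callback: Optional[Callable[[np.ndarray], float]] = None,
) -> ScreenReport:
    """Apply the geometric candidate criteria with adaptive window widening.

    Keeps conformers with Na within ``na_o_max`` of donor or acceptor AND a
    donor-acceptor distance inside [dd_min, dd_max]; widens dd_max by
    ``widen_step`` while fewer than ``min_candidates`` qualify (up to
    ``dd_hard_max``), then returns the lowest-energy qualifiers (stable sort,
    index tie-break).
    """
    if len(ens) == 0:
        raise EnsembleError("empty ensemble")
    xyz = ens.coords
    d_na_d = np.linalg.norm(xyz[:, roles.na] - xyz[:, roles.donor], axis=1)
    d_na_a = np.linalg.norm(xyz[:, roles.na] - xyz[:, roles.acceptor], axis=1)
    d_da = np.linalg.norm(xyz[:, roles.donor] - xyz[:, roles.acceptor], axis=1)
    na_ok = (d_na_d < criteria.na_o_max) | (d_na_a < criteria.na_o_max)

    if energy_callback is not None:
        energies = np.array([energy_callback(xyz[f]) for f in range(len(ens))])
    else:
        energies = ens.energies

    iterations: List[Tuple[float, int]] = []
    dd_max = criteria.dd_max
    while True:
        mask = na_ok & (d_da >= criteria.dd_min) & (d_da <= dd_max)
        count = int(mask.sum())
        iterations.append((round(dd_max, 6), count))
        if count >= criteria.min_candidates or dd_max >= criteria.dd_hard_max:
            break
        dd_max = min(dd_max + criteria.widen_step, criteria.dd_hard_max)

    passing = np.flatnonzero(mask)
    order = sorted(passing, key=lambda i: (energies[i], i))
    selected = [int(i) for i in order[: criteria.min_candidates]]
    return ScreenReport(
        selected=selected,
        window_used=(criteria.dd_min, round(dd_max, 6)),
        iterations=iterations,
        widened=len(iterations) > 1,
    )
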
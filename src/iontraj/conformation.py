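"""Side-chain and binding-site geometry.

chi2 classification windows (degrees, continuous-boundary form):

* lumen-facing:   |chi2| >= 120
* cytosol-facing: 40 <= |chi2| < 120
* unclassified:   |chi2| < 40

Occupancies are percentages of ALL frames; the unclassified residual is
reported explicitly rather than silently absorbed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import TopologyError
from .geomcore import DistanceSeries, dihedral_angle
from .structio import Frame, Topology, Trajectory, select_atoms

LUMEN = "lumen"
CYTOSOL = "cytosol"
UNCLASSIFIED = "unclassified"

LUMEN_MIN_ABS = 120.0
CYTOSOL_MIN_ABS = 40.0


@dataclass
class StateOccupancy:
    """Percent of frames per orientation label (sums to 100)."""

    percent: dict[str, float]

    def __post_init__(self):
        total = sum(self.percent.values())
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"occupancies sum to {total}, expected 100")

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.percent, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class Chi2StateSeries:
    residue: int
    times: np.ndarray
    angles: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.labels is not None and len(self.labels) != len(self.angles):
            raise ValueError("labels and angles differ in length")

    def write_csv(self, path) -> None:
        labels = self.labels or [""] * len(self.angles)
        with open(path, "w") as fh:
            fh.write("time_us,angle_deg,label\n")
            for t, a, lab in zip(self.times, self.angles, labels):
                fh.write(f"{t:.6f},{a:.4f},{lab}\n")


@dataclass(frozen=True)
class CarboxylPairSpec:
    """Named atom-pair convention: one (resid, atom name) selector per end."""

    name: str
    resid_a: int
    atom_a: str
    resid_b: int
    atom_b: str

    def selectors(self) -> tuple[str, str]:
        return (
            f"resid {self.resid_a} and name {self.atom_a}",
            f"resid {self.resid_b} and name {self.atom_b}",
        )


#: Built-in carboxyl-pair conventions. For E908 the protonated oxygen OE2 is
#: used wherever an unnumbered "Oe" is called for.
BUILTIN_PAIRS: dict[str, CarboxylPairSpec] = {
    "E771-D800": CarboxylPairSpec("E771-D800", 771, "CD", 800, "CG"),
    "E771-E908": CarboxylPairSpec("E771-E908", 771, "OE1", 908, "OE2"),
    "D800-E908": CarboxylPairSpec("D800-E908", 800, "CG", 908, "OE2"),
}


# ---------------------------------------------------------------------------
# chi2 series and classification
# ---------------------------------------------------------------------------

def _chi2_atom_indices(topology: Topology, resid: int) -> list[int]:
    indices = []
    for name in ("CA", "CB", "CG", "CD"):
        found = select_atoms(topology, f"resid {resid} and name {name}")
        if not found:
            raise TopologyError(f"residue {resid} is missing atom {name}")
        indices.append(found[0])
    return indices


def chi2_series(traj: Trajectory, resid: int) -> Chi2StateSeries:
    """Per-frame side-chain chi2 dihedral (CA-CB-CG-CD order), degrees."""
    ia, ib, ig, idd = _chi2_atom_indices(traj.topology, resid)
    angles = np.array([
        dihedral_angle(traj.coords[k, ia], traj.coords[k, ib],
                       traj.coords[k, ig], traj.coords[k, idd])
        for k in range(traj.n_frames)
    ])
    return Chi2StateSeries(residue=resid, times=traj.times.copy(), angles=angles)


def classify_chi2(angles) -> tuple[list[str], StateOccupancy]:
    """Label each angle lumen / cytosol / unclassified and tally occupancy.

    The denominator is all frames; every finite angle receives exactly one
    label.
    """
    angles = np.asarray(angles, dtype=float)
    labels = []
    for a in angles:
        mag = abs(a)
        if mag >= LUMEN_MIN_ABS:
            labels.append(LUMEN)
        elif mag >= CYTOSOL_MIN_ABS:
            labels.append(CYTOSOL)
        else:
            labels.append(UNCLASSIFIED)
    n = len(labels)
    occupancy = StateOccupancy(
        percent={
            lab: 100.0 * labels.count(lab) / n
            for lab in (LUMEN, CYTOSOL, UNCLASSIFIED)
        }
    )
    return labels, occupancy


def classify_chi2_series(series: Chi2StateSeries) -> tuple[Chi2StateSeries, StateOccupancy]:
    labels, occ = classify_chi2(series.angles)
    return (
        Chi2StateSeries(residue=series.residue, times=series.times,
                        angles=series.angles, labels=labels),
        occ,
    )


# ---------------------------------------------------------------------------
# Carboxyl pairs and crystal references
# ---------------------------------------------------------------------------

def carboxyl_pair_series(traj: Trajectory, pair: CarboxylPairSpec | str) -> DistanceSeries:
    """Per-frame distance for a named or explicit carboxyl-pair convention."""
    if isinstance(pair, str):
        try:
            pair = BUILTIN_PAIRS[pair]
        except KeyError:
            raise TopologyError(
                f"unknown pair {pair!r}; built-ins: {sorted(BUILTIN_PAIRS)}"
            ) from None
    sel_a, sel_b = pair.selectors()
    ia = select_atoms(traj.topology, sel_a)
    ib = select_atoms(traj.topology, sel_b)
    if len(ia) != 1 or len(ib) != 1:
        raise TopologyError(
            f"pair {pair.name}: selectors resolved to {len(ia)} and {len(ib)} atoms"
        )
    values = np.linalg.norm(traj.coords[:, ia[0], :] - traj.coords[:, ib[0], :], axis=1)
    return DistanceSeries(label=pair.name, times=traj.times.copy(), values=values)


def crystal_reference_distance(topology: Topology, frame: Frame,
                               pair: CarboxylPairSpec | str) -> float:
    """Single pair distance (nm) on a one-frame structure.

    Averaging over multiple crystal structures is the caller's loop.
    """
    if isinstance(pair, str):
        try:
            pair = BUILTIN_PAIRS[pair]
        except KeyError:
            raise TopologyError(
                f"unknown pair {pair!r}; built-ins: {sorted(BUILTIN_PAIRS)}"
            ) from None
    sel_a, sel_b = pair.selectors()
    ia = select_atoms(topology, sel_a)
    ib = select_atoms(topology, sel_b)
    if len(ia) != 1 or len(ib) != 1:
        raise TopologyError(
            f"pair {pair.name}: selectors resolved to {len(ia)} and {len(ib)} atoms"
        )
    return float(np.linalg.norm(frame.coords[ia[0]] - frame.coords[ib[0]]))
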
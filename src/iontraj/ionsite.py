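"""Ion-centric analyses: coordination numbers, ligand distance tables,
binding-event detection, gateway contact ordering, and a nonbonded
interaction-energy estimate.

Coordination counts use a strict distance inequality (< cutoff) and include
every oxygen atom, protein and water alike. Bonding thresholds for the
distance table are species-specific and applied to the per-atom MEAN
distance: >= 0.21 nm (Mg), >= 0.30 nm (K), >= 0.25 nm (Ca) is non-bonding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    ParameterError,
    SelectionError,
)
from .geomcore import _resolve
from .structio import Trajectory

#: species -> bonding threshold (nm) applied to the mean ion-oxygen distance
BONDING_THRESHOLDS = {"MG": 0.21, "K": 0.30, "CA": 0.25}

#: Coulomb constant in kcal*Angstrom/(mol*e^2)
COULOMB_KCAL_A = 332.0636

NM_TO_ANGSTROM = 10.0


@dataclass
class CoordinationSeries:
    ion: int
    species: str
    cutoff: float
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ParameterError("coordination cutoff must be positive")
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ParameterError("coordination counts must be non-negative")


@dataclass
class CoordinationPopulation:
    """Percent of sampled frames at each observed coordination number."""

    percentages: dict[int, float]

    def __post_init__(self):
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 0.1:
            raise ParameterError(f"populations sum to {total}, expected 100")

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.percentages.items())
        return pd.DataFrame(rows, columns=["coordination_number", "percent"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class LigandDistanceTable:
    species: str
    rows: pd.DataFrame  # residue, resid, atom_name, mean_nm, sd_nm, bonded

    def bonded_only(self) -> pd.DataFrame:
        return self.rows[self.rows["bonded"]].reset_index(drop=True)

    def write_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.4f")


@dataclass(frozen=True)
class BindingEvent:
    ion: int
    site: str
    t_on: float
    sustained: bool


@dataclass
class NonbondedParams:
    """Per-atom partial charges (e) and 12-6 Lennard-Jones parameters.

    ``charges[i]`` in elementary charges; ``epsilon[i]`` is the well depth
    (kcal/mol, >= 0); ``rmin[i]`` the per-atom minimum-energy distance (nm),
    combined across pairs by Lorentz-Berthelot rules.
    """

    charges: dict[int, float]
    epsilon: dict[int, float] = field(default_factory=dict)
    rmin: dict[int, float] = field(default_factory=dict)
    dielectric: float = 1.0

    def __post_init__(self):
        if self.dielectric <= 0:
            raise ParameterError("dielectric must be positive")
        for i, eps in self.epsilon.items():
            if eps < 0:
                raise ParameterError(f"negative LJ well depth for atom {i}")

    def require(self, index: int, topology=None) -> None:
        if index not in self.charges:
            name = ""
            if topology is not None:
                a = topology.atoms[index]
                name = f" ({a.resname}{a.resid} {a.name})"
            raise ParameterError(f"no nonbonded parameters for atom {index}{name}")

    @classmethod
    def from_table(cls, path, topology, dielectric: float = 1.0) -> "NonbondedParams":
        """Read a whitespace-separated table: selection, charge, eps, rmin_nm.

        Each row's selection expression is resolved on `topology`; later
        rows override earlier ones for overlapping atoms. Lines starting
        with '#' are comments.
        """
        from .structio import select_atoms

        charges: dict[int, float] = {}
        epsilon: dict[int, float] = {}
        rmin: dict[int, float] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.rsplit(None, 3)
                if len(parts) != 4:
                    raise ParameterError(f"bad parameter row: {raw!r}")
                sel, q, eps, rm = parts
                for idx in select_atoms(topology, sel.strip()):
                    charges[idx] = float(q)
                    epsilon[idx] = float(eps)
                    rmin[idx] = float(rm)
        return cls(charges=charges, epsilon=epsilon, rmin=rmin, dielectric=dielectric)


# ---------------------------------------------------------------------------
# Coordination
# ---------------------------------------------------------------------------

def _check_ion(traj: Trajectory, ion: int) -> str:
    if ion not in traj.topology.ion_atoms:
        raise SelectionError(f"atom index {ion} is not an indexed ion")
    return traj.topology.ion_atoms[ion]


def coordination_series(traj: Trajectory, ion: int, cutoff: float,
                        stride: int = 1) -> CoordinationSeries:
    """Count oxygen atoms (protein and water) strictly within `cutoff` (nm)
    of the ion, every `stride` frames.
    """
    species = _check_ion(traj, ion)
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    oxy = traj.topology.oxygen_indices()
    sampled = np.arange(0, traj.n_frames, stride)
    ion_xyz = traj.coords[sampled][:, ion, :]
    oxy_xyz = traj.coords[sampled][:, oxy, :]
    dists = np.linalg.norm(oxy_xyz - ion_xyz[:, None, :], axis=2)
    counts = np.sum(dists < cutoff, axis=1)
    return CoordinationSeries(ion=ion, species=species, cutoff=cutoff,
                              times=traj.times[sampled], counts=counts)


def coordination_population(series: CoordinationSeries) -> CoordinationPopulation:
    """Percent of sampled frames at each observed coordination number."""
    if len(series.counts) == 0:
        raise InsufficientDataError("empty coordination series")
    values, counts = np.unique(series.counts, return_counts=True)
    pct = {int(v): 100.0 * c / len(series.counts) for v, c in zip(values, counts)}
    return CoordinationPopulation(percentages=pct)


# ---------------------------------------------------------------------------
# Ligand distance table
# ---------------------------------------------------------------------------

def ligand_distance_table(traj: Trajectory, ion: int, candidate_atoms,
                          species: str) -> LigandDistanceTable:
    """Mean +/- sd ion-oxygen distance per candidate atom, with a bonded
    flag set by the species threshold applied to the mean; sorted by resid.
    """
    species = species.upper()
    if species not in BONDING_THRESHOLDS:
        raise ParameterError(
            f"unknown species {species!r}; expected one of {sorted(BONDING_THRESHOLDS)}"
        )
    _check_ion(traj, ion)
    indices = _resolve(traj, candidate_atoms)
    threshold = BONDING_THRESHOLDS[species]
    records = []
    ion_xyz = traj.coords[:, ion, :]
    for idx in indices:
        d = np.linalg.norm(traj.coords[:, idx, :] - ion_xyz, axis=1)
        atom = traj.topology.atoms[idx]
        mean = float(np.mean(d))
        records.append(
            {
                "residue": f"{atom.resname}{atom.resid}",
                "resid": atom.resid,
                "atom_name": atom.name,
                "mean_nm": mean,
                "sd_nm": float(np.std(d)),
                "bonded": bool(mean < threshold),
            }
        )
    rows = pd.DataFrame(records,
                        columns=["residue", "resid", "atom_name",
                                 "mean_nm", "sd_nm", "bonded"])
    rows = rows.sort_values(["resid", "atom_name"], kind="stable").reset_index(drop=True)
    return LigandDistanceTable(species=species, rows=rows)


# ---------------------------------------------------------------------------
# Binding events and gateway contacts
# ---------------------------------------------------------------------------

def detect_binding_event(traj: Trajectory, ion: int, site_atoms, cutoff: float,
                         dwell: int = 10, site: str = "") -> BindingEvent | None:
    """First time the ion stays within `cutoff` of >= 1 site atom for at
    least `dwell` consecutive frames; None if no such run exists.
    """
    _check_ion(traj, ion)
    if dwell < 1:
        raise ParameterError("dwell must be >= 1")
    site_idx = _resolve(traj, site_atoms)
    if not site_idx:
        raise SelectionError("empty site selection")
    ion_xyz = traj.coords[:, ion, :]
    site_xyz = traj.coords[:, site_idx, :]
    dmin = np.min(np.linalg.norm(site_xyz - ion_xyz[:, None, :], axis=2), axis=1)
    inside = dmin < cutoff
    run = 0
    for k, flag in enumerate(inside):
        run = run + 1 if flag else 0
        if run >= dwell:
            start = k - dwell + 1
            sustained = bool(np.all(inside[start:]))
            return BindingEvent(ion=ion, site=site,
                                t_on=float(traj.times[start]), sustained=sustained)
    return None


def gateway_contact_order(traj: Trajectory, ion: int, gateway_resids,
                          contact_cutoff: float) -> list[tuple[int, float]]:
    """First-contact time of the ion with each gateway residue's side-chain
    oxygens, sorted by time; residues never contacted are omitted.
    """
    _check_ion(traj, ion)
    ion_xyz = traj.coords[:, ion, :]
    out: list[tuple[int, float]] = []
    backbone_o = {"O", "OT1", "OT2", "OXT"}
    for resid in gateway_resids:
        idx = [
            i for i, a in enumerate(traj.topology.atoms)
            if a.resid == resid and a.element.upper() == "O"
            and a.name not in backbone_o
        ]
        if not idx:
            continue
        d = np.min(
            np.linalg.norm(traj.coords[:, idx, :] - ion_xyz[:, None, :], axis=2),
            axis=1,
        )
        hits = np.flatnonzero(d < contact_cutoff)
        if hits.size:
            out.append((resid, float(traj.times[hits[0]])))
    out.sort(key=lambda item: item[1])
    return out


# ---------------------------------------------------------------------------
# Nonbonded interaction energy
# ---------------------------------------------------------------------------

def interaction_energy(traj: Trajectory, ion: int, partner_sel,
                       params: NonbondedParams,
                       include_lj: bool = True) -> tuple[float, np.ndarray]:
    """Trajectory-averaged nonbonded ion-partner energy (kcal/mol).

    Per frame: sum over partner atoms of the Coulomb term
    (332.0636 * qi * qj / (eps_r * r_A)) plus 12-6 Lennard-Jones with
    Lorentz-Berthelot combining. No distance cutoff. This is an estimate:
    it is only as good as the parameter table supplied.

    Returns (mean_energy, per_frame_series).
    """
    _check_ion(traj, ion)
    partners = _resolve(traj, partner_sel)
    params.require(ion, traj.topology)
    for idx in partners:
        params.require(idx, traj.topology)

    q_ion = params.charges[ion]
    q = np.array([params.charges[i] for i in partners])
    r_A = (
        np.linalg.norm(traj.coords[:, partners, :] - traj.coords[:, ion, :][:, None, :],
                       axis=2)
        * NM_TO_ANGSTROM
    )
    energy = np.sum(COULOMB_KCAL_A * q_ion * q / (params.dielectric * r_A), axis=1)

    if include_lj and partners and ion in params.epsilon:
        eps = np.array([
            np.sqrt(params.epsilon.get(i, 0.0) * params.epsilon[ion])
            for i in partners
        ])
        rmin_A = np.array([
            0.5 * (params.rmin.get(i, 0.0) + params.rmin[ion])
            for i in partners
        ]) * NM_TO_ANGSTROM
        ratio6 = (rmin_A / r_A) ** 6
        energy = energy + np.sum(eps * (ratio6**2 - 2.0 * ratio6), axis=1)

    return float(np.mean(energy)), energy
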
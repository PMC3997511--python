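"""Synthetic trajectory generators with ground-truth manifests.

Each generator returns an in-memory :class:`~iontraj.structio.Trajectory`
plus a :class:`GroundTruthManifest` that records every parameter actually
used and the derived expectations (stationary coordination-number law,
expected RMSF, expected state occupancies, mixture parameters), so
parameter-recovery tests never re-derive their targets at run time.

State switching uses Markov chains rather than independent draws — the
analyses must be robust to the temporal correlation real trajectories have.
The default correlation structure is a switching chain whose rows are
``(1 - a) * I + a * 1 pi^T`` (stationary law exactly ``pi``, mean dwell
``1/a`` frames).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .structio import (
    AtomRecord,
    Topology,
    Trajectory,
    default_domain_map,
    write_trajectory,
)

DEFAULT_FRAME_DT = 0.0001  # us per frame at 20k frames -> 2 us of pseudo-time


@dataclass
class GroundTruthManifest:
    """Everything needed to recompute a generator's expectations."""

    kind: str
    seed: int
    parameters: dict
    expectations: dict
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "seed": self.seed,
            "parameters": self.parameters,
            "expectations": self.expectations,
            "warnings": self.warnings,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _switching_chain(rng: np.random.Generator, stationary, n: int,
                     switch_rate: float) -> np.ndarray:
    """Markov chain with rows (1-a) I + a 1 pi^T; stationary law == pi."""
    pi = np.asarray(stationary, dtype=float)
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ParameterError("stationary distribution must be a probability vector")
    if not 0 < switch_rate <= 1:
        raise ParameterError("switch_rate must be in (0, 1]")
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(len(pi), p=pi)
    redraw = rng.random(n) < switch_rate
    draws = rng.choice(len(pi), size=n, p=pi)
    for k in range(1, n):
        states[k] = draws[k] if redraw[k] else states[k - 1]
    return states


# ---------------------------------------------------------------------------
# Ion coordination site
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LigandSpec:
    resname: str
    resid: int
    atom_name: str
    target_nm: float
    is_water: bool = False


@dataclass(frozen=True)
class SitePreset:
    """Ion-in-a-cage preset with Markov-switching shell occupancy.

    The Markov state picks a coordination number from ``cn_values``; the
    first k ligands (in listed order) sit at their target distances, the
    rest are displaced to ``cutoff + excluded_offset``. The ion carries
    isotropic Gaussian jitter of per-axis sd ``jitter_sd`` (so its expected
    RMSF is ``jitter_sd * sqrt(3)``); ligand oxygens ride the ion with a
    small uniform radial wobble ``ligand_noise``.
    """

    name: str
    species: str
    cutoff: float
    ligands: tuple[LigandSpec, ...]
    cn_values: tuple[int, ...]
    stationary: tuple[float, ...]
    jitter_sd: float
    ligand_noise: float = 0.003
    excluded_offset: float = 0.08
    switch_rate: float = 0.1
    frames: int = 20000

    def __post_init__(self):
        if len(self.cn_values) != len(self.stationary):
            raise ParameterError("cn_values and stationary lengths differ")
        if abs(sum(self.stationary) - 1.0) > 1e-9:
            raise ParameterError("stationary distribution must sum to 1")
        if max(self.cn_values) > len(self.ligands):
            raise ParameterError(
                f"preset {self.name}: max coordination number "
                f"{max(self.cn_values)} exceeds ligand count {len(self.ligands)}"
            )
        for lig in self.ligands:
            if lig.target_nm + self.ligand_noise >= self.cutoff:
                raise ParameterError(
                    f"preset {self.name}: ligand {lig.atom_name} target "
                    f"{lig.target_nm} + noise reaches the cutoff {self.cutoff}"
                )


_CAGE_DIRECTIONS = np.array(
    [
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [0.57735027, 0.57735027, 0.57735027],
        [-0.57735027, -0.57735027, 0.57735027],
    ]
)

_ANCHOR_POSITIONS = np.array(
    [[1.0, 1.0, 1.0], [-1.0, -1.0, 1.0], [-1.0, 1.0, -1.0], [1.0, -1.0, -1.0]]
)


def gen_ion_site(preset: SitePreset, seed: int = 0,
                 frame_dt: float = DEFAULT_FRAME_DT) -> tuple[Trajectory, GroundTruthManifest]:
    """Generate an ion-in-a-cage trajectory following `preset`.

    The topology contains the ion, the cage oxygens (protein-labelled and
    water), and four static CA anchor atoms for alignment (selection
    ``"name CA"``).
    """
    if len(preset.ligands) > len(_CAGE_DIRECTIONS):
        raise ParameterError(
            f"{len(preset.ligands)} ligands exceed the "
            f"{len(_CAGE_DIRECTIONS)} placeable cage directions"
        )
    rng = np.random.default_rng(seed)
    n = preset.frames

    atoms: list[AtomRecord] = [
        AtomRecord(serial=1, name=preset.species, element=preset.species,
                   resname=preset.species, resid=1001)
    ]
    for j, lig in enumerate(preset.ligands):
        atoms.append(
            AtomRecord(serial=2 + j, name=lig.atom_name, element="O",
                       resname=lig.resname, resid=lig.resid)
        )
    n_lig = len(preset.ligands)
    for j in range(len(_ANCHOR_POSITIONS)):
        atoms.append(
            AtomRecord(serial=2 + n_lig + j, name="CA", element="C",
                       resname="GLY", resid=9001 + j)
        )
    topology = Topology.from_atoms(atoms)

    states = _switching_chain(rng, preset.stationary, n, preset.switch_rate)
    cn = np.asarray(preset.cn_values)[states]

    ion = rng.normal(0.0, preset.jitter_sd, size=(n, 3))
    coords = np.empty((n, len(atoms), 3))
    coords[:, 0, :] = ion
    for j, lig in enumerate(preset.ligands):
        included = cn > j
        wobble = rng.uniform(-preset.ligand_noise, preset.ligand_noise, size=n)
        dist = np.where(included, lig.target_nm,
                        preset.cutoff + preset.excluded_offset) + wobble
        coords[:, 1 + j, :] = ion + dist[:, None] * _CAGE_DIRECTIONS[j]
    coords[:, 1 + n_lig:, :] = _ANCHOR_POSITIONS[None, :, :]

    traj = Trajectory(topology=topology, times=np.arange(n) * frame_dt, coords=coords)

    pi = np.asarray(preset.stationary)
    inclusion = np.array([np.sum(pi[np.asarray(preset.cn_values) > j])
                          for j in range(n_lig)])
    expected_means = {
        f"{lig.resname}{lig.resid}:{lig.atom_name}": float(
            inclusion[j] * lig.target_nm
            + (1 - inclusion[j]) * (preset.cutoff + preset.excluded_offset)
        )
        for j, lig in enumerate(preset.ligands)
    }
    manifest = GroundTruthManifest(
        kind="ion_site",
        seed=seed,
        parameters={
            "preset": preset.name,
            "species": preset.species,
            "cutoff_nm": preset.cutoff,
            "ligands": [asdict(l) for l in preset.ligands],
            "cn_values": list(preset.cn_values),
            "stationary": list(preset.stationary),
            "jitter_sd_nm": preset.jitter_sd,
            "ligand_noise_nm": preset.ligand_noise,
            "excluded_offset_nm": preset.excluded_offset,
            "switch_rate": preset.switch_rate,
            "frames": preset.frames,
            "frame_dt_us": frame_dt,
            "ion_index": 0,
            "align_selection": "name CA",
        },
        expectations={
            "cn_stationary": {str(v): float(p)
                              for v, p in zip(preset.cn_values, preset.stationary)},
            "expected_rmsf_nm": float(preset.jitter_sd * np.sqrt(3.0)),
            "expected_ligand_means_nm": expected_means,
        },
    )
    return traj, manifest


# ---------------------------------------------------------------------------
# Two-state dihedral
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DihedralPreset:
    """Two-state Markov chi2 dihedral with angular jitter."""

    name: str
    resid: int
    state_centers: tuple[float, float]  # (lumen-facing, cytosol-facing), degrees
    stationary_lumen: float
    angle_sd: float = 8.0
    switch_rate: float = 0.4
    frames: int = 20000

    def __post_init__(self):
        if not 0 < self.stationary_lumen < 1:
            raise ParameterError("stationary lumen fraction must be in (0, 1)")


def _window_escape_probability(center: float, sd: float) -> float:
    """Probability that a jittered angle leaves its classification window."""
    from scipy import stats

    mag = abs(center)
    if mag >= 120.0:  # lumen: escapes only below 120 (wrap at 180 stays lumen)
        return float(stats.norm.cdf((120.0 - mag) / sd))
    lo, hi = 40.0, 120.0
    return float(stats.norm.cdf((lo - mag) / sd)
                 + stats.norm.sf((hi - mag) / sd))


def gen_dihedral(preset: DihedralPreset, seed: int = 0,
                 frame_dt: float = DEFAULT_FRAME_DT) -> tuple[Trajectory, GroundTruthManifest]:
    """Four-atom side-chain fragment (CA, CB, CG, CD of a glutamate) whose
    chi2 follows a two-state Markov chain with Gaussian angular jitter.
    """
    rng = np.random.default_rng(seed)
    n = preset.frames

    resid = preset.resid
    atoms = [
        AtomRecord(serial=1, name="CA", element="C", resname="GLU", resid=resid),
        AtomRecord(serial=2, name="CB", element="C", resname="GLU", resid=resid),
        AtomRecord(serial=3, name="CG", element="C", resname="GLU", resid=resid),
        AtomRecord(serial=4, name="CD", element="C", resname="GLU", resid=resid),
    ]
    topology = Topology.from_atoms(atoms)

    p_lumen = preset.stationary_lumen
    states = _switching_chain(rng, (p_lumen, 1.0 - p_lumen), n, preset.switch_rate)
    centers = np.asarray(preset.state_centers)[states]
    angles = centers + rng.normal(0.0, preset.angle_sd, size=n)
    angles = ((angles + 180.0) % 360.0) - 180.0
    angles[angles == -180.0] = 180.0

    ca = np.array([0.15, 0.0, -0.05])
    cb = np.zeros(3)
    cg = np.array([0.0, 0.0, 0.15])
    cd_offset = np.array([0.15, 0.0, 0.05])  # cis position relative to CG

    rad = np.radians(angles)
    cos, sin = np.cos(rad), np.sin(rad)
    coords = np.empty((n, 4, 3))
    coords[:, 0, :] = ca
    coords[:, 1, :] = cb
    coords[:, 2, :] = cg
    # rotate the cis CD offset about the CB->CG axis (+z) by chi2
    coords[:, 3, 0] = cg[0] + cos * cd_offset[0] - sin * cd_offset[1]
    coords[:, 3, 1] = cg[1] + sin * cd_offset[0] + cos * cd_offset[1]
    coords[:, 3, 2] = cg[2] + cd_offset[2]

    traj = Trajectory(topology=topology, times=np.arange(n) * frame_dt, coords=coords)

    warnings = []
    for center in preset.state_centers:
        escape = _window_escape_probability(center, preset.angle_sd)
        if escape > 0.01:
            warnings.append(
                f"state at {center} deg crosses its window boundary with "
                f"probability {escape:.3f} (> 0.01)"
            )

    manifest = GroundTruthManifest(
        kind="dihedral",
        seed=seed,
        parameters={
            "preset": preset.name,
            "resid": preset.resid,
            "state_centers_deg": list(preset.state_centers),
            "stationary_lumen": p_lumen,
            "angle_sd_deg": preset.angle_sd,
            "switch_rate": preset.switch_rate,
            "frames": preset.frames,
            "frame_dt_us": frame_dt,
        },
        expectations={"lumen_fraction_percent": 100.0 * p_lumen},
        warnings=warnings,
    )
    return traj, manifest


# ---------------------------------------------------------------------------
# Headpiece marker distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairLaw:
    """Marginal mixture law for one interdomain distance."""

    order: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self):
        if self.order not in (1, 2):
            raise ParameterError("pair law order must be 1 or 2")
        if not (len(self.weights) == len(self.means) == len(self.sds) == self.order):
            raise ParameterError("pair law component lengths inconsistent")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ParameterError("pair law weights must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ParameterError("pair law sds must be positive")
        if any(m <= 0 for m in self.means):
            raise ParameterError("pair law means must be positive distances")


@dataclass(frozen=True)
class HeadpiecePreset:
    name: str
    pairs: dict  # pair name -> PairLaw for "N-A", "N-P", "A-P"
    autocorr_frames: float = 20.0
    frames: int = 20000

    def __post_init__(self):
        for required in ("N-A", "N-P", "A-P"):
            if required not in self.pairs:
                raise ParameterError(f"headpiece preset missing pair {required}")


def _pair_distance_process(rng: np.random.Generator, law: PairLaw, n: int,
                           autocorr_frames: float) -> np.ndarray:
    """Distance trace with the requested marginal mixture law: Markov state
    switching between components plus within-state AR(1) jitter.
    """
    phi = float(np.exp(-1.0 / autocorr_frames))
    switch_rate = min(1.0, 1.0 / autocorr_frames)
    if law.order == 1:
        states = np.zeros(n, dtype=int)
    else:
        states = _switching_chain(rng, law.weights, n, switch_rate)
    innovations = rng.normal(0.0, 1.0, size=n)
    e = np.empty(n)
    e[0] = innovations[0]
    scale = np.sqrt(1.0 - phi**2)
    for k in range(1, n):
        e[k] = phi * e[k - 1] + scale * innovations[k]
    means = np.asarray(law.means)[states]
    sds = np.asarray(law.sds)[states]
    return np.maximum(means + sds * e, 0.05)


def gen_headpiece(preset: HeadpiecePreset, seed: int = 0,
                  frame_dt: float = DEFAULT_FRAME_DT) -> tuple[Trajectory, GroundTruthManifest]:
    """Four marker CA atoms (K515, T171, R489, E680) placed on a chain so
    that the three registry pair distances follow the preset's mixture laws
    exactly and independently.
    """
    rng = np.random.default_rng(seed)
    n = preset.frames

    d_na = _pair_distance_process(rng, preset.pairs["N-A"], n, preset.autocorr_frames)
    d_np = _pair_distance_process(rng, preset.pairs["N-P"], n, preset.autocorr_frames)
    d_ap = _pair_distance_process(rng, preset.pairs["A-P"], n, preset.autocorr_frames)

    atoms = [
        AtomRecord(serial=1, name="CA", element="C", resname="THR", resid=171),
        AtomRecord(serial=2, name="CA", element="C", resname="LYS", resid=515),
        AtomRecord(serial=3, name="CA", element="C", resname="GLU", resid=680),
        AtomRecord(serial=4, name="CA", element="C", resname="ARG", resid=489),
    ]
    topology = Topology.from_atoms(atoms)

    # chain placement: T171 at origin; K515 along +x (N-A distance);
    # E680 along +y (A-P distance); R489 above E680 along +z (N-P distance)
    coords = np.zeros((n, 4, 3))
    coords[:, 1, 0] = d_na
    coords[:, 2, 1] = d_ap
    coords[:, 3, 1] = d_ap
    coords[:, 3, 2] = d_np

    traj = Trajectory(topology=topology, times=np.arange(n) * frame_dt, coords=coords)
    manifest = GroundTruthManifest(
        kind="headpiece",
        seed=seed,
        parameters={
            "preset": preset.name,
            "autocorr_frames": preset.autocorr_frames,
            "frames": preset.frames,
            "frame_dt_us": frame_dt,
            "pairs": {name: asdict(law) for name, law in preset.pairs.items()},
        },
        expectations={
            "mixture": {
                name: {"order": law.order, "weights": list(law.weights),
                       "means_nm": list(law.means), "sds_nm": list(law.sds)}
                for name, law in preset.pairs.items()
            }
        },
    )
    return traj, manifest


# ---------------------------------------------------------------------------
# Rigid rotation and scripted ion paths
# ---------------------------------------------------------------------------

def gen_rotation(reference: np.ndarray, total_angle: float, frames: int,
                 noise_sd: float = 0.0, seed: int = 0,
                 frame_dt: float = 0.001) -> Trajectory:
    """Linear ramp of rotation about +z from 0 to `total_angle` degrees with
    additive Gaussian coordinate noise.
    """
    if frames < 2:
        raise ParameterError("gen_rotation requires at least 2 frames")
    rng = np.random.default_rng(seed)
    reference = np.asarray(reference, dtype=float)
    n_atoms = reference.shape[0]
    atoms = [
        AtomRecord(serial=i + 1, name="CA", element="C", resname="GLY", resid=i + 1)
        for i in range(n_atoms)
    ]
    topology = Topology.from_atoms(atoms)
    coords = np.empty((frames, n_atoms, 3))
    for k in range(frames):
        theta = np.radians(total_angle * k / (frames - 1))
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        coords[k] = reference @ R.T
    if noise_sd > 0:
        coords += rng.normal(0.0, noise_sd, size=coords.shape)
    return Trajectory(topology=topology, times=np.arange(frames) * frame_dt,
                      coords=coords)


def gen_binding_approach(entry_frame: int, frames: int = 1000,
                         frame_dt: float = 0.001, cutoff: float = 0.30,
                         species: str = "K") -> Trajectory:
    """Scripted ion approach: strictly outside `cutoff` of the single site
    oxygen before `entry_frame`, strictly inside from `entry_frame` on.
    """
    if not 0 <= entry_frame < frames:
        raise ParameterError("entry_frame must lie within the trajectory")
    atoms = [
        AtomRecord(serial=1, name="OD1", element="O", resname="ASP", resid=800),
        AtomRecord(serial=2, name=species, element=species, resname=species,
                   resid=2001),
    ]
    topology = Topology.from_atoms(atoms)
    coords = np.zeros((frames, 2, 3))
    k = np.arange(frames)
    approach = cutoff + 0.01 * np.maximum(entry_frame - k, 0) + 0.02
    inside = cutoff - 0.05
    coords[:, 1, 0] = np.where(k < entry_frame, approach, inside)
    return Trajectory(topology=topology, times=k * frame_dt, coords=coords)


def gen_gateway_path(gateway_resids=(55, 58, 59, 109), frames: int = 500,
                     frame_dt: float = 0.001, spacing: float = 0.5,
                     species: str = "K") -> Trajectory:
    """Scripted ion path sweeping past one side-chain oxygen per gateway
    residue (placed `spacing` nm apart along +x, in listed order).
    """
    atoms = [
        AtomRecord(serial=j + 1, name="OE1", element="O", resname="GLU", resid=r)
        for j, r in enumerate(gateway_resids)
    ]
    atoms.append(
        AtomRecord(serial=len(atoms) + 1, name=species, element=species,
                   resname=species, resid=2001)
    )
    topology = Topology.from_atoms(atoms)
    n_gate = len(gateway_resids)
    coords = np.zeros((frames, n_gate + 1, 3))
    for j in range(n_gate):
        coords[:, j, 0] = j * spacing
        coords[:, j, 1] = 0.1
    start = -2.0 * spacing
    end = (n_gate + 0.5) * spacing
    coords[:, n_gate, 0] = np.linspace(start, end, frames)
    return Trajectory(topology=topology, times=np.arange(frames) * frame_dt,
                      coords=coords)


# ---------------------------------------------------------------------------
# Presets encoding the repo's documented target values
# ---------------------------------------------------------------------------
#
# Targets slightly below the coordination cutoff (e.g. 0.206 instead of an
# exactly-at-cutoff 0.21) keep bonded ligands strictly inside the strict
# inequality; manifests carry the exact values used.

MG_SITE_PRESET = SitePreset(
    name="MG_SITE",
    species="MG",
    cutoff=0.21,
    ligands=(
        LigandSpec("GLU", 771, "OE1", 0.200),
        LigandSpec("GLU", 771, "OE2", 0.200),
        LigandSpec("ASP", 800, "OD1", 0.200),
        LigandSpec("ASP", 800, "OD2", 0.200),
        LigandSpec("ASN", 796, "OD1", 0.206),
        LigandSpec("TIP3", 5001, "OH2", 0.205, is_water=True),
        LigandSpec("TIP3", 5002, "OH2", 0.205, is_water=True),
    ),
    cn_values=(4, 5, 6, 7),
    stationary=(0.01, 0.14, 0.80, 0.05),
    jitter_sd=0.04 / np.sqrt(3.0),  # expected RMSF exactly 0.04 nm
)

K_I_SITE_PRESET = SitePreset(
    name="K_I_SITE",
    species="K",
    cutoff=0.30,
    ligands=(
        LigandSpec("GLU", 771, "OE1", 0.270),
        LigandSpec("THR", 799, "OG1", 0.290),
        LigandSpec("ASP", 800, "OD1", 0.295),
        LigandSpec("ASP", 800, "OD2", 0.295),
        LigandSpec("GLU", 908, "OE1", 0.290),
        LigandSpec("TIP3", 5001, "OH2", 0.285, is_water=True),
        LigandSpec("TIP3", 5002, "OH2", 0.285, is_water=True),
    ),
    cn_values=(2, 3, 4, 5, 6, 7),
    stationary=(0.05, 0.20, 0.36, 0.29, 0.09, 0.01),
    jitter_sd=0.06 / np.sqrt(3.0),
)

K_IPRIME_SITE_PRESET = SitePreset(
    name="K_IPRIME_SITE",
    species="K",
    cutoff=0.30,
    ligands=(
        LigandSpec("ALA", 305, "O", 0.260),
        LigandSpec("ASP", 800, "OD1", 0.295),
        LigandSpec("GLU", 771, "OE2", 0.290),
        LigandSpec("ASN", 796, "OD1", 0.290),
        LigandSpec("GLU", 908, "OE2", 0.290),
        LigandSpec("TIP3", 5001, "OH2", 0.285, is_water=True),
        LigandSpec("TIP3", 5002, "OH2", 0.285, is_water=True),
    ),
    cn_values=(2, 3, 4, 5, 6, 7),
    stationary=(0.05, 0.22, 0.38, 0.26, 0.085, 0.005),
    jitter_sd=0.06 / np.sqrt(3.0),
)

E1_MG_DIHEDRAL_PRESET = DihedralPreset(
    name="E1_MG_DIHEDRAL", resid=309,
    state_centers=(150.0, 80.0), stationary_lumen=0.62,
)

E1_2K_DIHEDRAL_PRESET = DihedralPreset(
    name="E1_2K_DIHEDRAL", resid=309,
    state_centers=(150.0, 80.0), stationary_lumen=0.69,
)

# sds below are repository constants (0.15 nm unimodal, 0.12 nm per
# bimodal component); the E1_MG A-P mean 2.1 nm is likewise a repo choice.
E1_MG_HEADPIECE_PRESET = HeadpiecePreset(
    name="E1_MG_HEADPIECE",
    pairs={
        "N-A": PairLaw(1, (1.0,), (2.7,), (0.15,)),
        "N-P": PairLaw(1, (1.0,), (0.95,), (0.15,)),
        "A-P": PairLaw(1, (1.0,), (2.1,), (0.15,)),
    },
)

E1_2K_HEADPIECE_PRESET = HeadpiecePreset(
    name="E1_2K_HEADPIECE",
    pairs={
        "N-A": PairLaw(2, (0.5, 0.5), (3.3, 3.8), (0.12, 0.12)),
        "N-P": PairLaw(2, (0.5, 0.5), (1.6, 2.4), (0.12, 0.12)),
        "A-P": PairLaw(1, (1.0,), (2.6,), (0.15,)),
    },
)

ENSEMBLES = {
    "E1_MG": {
        "site": (MG_SITE_PRESET,),
        "dihedral": E1_MG_DIHEDRAL_PRESET,
        "headpiece": E1_MG_HEADPIECE_PRESET,
    },
    "E1_2K": {
        "site": (K_I_SITE_PRESET, K_IPRIME_SITE_PRESET),
        "dihedral": E1_2K_DIHEDRAL_PRESET,
        "headpiece": E1_2K_HEADPIECE_PRESET,
    },
}


def gen_fixture_bundle(ensemble: str, out_dir, seed: int = 0,
                       frames: int | None = None) -> dict[str, Path]:
    """Write an ensemble's multi-model PDB fixtures, domain map, nonbonded
    parameter stub, and combined ground-truth manifest to `out_dir`.

    `frames` overrides every preset's frame count (handy for small files).
    Returns a dict of written paths.
    """
    try:
        spec = ENSEMBLES[ensemble]
    except KeyError:
        raise ParameterError(
            f"unknown ensemble {ensemble!r}; known: {sorted(ENSEMBLES)}"
        ) from None
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    combined: dict = {"ensemble": ensemble, "seed": seed, "members": {}}

    import dataclasses as _dc

    def _resize(preset):
        if frames is None:
            return preset
        return _dc.replace(preset, frames=frames)

    for i, site_preset in enumerate(spec["site"]):
        traj, manifest = gen_ion_site(_resize(site_preset), seed=seed + i)
        path = out / f"site_{site_preset.name.lower()}.pdb"
        write_trajectory(traj, path)
        written[f"site_{i}"] = path
        combined["members"][f"site_{site_preset.name}"] = manifest.to_dict()

    traj, manifest = gen_dihedral(_resize(spec["dihedral"]), seed=seed + 10)
    path = out / "dihedral.pdb"
    write_trajectory(traj, path)
    written["dihedral"] = path
    combined["members"]["dihedral"] = manifest.to_dict()

    traj, manifest = gen_headpiece(_resize(spec["headpiece"]), seed=seed + 20)
    path = out / "headpiece.pdb"
    write_trajectory(traj, path)
    written["headpiece"] = path
    combined["members"]["headpiece"] = manifest.to_dict()

    dm_path = out / "domain_map.yaml"
    dm = default_domain_map()
    with open(dm_path, "w") as fh:
        yaml_ranges = {
            dom: [list(r) for r in ranges] for dom, ranges in dm.domains.items()
        }
        import yaml as _yaml

        _yaml.safe_dump({"domains": yaml_ranges}, fh, sort_keys=True)
    written["domain_map"] = dm_path

    nb_path = out / "nonbonded_params.tsv"
    with open(nb_path, "w") as fh:
        fh.write("# selection\tcharge_e\tepsilon_kcal_mol\trmin_nm\n")
        fh.write("resname MG\t2.0\t0.0015\t0.1185\n")
        fh.write("resname K\t1.0\t0.0870\t0.1763\n")
        fh.write("element O\t-0.76\t0.1200\t0.1700\n")
    written["nonbonded_params"] = nb_path

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(combined, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written["manifest"] = manifest_path
    return written
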
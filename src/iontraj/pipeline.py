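"""Configuration-driven orchestration of the full analysis battery.

A :class:`RunConfig` (usually loaded from YAML) names input trajectories
and toggles stages; :func:`run_analysis` executes every enabled stage,
isolating failures so one broken stage cannot corrupt the others, and
writes a :class:`ReportBundle` of CSV tables and JSON summaries with full
provenance. Identical config + inputs give byte-identical tables;
wall-clock timings live only in the run log.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .conformation import (
    BUILTIN_PAIRS,
    carboxyl_pair_series,
    chi2_series,
    classify_chi2_series,
)
from .errors import ParameterError
from .geomcore import axial_rotation_angle, rmsd_series, rmsf
from .headpiece import (
    compare_to_crystal,
    estimate_density,
    fit_mixture,
    interdomain_series,
    select_model,
    write_fit_report,
)
from .ionsite import (
    coordination_population,
    coordination_series,
    detect_binding_event,
    ligand_distance_table,
)
from .structio import load_domain_map, read_structure, read_trajectory


@dataclass
class RunConfig:
    """Validated run configuration.

    ``ions`` is a list of dicts, one per ion assignment, each naming its
    trajectory, the ion's atom index (or species to auto-locate), cutoff,
    stride and optional rmsf/binding settings. Stage dicts that are absent
    or falsy disable that stage.
    """

    output_dir: Path
    frame_dt: float = 0.01
    seed: int = 0
    domain_map: Path | None = None
    ions: list = field(default_factory=list)
    chi2: dict | None = None
    carboxyl_pairs: dict | None = None
    rmsd: dict | None = None
    axial_rotation: dict | None = None
    headpiece: dict | None = None
    crystal_refs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides or {})
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        def respath(value):
            p = Path(value)
            return p if p.is_absolute() else base / p

        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ParameterError("config must set output_dir")
        cfg = cls(
            output_dir=respath(raw["output_dir"]),
            frame_dt=float(raw.get("frame_dt", 0.01)),
            seed=int(raw.get("seed", 0)),
            domain_map=respath(raw["domain_map"]) if raw.get("domain_map") else None,
            ions=raw.get("ions") or [],
            chi2=raw.get("chi2") or None,
            carboxyl_pairs=raw.get("carboxyl_pairs") or None,
            rmsd=raw.get("rmsd") or None,
            axial_rotation=raw.get("axial_rotation") or None,
            headpiece=raw.get("headpiece") or None,
            crystal_refs=raw.get("crystal_refs") or {},
        )
        for entry in cfg.ions:
            entry["trajectory"] = str(respath(entry["trajectory"]))
        for stage in (cfg.chi2, cfg.carboxyl_pairs, cfg.rmsd,
                      cfg.axial_rotation, cfg.headpiece):
            if stage and "trajectory" in stage:
                stage["trajectory"] = str(respath(stage["trajectory"]))
        cfg.crystal_refs = {k: str(respath(v)) for k, v in cfg.crystal_refs.items()}
        return cfg

    def canonical_dict(self) -> dict:
        return {
            "output_dir": str(self.output_dir),
            "frame_dt": self.frame_dt,
            "seed": self.seed,
            "domain_map": str(self.domain_map) if self.domain_map else None,
            "ions": self.ions,
            "chi2": self.chi2,
            "carboxyl_pairs": self.carboxyl_pairs,
            "rmsd": self.rmsd,
            "axial_rotation": self.axial_rotation,
            "headpiece": self.headpiece,
            "crystal_refs": self.crystal_refs,
        }

    def digest(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ReportBundle:
    output_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    summaries: dict[str, Path] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)
    partial: bool = False

    def record(self, stage: str, status: str, seconds: float, **extra) -> None:
        self.log.append({"stage": stage, "status": status,
                         "seconds": round(seconds, 3), **extra})

    def write_log(self, config: RunConfig) -> None:
        payload = {
            "iontraj_version": __version__,
            "config_sha256": config.digest(),
            "partial": self.partial,
            "stages": self.log,
            "tables": {k: str(v) for k, v in sorted(self.tables.items())},
            "summaries": {k: str(v) for k, v in sorted(self.summaries.items())},
        }
        with open(self.output_dir / "run_log.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _find_ion_index(traj, entry: dict) -> int:
    if "index" in entry:
        return int(entry["index"])
    species = entry.get("species", "").upper()
    matches = [i for i, sp in traj.topology.ion_atoms.items() if sp == species]
    if len(matches) != 1:
        raise ParameterError(
            f"ion assignment {entry.get('name', '?')!r}: species {species!r} "
            f"matched {len(matches)} atoms; give an explicit index"
        )
    return matches[0]


def run_analysis(config: RunConfig) -> ReportBundle:
    """Execute every enabled stage of the analysis battery.

    Stage failures are caught, logged, and leave the remaining independent
    stages running; the bundle is then marked partial.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(output_dir=out)

    domain_map = load_domain_map(config.domain_map) if config.domain_map else None
    traj_cache: dict[str, object] = {}

    def load(path: str):
        if path not in traj_cache:
            traj = read_trajectory(path, frame_dt=config.frame_dt)
            if domain_map is not None:
                traj.topology = traj.topology.with_domain_map(domain_map)
            traj_cache[path] = traj
        return traj_cache[path]

    def stage(name: str):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                extra = fn() or {}
                bundle.record(name, "ok", time.perf_counter() - t0, **extra)
            except Exception as exc:  # isolation: log and continue
                bundle.record(name, "error", time.perf_counter() - t0,
                              error=f"{type(exc).__name__}: {exc}")
                bundle.partial = True
        return wrap

    for entry in config.ions:
        label = entry.get("name", f"ion{config.ions.index(entry)}")
        safe = label.replace("'", "p").replace(" ", "_")

        @stage(f"ion:{label}")
        def _ion_stage(entry=entry, label=label, safe=safe):
            traj = load(entry["trajectory"])
            ion = _find_ion_index(traj, entry)
            species = traj.topology.ion_atoms[ion]
            cutoff = float(entry.get("cutoff", 0.21 if species == "MG" else 0.30))
            stride = int(entry.get("stride", 1))
            series = coordination_series(traj, ion, cutoff, stride=stride)
            pop = coordination_population(series)
            pop_path = out / f"coordination_population_{safe}.csv"
            pop.write_csv(pop_path)
            bundle.tables[f"coordination_population_{safe}"] = pop_path

            table = ligand_distance_table(
                traj, ion, entry.get("ligand_selection", "element O and not water"),
                species,
            )
            tbl_path = out / f"ligand_distances_{safe}.csv"
            table.write_csv(tbl_path)
            bundle.tables[f"ligand_distances_{safe}"] = tbl_path

            extra = {"ion_index": ion, "species": species,
                     "cutoff_nm": cutoff, "n_samples": len(series.counts)}
            if entry.get("rmsf_align"):
                value = rmsf(traj, [ion], entry["rmsf_align"])[0]
                rmsf_path = out / f"rmsf_{safe}.json"
                with open(rmsf_path, "w") as fh:
                    json.dump({"ion": label, "rmsf_nm": float(value)}, fh, indent=1)
                    fh.write("\n")
                bundle.summaries[f"rmsf_{safe}"] = rmsf_path
                extra["rmsf_nm"] = float(value)
            if entry.get("binding_site"):
                event = detect_binding_event(
                    traj, ion, entry["binding_site"], cutoff,
                    dwell=int(entry.get("dwell", 10)), site=label,
                )
                evt_path = out / f"binding_event_{safe}.json"
                with open(evt_path, "w") as fh:
                    payload = (
                        {"site": label, "t_on_us": event.t_on,
                         "sustained": event.sustained}
                        if event else {"site": label, "t_on_us": None}
                    )
                    json.dump(payload, fh, indent=1)
                    fh.write("\n")
                bundle.summaries[f"binding_event_{safe}"] = evt_path
            return extra

    if config.chi2:
        @stage("chi2")
        def _chi2_stage():
            traj = load(config.chi2["trajectory"])
            resid = int(config.chi2.get("resid", 309))
            series = chi2_series(traj, resid)
            labelled, occupancy = classify_chi2_series(series)
            csv_path = out / f"chi2_{resid}.csv"
            labelled.write_csv(csv_path)
            bundle.tables[f"chi2_{resid}"] = csv_path
            occ_path = out / f"chi2_occupancy_{resid}.json"
            occupancy.write_json(occ_path)
            bundle.summaries[f"chi2_occupancy_{resid}"] = occ_path
            return {"resid": resid, **{k: round(v, 3)
                                       for k, v in occupancy.percent.items()}}

    if config.carboxyl_pairs:
        @stage("carboxyl_pairs")
        def _pairs_stage():
            traj = load(config.carboxyl_pairs["trajectory"])
            pairs = config.carboxyl_pairs.get("pairs", sorted(BUILTIN_PAIRS))
            for name in pairs:
                series = carboxyl_pair_series(traj, name)
                path = out / f"carboxyl_pair_{name}.csv"
                series.write_csv(path)
                bundle.tables[f"carboxyl_pair_{name}"] = path
            return {"pairs": list(pairs)}

    if config.rmsd:
        @stage("rmsd")
        def _rmsd_stage():
            traj = load(config.rmsd["trajectory"])
            align = config.rmsd.get("align", "domain TM and backbone")
            domains = config.rmsd.get("domains", ["N", "P", "A", "TM"])
            reference = traj.frame(0)
            for dom in domains:
                series = rmsd_series(
                    traj, f"domain {dom} and backbone", align, reference,
                    domain=dom,
                )
                path = out / f"rmsd_{dom}.csv"
                series.write_csv(path)
                bundle.tables[f"rmsd_{dom}"] = path
            return {"domains": list(domains), "align": align}

    if config.axial_rotation:
        @stage("axial_rotation")
        def _axial_stage():
            traj = load(config.axial_rotation["trajectory"])
            sel = config.axial_rotation.get("selection", "domain A and backbone")
            from .geomcore import _resolve

            idx = _resolve(traj, sel)
            angle = axial_rotation_angle(traj.coords[0][idx], traj.coords[-1][idx])
            path = out / "axial_rotation.json"
            with open(path, "w") as fh:
                json.dump({"selection": sel, "angle_deg": float(angle)}, fh, indent=1)
                fh.write("\n")
            bundle.summaries["axial_rotation"] = path
            return {"angle_deg": round(float(angle), 3)}

    if config.headpiece:
        @stage("headpiece")
        def _headpiece_stage():
            traj = load(config.headpiece["trajectory"])
            bin_width = float(config.headpiece.get("bin_width", 0.05))
            pairs = config.headpiece.get("pairs", ["N-A", "N-P", "A-P"])
            crystal_values = _crystal_anchor_distances(config, pairs)
            chosen_orders = {}
            for pair in pairs:
                series = interdomain_series(traj, pair)
                dist = estimate_density(series.values, bin_width=bin_width, pair=pair)
                fit1 = fit_mixture(dist, 1)
                fit2 = fit_mixture(dist, 2)
                chosen = select_model(fit1, fit2)
                rows = (compare_to_crystal(chosen, crystal_values[pair])
                        if crystal_values.get(pair) else None)
                path = out / f"headpiece_{pair}.csv"
                write_fit_report(path, dist, [fit1, fit2], chosen, rows)
                bundle.tables[f"headpiece_{pair}"] = path
                bundle.summaries[f"headpiece_{pair}"] = path.with_suffix(".json")
                chosen_orders[pair] = chosen.order
            return {"chosen_orders": chosen_orders}

    bundle.write_log(config)
    return bundle


def _crystal_anchor_distances(config: RunConfig, pairs) -> dict[str, dict[str, float]]:
    """Calpha-Calpha registry distances measured on each crystal reference."""
    from .headpiece import PAIR_REGISTRY
    from .structio import select_atoms

    out: dict[str, dict[str, float]] = {p: {} for p in pairs}
    for name, path in config.crystal_refs.items():
        topology, frame = read_structure(path)
        for pair in pairs:
            resid_a, resid_b = PAIR_REGISTRY[pair]
            ia = select_atoms(topology, f"resid {resid_a} and name CA")
            ib = select_atoms(topology, f"resid {resid_b} and name CA")
            if len(ia) == 1 and len(ib) == 1:
                out[pair][name] = float(
                    np.linalg.norm(frame.coords[ia[0]] - frame.coords[ib[0]])
                )
    return out


# ---------------------------------------------------------------------------
# Run comparison
# ---------------------------------------------------------------------------

def compare_runs(dir_a, dir_b) -> dict:
    """Difference report between two report bundles (by output directory).

    Shared CSV tables are compared cell-wise on their numeric columns;
    mixture-fit JSON summaries are compared on chosen order and component
    means. Tables present on only one side are flagged, not fatal.
    """
    import pandas as pd

    dir_a, dir_b = Path(dir_a), Path(dir_b)
    tables_a = {p.name: p for p in dir_a.glob("*.csv")}
    tables_b = {p.name: p for p in dir_b.glob("*.csv")}
    shared = sorted(set(tables_a) & set(tables_b))
    report: dict = {
        "shared_tables": shared,
        "only_in_a": sorted(set(tables_a) - set(tables_b)),
        "only_in_b": sorted(set(tables_b) - set(tables_a)),
        "tables": {},
        "fits": {},
        "warnings": [],
    }
    if not shared:
        report["warnings"].append("no shared tables between the two bundles")

    for name in shared:
        a = pd.read_csv(tables_a[name])
        b = pd.read_csv(tables_b[name])
        entry: dict = {}
        if a.shape != b.shape or list(a.columns) != list(b.columns):
            entry["comparable"] = False
        else:
            entry["comparable"] = True
            num = a.select_dtypes("number")
            diffs = (b[num.columns] - num).abs()
            entry["max_abs_diff"] = {
                col: float(diffs[col].max()) for col in num.columns
            }
            entry["identical"] = bool((diffs.to_numpy() == 0).all())
        report["tables"][name] = entry

    fits_a = {p.name: p for p in dir_a.glob("headpiece_*.json")}
    fits_b = {p.name: p for p in dir_b.glob("headpiece_*.json")}
    for name in sorted(set(fits_a) & set(fits_b)):
        with open(fits_a[name]) as fh:
            ja = json.load(fh)
        with open(fits_b[name]) as fh:
            jb = json.load(fh)

        def chosen_means(j):
            order = j.get("chosen_order")
            for f in j.get("fits", []):
                if f["order"] == order:
                    return [c["mean_nm"] for c in f["components"]]
            return []

        report["fits"][name] = {
            "order_a": ja.get("chosen_order"),
            "order_b": jb.get("chosen_order"),
            "order_differs": ja.get("chosen_order") != jb.get("chosen_order"),
            "means_a_nm": chosen_means(ja),
            "means_b_nm": chosen_means(jb),
        }
    return report


# ---------------------------------------------------------------------------
# Small report utilities
# ---------------------------------------------------------------------------

def round_sig(value: float, sig_figs: int = 2) -> float:
    """Round to a number of significant figures."""
    if value == 0:
        return 0.0
    from math import floor, log10

    return round(value, -int(floor(log10(abs(value)))) + (sig_figs - 1))


def radius_ratio(radius_a_nm: float, radius_b_nm: float, sig_figs: int = 2) -> float:
    """Ratio of two ionic radii, rounded to `sig_figs` significant figures."""
    if radius_b_nm <= 0:
        raise ParameterError("denominator radius must be positive")
    return round_sig(radius_a_nm / radius_b_nm, sig_figs)
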
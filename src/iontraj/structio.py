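"""Structure and trajectory I/O, atom selection, and domain bookkeeping.

All coordinates are stored in nanometres and all times in microseconds.
PDB files (Angstrom) are converted at the read/write boundary. Multi-model
PDB is the canonical trajectory interchange format; model 1 defines the
topology and atom ordering.

Residue numbers are taken verbatim from the file (author numbering); no
renumbering is ever performed, so selections written against the source
numbering resolve directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import (
    AlignmentError,
    EmptyInputError,
    FormatError,
    SelectionError,
    ValidationError,
)

ANGSTROM_PER_NM = 10.0

#: resnames recognised as water (force-field and crystallographic dialects)
WATER_RESNAMES = frozenset({"HOH", "TIP3", "WAT", "SOL", "TIP", "SPC"})

#: resname -> canonical monatomic ion species label
ION_RESNAMES = {"MG": "MG", "K": "K", "POT": "K", "CA": "CA", "CAL": "CA"}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

_SELECTION_KEYWORDS = frozenset(
    {
        "and", "or", "not",
        "name", "resname", "resid", "element", "chain", "domain",
        "backbone", "sidechain", "ion", "water", "protein", "all",
    }
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology, in PDB conventions."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str = "A"
    altloc: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValidationError("atom name must be nonempty")
        if self.serial <= 0:
            raise ValidationError(f"atom serial must be positive, got {self.serial}")


@dataclass(frozen=True)
class DomainMap:
    """Closed residue-range intervals for the N, P, A and TM domains.

    Ranges are inclusive ``(start, stop)`` pairs in author numbering.
    Within a domain ranges must not overlap and the four domains must be
    pairwise disjoint.
    """

    domains: dict[str, tuple[tuple[int, int], ...]]

    REQUIRED = ("N", "P", "A", "TM")

    def __post_init__(self):
        for required in self.REQUIRED:
            if required not in self.domains:
                raise ValidationError(f"domain map is missing domain {required!r}")
        seen: dict[int, str] = {}
        for dom, ranges in self.domains.items():
            for start, stop in ranges:
                if start > stop:
                    raise ValidationError(
                        f"domain {dom}: range start {start} exceeds end {stop}"
                    )
                for resid in range(start, stop + 1):
                    if resid in seen:
                        raise ValidationError(
                            f"residue {resid} assigned to both {seen[resid]} and {dom}"
                        )
                    seen[resid] = dom

    def domain_of(self, resid: int) -> str | None:
        for dom, ranges in self.domains.items():
            for start, stop in ranges:
                if start <= resid <= stop:
                    return dom
        return None

    def resids(self, domain: str) -> set[int]:
        if domain not in self.domains:
            raise ValidationError(f"unknown domain {domain!r}")
        out: set[int] = set()
        for start, stop in self.domains[domain]:
            out.update(range(start, stop + 1))
        return out


@dataclass
class Topology:
    """Ordered atom records plus derived ion/water indices and a domain map."""

    atoms: list[AtomRecord]
    domain_map: DomainMap | None = None
    ion_atoms: dict[int, str] = field(default_factory=dict)
    water_oxygen_atoms: list[int] = field(default_factory=list)

    def __post_init__(self):
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValidationError("atom serials are not unique within the topology")
        n = len(self.atoms)
        for idx in self.ion_atoms:
            if not 0 <= idx < n:
                raise ValidationError(f"ion atom index {idx} out of range")
        for idx in self.water_oxygen_atoms:
            if not 0 <= idx < n:
                raise ValidationError(f"water oxygen index {idx} out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @classmethod
    def from_atoms(cls, atoms: list[AtomRecord], domain_map: DomainMap | None = None) -> "Topology":
        """Build a topology, detecting ions and water oxygens heuristically."""
        ion_atoms: dict[int, str] = {}
        water_ox: list[int] = []
        for i, atom in enumerate(atoms):
            resname = atom.resname.upper()
            if resname in ION_RESNAMES:
                ion_atoms[i] = ION_RESNAMES[resname]
            elif resname in WATER_RESNAMES and atom.element.upper() == "O":
                water_ox.append(i)
        return cls(atoms=atoms, domain_map=domain_map, ion_atoms=ion_atoms,
                   water_oxygen_atoms=water_ox)

    def with_domain_map(self, domain_map: DomainMap) -> "Topology":
        return Topology(atoms=self.atoms, domain_map=domain_map,
                        ion_atoms=dict(self.ion_atoms),
                        water_oxygen_atoms=list(self.water_oxygen_atoms))

    def oxygen_indices(self) -> np.ndarray:
        """Indices of every oxygen atom (protein and water alike)."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.element.upper() == "O"],
            dtype=int,
        )


@dataclass
class Frame:
    """A single coordinate set: time in us, coords in nm, one row per atom."""

    time: float
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("frame coordinates must be an (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("frame contains non-finite coordinates")


@dataclass
class Trajectory:
    """Topology plus an ordered stack of frames (times us, coords nm)."""

    topology: Topology
    times: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("trajectory coordinates must be (F, N, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ValidationError("times and coordinate frames differ in length")
        if self.coords.shape[0] < 1:
            raise ValidationError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValidationError(
                f"coordinate columns ({self.coords.shape[1]}) do not match "
                f"topology atom count ({self.topology.n_atoms})"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), coords=self.coords[i])

    @classmethod
    def from_frames(cls, topology: Topology, frames: list[Frame]) -> "Trajectory":
        if not frames:
            raise ValidationError("trajectory must contain at least one frame")
        return cls(
            topology=topology,
            times=np.array([f.time for f in frames]),
            coords=np.stack([f.coords for f in frames]),
        )


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, line_number: int) -> tuple[AtomRecord, np.ndarray]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparseable ATOM/HETATM record: {exc}", line_number) from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name, resname)
    return (
        AtomRecord(serial=serial, name=name, element=element, resname=resname,
                   resid=resid, chain=chain, altloc=altloc),
        xyz / ANGSTROM_PER_NM,
    )


def _guess_element(name: str, resname: str) -> str:
    resname = resname.upper()
    if resname in ION_RESNAMES:
        return ION_RESNAMES[resname]
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _apply_altloc_policy(records, policy: str):
    """records: list of (AtomRecord, xyz). Returns a filtered list."""
    if policy == "all":
        return records
    if policy == "first":
        seen: set[tuple] = set()
        kept = []
        for rec, xyz in records:
            if rec.altloc:
                key = (rec.chain, rec.resid, rec.resname, rec.name)
                if key in seen:
                    continue
                seen.add(key)
            kept.append((rec, xyz))
        return kept
    # explicit altloc letter: keep blank altloc plus the requested one
    kept = [(r, x) for r, x in records if r.altloc in ("", policy)]
    return kept


def read_structure(path, altloc_policy: str = "first") -> tuple[Topology, Frame]:
    """Read a single-model PDB file (first model of a multi-model file).

    Coordinates are converted from Angstrom to nm. Ions and water oxygens
    are detected by resname/element heuristics and indexed on the topology.
    """
    records: list[tuple[AtomRecord, np.ndarray]] = []
    with open(path) as handle:
        for line_number, line in enumerate(handle, start=1):
            tag = line[:6].strip()
            if tag in ("ATOM", "HETATM"):
                records.append(_parse_atom_line(line, line_number))
            elif tag == "ENDMDL":
                break
    records = _apply_altloc_policy(records, altloc_policy)
    if not records:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
    atoms = [rec for rec, _ in records]
    coords = np.stack([xyz for _, xyz in records])
    return Topology.from_atoms(atoms), Frame(time=0.0, coords=coords)


def read_trajectory(path, frame_dt: float = 0.01, altloc_policy: str = "first") -> Trajectory:
    """Read a multi-model PDB as a trajectory; frame k gets time k*frame_dt (us).

    The topology (atom records, ion/water indexing) is taken from model 1.
    A file without MODEL records is treated as a single-frame trajectory.
    """
    models: list[list[tuple[AtomRecord, np.ndarray]]] = []
    current: list[tuple[AtomRecord, np.ndarray]] = []
    in_model = False
    with open(path) as handle:
        for line_number, line in enumerate(handle, start=1):
            tag = line[:6].strip()
            if tag == "MODEL":
                in_model = True
                current = []
            elif tag == "ENDMDL":
                models.append(current)
                in_model = False
                current = []
            elif tag in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line, line_number))
    if current and not in_model:
        pass
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
    models = [_apply_altloc_policy(m, altloc_policy) for m in models]

    n_ref = len(models[0])
    for k, model in enumerate(models, start=1):
        if len(model) != n_ref:
            raise AlignmentError(
                f"model {k} has {len(model)} atoms but model 1 has {n_ref}"
            )
    atoms = [rec for rec, _ in models[0]]
    coords = np.stack(
        [np.stack([xyz for _, xyz in model]) for model in models]
    )
    times = np.arange(len(models)) * float(frame_dt)
    return Trajectory(topology=Topology.from_atoms(atoms), times=times, coords=coords)


def _format_atom_line(atom: AtomRecord, xyz_nm: np.ndarray) -> str:
    x, y, z = (np.asarray(xyz_nm) * ANGSTROM_PER_NM).tolist()
    record = "HETATM" if atom.resname.upper() in ION_RESNAMES or atom.resname.upper() in WATER_RESNAMES else "ATOM  "
    name = atom.name
    # PDB alignment: 1-3 char names start in column 14 unless 4 chars
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"{record}{atom.serial:>5d} {name_field}{'':1s}{atom.resname:<4s}"
        f"{atom.chain:1s}{atom.resid:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2s}\n"
    )


def write_structure(topology: Topology, frame: Frame, path) -> None:
    """Write a single-model PDB (nm converted back to Angstrom)."""
    with open(path, "w") as handle:
        for atom, xyz in zip(topology.atoms, frame.coords):
            handle.write(_format_atom_line(atom, xyz))
        handle.write("END\n")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a multi-model PDB; model k+1 holds frame k."""
    with open(path, "w") as handle:
        for k in range(traj.n_frames):
            handle.write(f"MODEL     {k + 1:>4d}\n")
            for atom, xyz in zip(traj.topology.atoms, traj.coords[k]):
                handle.write(_format_atom_line(atom, xyz))
            handle.write("ENDMDL\n")
        handle.write("END\n")


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------
#
#   expr      := term ("or" term)*
#   term      := factor ("and" factor)*
#   factor    := "not" factor | "(" expr ")" | primitive
#   primitive := "name" VALUE+ | "resname" VALUE+ | "element" VALUE+
#              | "chain" VALUE+ | "resid" (INT | INT ":" INT)+
#              | "domain" VALUE+ | "backbone" | "sidechain"
#              | "ion" | "water" | "protein" | "all"
#
# Value lists are OR-combined. resid accepts closed ranges written a:b.

_TOKEN_RE = re.compile(r"\S+")


class _Token:
    __slots__ = ("text", "pos")

    def __init__(self, text: str, pos: int):
        self.text = text
        self.pos = pos


def _tokenize(expr: str) -> list[_Token]:
    tokens: list[_Token] = []
    for match in _TOKEN_RE.finditer(expr):
        text = match.group()
        pos = match.start()
        # split parentheses off words
        while text:
            lead = re.match(r"[()]", text)
            if lead:
                tokens.append(_Token(lead.group(), pos))
                text = text[1:]
                pos += 1
                continue
            body = re.match(r"[^()]+", text)
            tokens.append(_Token(body.group(), pos))
            pos += len(body.group())
            text = text[len(body.group()):]
    return tokens


class _SelectionParser:
    def __init__(self, expr: str, topology: Topology):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0
        self.top = topology

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise SelectionError(
                f"unexpected end of selection {self.expr!r}", len(self.expr)
            )
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.parse_expr()
        if self.peek() is not None:
            tok = self.peek()
            raise SelectionError(f"unexpected token {tok.text!r}", tok.pos)
        return mask

    def parse_expr(self) -> np.ndarray:
        mask = self.parse_term()
        while (tok := self.peek()) is not None and tok.text == "or":
            self.next()
            mask = mask | self.parse_term()
        return mask

    def parse_term(self) -> np.ndarray:
        mask = self.parse_factor()
        while (tok := self.peek()) is not None and tok.text == "and":
            self.next()
            mask = mask & self.parse_factor()
        return mask

    def parse_factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError(
                f"unexpected end of selection {self.expr!r}", len(self.expr)
            )
        if tok.text == "not":
            self.next()
            return ~self.parse_factor()
        if tok.text == "(":
            self.next()
            mask = self.parse_expr()
            closing = self.peek()
            if closing is None or closing.text != ")":
                raise SelectionError("unbalanced parenthesis", tok.pos)
            self.next()
            return mask
        return self.parse_primitive()

    def _collect_values(self) -> list[_Token]:
        values = []
        while (tok := self.peek()) is not None and tok.text not in _SELECTION_KEYWORDS \
                and tok.text not in ("(", ")"):
            values.append(self.next())
        return values

    def parse_primitive(self) -> np.ndarray:
        tok = self.next()
        atoms = self.top.atoms
        n = len(atoms)
        word = tok.text

        if word == "all":
            return np.ones(n, dtype=bool)
        if word == "backbone":
            return np.array(
                [a.name in BACKBONE_NAMES and self._is_protein(i)
                 for i, a in enumerate(atoms)]
            )
        if word == "sidechain":
            return np.array(
                [a.name not in BACKBONE_NAMES and self._is_protein(i)
                 for i, a in enumerate(atoms)]
            )
        if word == "ion":
            mask = np.zeros(n, dtype=bool)
            mask[list(self.top.ion_atoms)] = True
            return mask
        if word == "water":
            return np.array(
                [a.resname.upper() in WATER_RESNAMES for a in atoms]
            )
        if word == "protein":
            return np.array([self._is_protein(i) for i in range(n)])

        if word in ("name", "resname", "element", "chain", "domain", "resid"):
            values = self._collect_values()
            if not values:
                raise SelectionError(f"{word} requires at least one value", tok.pos)
            if word == "resid":
                wanted: set[int] = set()
                for v in values:
                    if ":" in v.text:
                        try:
                            lo, hi = (int(p) for p in v.text.split(":"))
                        except ValueError:
                            raise SelectionError(
                                f"bad resid range {v.text!r}", v.pos
                            ) from None
                        wanted.update(range(lo, hi + 1))
                    else:
                        try:
                            wanted.add(int(v.text))
                        except ValueError:
                            raise SelectionError(
                                f"bad resid {v.text!r}", v.pos
                            ) from None
                return np.array([a.resid in wanted for a in atoms])
            if word == "domain":
                if self.top.domain_map is None:
                    raise SelectionError(
                        "selection uses 'domain' but no domain map is attached",
                        tok.pos,
                    )
                wanted_resids: set[int] = set()
                for v in values:
                    dom = v.text.upper()
                    if dom not in self.top.domain_map.domains:
                        raise SelectionError(f"unknown domain {v.text!r}", v.pos)
                    wanted_resids |= self.top.domain_map.resids(dom)
                return np.array([a.resid in wanted_resids for a in atoms])
            wanted_text = {v.text.upper() for v in values}
            getter = {
                "name": lambda a: a.name.upper(),
                "resname": lambda a: a.resname.upper(),
                "element": lambda a: a.element.upper(),
                "chain": lambda a: a.chain.upper(),
            }[word]
            return np.array([getter(a) in wanted_text for a in atoms])

        raise SelectionError(f"unknown selection keyword {word!r}", tok.pos)

    def _is_protein(self, i: int) -> bool:
        a = self.top.atoms[i]
        return (
            i not in self.top.ion_atoms
            and a.resname.upper() not in WATER_RESNAMES
        )


def select_atoms(topology: Topology, expr: str) -> list[int]:
    """Resolve a selection expression to an order-preserving atom index list.

    An empty result is allowed; a malformed expression raises
    :class:`~iontraj.errors.SelectionError` with the offending position.
    """
    if not expr or not expr.strip():
        raise SelectionError("empty selection expression", 0)
    mask = _SelectionParser(expr, topology).parse()
    return [int(i) for i in np.flatnonzero(mask)]


# ---------------------------------------------------------------------------
# Domain map loading
# ---------------------------------------------------------------------------

def load_domain_map(path) -> DomainMap:
    """Load a YAML domain-map config.

    Expected layout::

        domains:
          N: [[360, 600]]
          P: [[330, 359], [601, 739]]
          A: [[1, 43], [124, 235]]
          TM: [[44, 123], [236, 329], [740, 994]]
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or "domains" not in raw:
        raise ValidationError(f"{path}: expected a top-level 'domains' mapping")
    return domain_map_from_dict(raw["domains"])


def domain_map_from_dict(domains: dict) -> DomainMap:
    parsed: dict[str, tuple[tuple[int, int], ...]] = {}
    for dom, ranges in domains.items():
        if not isinstance(ranges, (list, tuple)):
            raise ValidationError(f"domain {dom}: ranges must be a list of pairs")
        clean: list[tuple[int, int]] = []
        for rng in ranges:
            if not (isinstance(rng, (list, tuple)) and len(rng) == 2):
                raise ValidationError(f"domain {dom}: range {rng!r} is not a pair")
            clean.append((int(rng[0]), int(rng[1])))
        parsed[str(dom)] = tuple(clean)
    return DomainMap(domains=parsed)


def default_domain_map() -> DomainMap:
    """The repo's documented default N/P/A/TM partition (a repo choice)."""
    from importlib.resources import files

    return load_domain_map(files("iontraj.data") / "default_domain_map.yaml")
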
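"""Structure/trajectory containers and readers.

Internal units are nm for lengths and ps for time, matching the GRO/XTC
conventions. PDB coordinates (Å) are converted on read. Only orthorhombic
boxes are supported; triclinic input is rejected.

Atoms carry a *role* flag (``protein`` / ``water`` / ``ion``) assigned from
residue-name tables that can be extended through a YAML config, so that
arbitrary salt species (NH4+, Sr2+, ...) can be named.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "ParseError",
    "SelectionError",
    "DEFAULT_WATER_RESNAMES",
    "DEFAULT_ION_CHARGES",
    "load_role_table",
    "assign_role",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select",
]

PROTEIN = "protein"
WATER = "water"
ION = "ion"

#: residue names recognised as water
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "SOL", "TIP3", "TIP3P", "WAT", "SPC", "T3P"})

#: residue name -> signed integer charge for monatomic/simple ions
DEFAULT_ION_CHARGES: dict[str, int] = {
    "NA": 1, "SOD": 1, "NA+": 1,
    "CL": -1, "CLA": -1, "CL-": -1,
    "MG": 2, "MG2": 2,
    "K": 1, "POT": 1,
    "LI": 1, "LIT": 1,
    "CA": 2, "CAL": 2,
    "SR": 2, "SR2": 2,
    "NH4": 1,
}

_ION_ELEMENTS = {
    "NA": "Na", "SOD": "Na", "CL": "Cl", "CLA": "Cl", "MG": "Mg", "MG2": "Mg",
    "K": "K", "POT": "K", "LI": "Li", "LIT": "Li", "CA": "Ca", "CAL": "Ca",
    "SR": "Sr", "SR2": "Sr", "NH4": "N",
}


class ParseError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


class SelectionError(ValueError):
    """Raised for syntax errors in the selection mini-language."""


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    element: str
    resname: str
    resnum: int
    chain: str
    role: str
    charge: int = 0  # signed valence, nonzero only for role == "ion"


@dataclass
class Topology:
    """Ordered atom records with role flags.

    Serial indices are 0-based and contiguous; residue numbers are kept as
    authored in the source file (usually 1-based).
    """

    atoms: list[Atom]

    def __post_init__(self) -> None:
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise ValueError(
                    f"atom indices must be contiguous from 0; atom {i} has index {a.index}"
                )
            if a.role not in (PROTEIN, WATER, ION):
                raise ValueError(f"unknown role {a.role!r} for atom {i}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    # vectorised field views, built lazily and cached
    def _arr(self, key: str) -> np.ndarray:
        cache = self.__dict__.setdefault("_field_cache", {})
        if key not in cache:
            cache[key] = np.array([getattr(a, key) for a in self.atoms])
        return cache[key]

    @property
    def names(self) -> np.ndarray:
        return self._arr("name")

    @property
    def resnames(self) -> np.ndarray:
        return self._arr("resname")

    @property
    def resnums(self) -> np.ndarray:
        return self._arr("resnum")

    @property
    def chains(self) -> np.ndarray:
        return self._arr("chain")

    @property
    def roles(self) -> np.ndarray:
        return self._arr("role")

    @property
    def elements(self) -> np.ndarray:
        return self._arr("element")

    def residues(self) -> Iterable[tuple[tuple[str, int, str], np.ndarray]]:
        """Yield ((resname, resnum, chain), atom indices) in file order."""
        keys: list[tuple[str, int, str]] = []
        groups: dict[tuple[str, int, str], list[int]] = {}
        for a in self.atoms:
            k = (a.resname, a.resnum, a.chain)
            if k not in groups:
                groups[k] = []
                keys.append(k)
            groups[k].append(a.index)
        for k in keys:
            yield k, np.asarray(groups[k], dtype=np.intp)

    def water_oxygen_indices(self) -> np.ndarray:
        """One oxygen atom index per water residue (the solvent-count proxy)."""
        out = []
        for (resname, resnum, chain), idx in self.residues():
            if self.atoms[idx[0]].role != WATER:
                continue
            ox = [i for i in idx if self.atoms[i].element == "O"]
            if not ox:
                raise ValueError(
                    f"water residue {resname} {resnum} (chain {chain!r}) has no oxygen atom"
                )
            out.append(ox[0])
        return np.asarray(out, dtype=np.intp)


@dataclass
class Frame:
    """One set of coordinates (nm) with an optional orthorhombic box and time."""

    coordinates: np.ndarray  # (n_atoms, 3) nm
    box: np.ndarray | None = None  # (3,) nm, orthorhombic
    time: float | None = None  # ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box lengths must be strictly positive")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]
    superposed: bool = False  # set by essential_dynamics.superpose

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {f.coordinates.shape[0]} atoms, topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_array(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Stack coordinates into (n_frames, n_sel, 3)."""
        if indices is None:
            return np.stack([f.coordinates for f in self.frames])
        return np.stack([f.coordinates[indices] for f in self.frames])


@dataclass(frozen=True)
class Selection:
    label: str
    indices: np.ndarray  # ordered, unique atom indices

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.size != np.unique(idx).size:
            raise ValueError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


# ---------------------------------------------------------------------------
# role assignment


def load_role_table(path: str | Path) -> tuple[frozenset[str], dict[str, int]]:
    """Merge a YAML role table into the defaults.

    Schema::

        water: [HOH, SOL]
        ions: {NH4: 1, SR: 2, CL: -1}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    water = set(DEFAULT_WATER_RESNAMES) | {str(w).upper() for w in cfg.get("water", [])}
    ions = dict(DEFAULT_ION_CHARGES)
    for k, v in (cfg.get("ions") or {}).items():
        ions[str(k).upper()] = int(v)
    return frozenset(water), ions


def assign_role(
    resname: str,
    water_resnames: frozenset[str] = DEFAULT_WATER_RESNAMES,
    ion_charges: Mapping[str, int] = DEFAULT_ION_CHARGES,
) -> tuple[str, int]:
    rn = resname.upper()
    if rn in water_resnames:
        return WATER, 0
    if rn in ion_charges:
        return ION, ion_charges[rn]
    return PROTEIN, 0


_STANDARD_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)


def _guess_element(name: str, resname: str, role: str) -> str:
    if role == ION:
        return _ION_ELEMENTS.get(resname.upper(), name[:1].upper())
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


# ---------------------------------------------------------------------------
# file I/O (MDAnalysis behind the scenes)


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _box_from_dimensions(dimensions) -> np.ndarray | None:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=np.float64)
    if dims.size < 6 or np.all(dims[:3] == 0):
        return None
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise ParseError(
            f"triclinic box (angles {dims[3:6]}) not supported; orthorhombic only"
        )
    return dims[:3] / 10.0  # Å -> nm


def read_structure(
    path: str | Path,
    format: str | None = None,
    water_resnames: frozenset[str] = DEFAULT_WATER_RESNAMES,
    ion_charges: Mapping[str, int] = DEFAULT_ION_CHARGES,
) -> tuple[Topology, list[Frame]]:
    """Read a PDB (possibly multi-MODEL) or GRO file.

    Returns the topology and one Frame per model, with coordinates in nm.
    Roles are assigned from the residue-name tables; unrecognised non-standard
    residue names fall back to ``protein`` with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    mda = _import_mda()
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in ("PDB", "GRO"):
        raise ValueError(f"unsupported structure format {fmt!r} (PDB or GRO)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt, to_guess=())
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise ParseError(f"{path}: {exc}") from exc

    atoms = []
    warned: set[str] = set()
    for i, a in enumerate(u.atoms):
        resname = str(a.resname).strip()
        role, charge = assign_role(resname, water_resnames, ion_charges)
        if (
            role == PROTEIN
            and resname.upper() not in _STANDARD_RESNAMES
            and resname.upper() not in warned
        ):
            warned.add(resname.upper())
            warnings.warn(
                f"unknown residue name {resname!r}: assigning role=protein",
                stacklevel=2,
            )
        try:
            chain = str(a.chainID)
        except AttributeError:  # GRO has no chain records
            chain = ""
        name = str(a.name).strip()
        atoms.append(
            Atom(
                index=i,
                name=name,
                element=_guess_element(name, resname, role),
                resname=resname,
                resnum=int(a.resid),
                chain=chain,
                role=role,
                charge=charge,
            )
        )
    top = Topology(atoms)

    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            frames.append(
                Frame(
                    coordinates=ts.positions.astype(np.float64) / 10.0,
                    box=_box_from_dimensions(ts.dimensions),
                    time=float(ts.time) if ts.time is not None else None,
                )
            )
    if not frames:
        raise ParseError(f"{path}: no coordinate models found")
    return top, frames


def read_trajectory(
    path: str | Path,
    topology: Topology,
    format: str | None = None,
) -> Trajectory:
    """Read an XTC or multi-model PDB trajectory onto an existing topology."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "PDB":
        top2, frames = read_structure(path, format="PDB")
        if top2.n_atoms != topology.n_atoms:
            raise ValueError(
                f"atom count mismatch: file has {top2.n_atoms}, topology has {topology.n_atoms}"
            )
        return Trajectory(topology, frames)
    if fmt != "XTC":
        raise ValueError(f"unsupported trajectory format {fmt!r} (XTC or PDB)")
    from MDAnalysis.coordinates.XTC import XTCReader

    try:
        reader = XTCReader(str(path))
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: {exc}") from exc
    with reader, warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if reader.n_atoms != topology.n_atoms:
            raise ValueError(
                f"atom count mismatch: file has {reader.n_atoms}, "
                f"topology has {topology.n_atoms}"
            )
        frames = []
        for ts in reader:
            frames.append(
                Frame(
                    coordinates=ts.positions.astype(np.float64) / 10.0,
                    box=_box_from_dimensions(ts.dimensions),
                    time=float(ts.time),
                )
            )
    if not frames:
        raise ParseError(f"{path}: no frames read")
    return Trajectory(topology, frames)


def _as_universe(traj: Trajectory):
    """Materialise an in-memory MDAnalysis Universe (Å) from a Trajectory."""
    mda = _import_mda()
    top = traj.topology
    n = top.n_atoms
    res_keys = list(dict.fromkeys((a.resname, a.resnum, a.chain) for a in top.atoms))
    res_index = {k: i for i, k in enumerate(res_keys)}
    atom_resindex = np.array(
        [res_index[(a.resname, a.resnum, a.chain)] for a in top.atoms]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=len(res_keys),
            atom_resindex=atom_resindex,
            residue_segindex=np.zeros(len(res_keys), dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in top.atoms])
        u.add_TopologyAttr("elements", [a.element for a in top.atoms])
        u.add_TopologyAttr("resnames", [k[0] for k in res_keys])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
    coords = traj.coordinate_array() * 10.0  # nm -> Å
    dims = None
    if traj.frames[0].box is not None:
        dims = np.array(
            [np.concatenate([f.box * 10.0, [90.0, 90.0, 90.0]]) for f in traj.frames]
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.load_new(coords, order="fac", dimensions=dims)
    return u


def write_structure(path: str | Path, topology: Topology, frames: Frame | Sequence[Frame]) -> None:
    """Write a GRO (single frame) or PDB (one MODEL per frame) file."""
    if isinstance(frames, Frame):
        frames = [frames]
    traj = Trajectory(topology, list(frames))
    u = _as_universe(traj)
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix.lower() == ".gro":
            u.atoms.write(str(path))
        else:
            import MDAnalysis as mda

            with mda.Writer(str(path), multiframe=len(traj.frames) > 1) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write frames to XTC (coordinates nm, times ps)."""
    from MDAnalysis.coordinates.XTC import XTCWriter

    u = _as_universe(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with XTCWriter(str(Path(path)), n_atoms=traj.topology.n_atoms) as w:
            for i, ts in enumerate(u.trajectory):
                t = traj.frames[i].time
                ts.time = float(t) if t is not None else float(i)
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# selection mini-language
#
# expr     := term ("or" term)*
# term     := factor ("and" factor)*
# factor   := "not" factor | "(" expr ")" | predicate
# predicate:= FIELD value+            (multiple values mean any-of)
# FIELD    := name | resname | resnum | resid | role | element | chain
# resnum values may be single integers or inclusive ranges "a:b"

_FIELDS = {"name", "resname", "resnum", "resid", "role", "element", "chain"}
_KEYWORDS = {"and", "or", "not", "(", ")"} | _FIELDS


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(expr) and not expr[j].isspace() and expr[j] not in "()":
            j += 1
        tokens.append((expr[i:j], i))
        i = j
    return tokens


class _Parser:
    def __init__(self, expr: str, top: Topology):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0
        self.top = top

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expr))

    def _next(self):
        tok = self._peek()
        self.pos += 1
        return tok

    def _err(self, msg: str, pos: int):
        raise SelectionError(f"{msg} at position {pos} in {self.expr!r}")

    def parse(self) -> np.ndarray:
        if not self.tokens:
            self._err("empty expression", 0)
        mask = self._expr()
        tok, pos = self._peek()
        if tok is not None:
            self._err(f"unexpected token {tok!r}", pos)
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek()[0] == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while self._peek()[0] == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok, pos = self._peek()
        if tok == "not":
            self._next()
            return ~self._factor()
        if tok == "(":
            self._next()
            mask = self._expr()
            tok2, pos2 = self._next()
            if tok2 != ")":
                self._err("expected ')'", pos2)
            return mask
        if tok in _FIELDS:
            return self._predicate()
        self._err(f"expected a field, 'not' or '(' but got {tok!r}", pos)

    def _predicate(self) -> np.ndarray:
        fld, pos = self._next()
        values = []
        while True:
            tok, _ = self._peek()
            if tok is None or tok in _KEYWORDS:
                break
            values.append(self._next()[0])
        if not values:
            self._err(f"field {fld!r} needs at least one value", pos)
        top = self.top
        if fld in ("resnum", "resid"):
            mask = np.zeros(top.n_atoms, dtype=bool)
            for v in values:
                if ":" in v:
                    lo_s, _, hi_s = v.partition(":")
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        self._err(f"bad residue range {v!r}", pos)
                    mask |= (top.resnums >= lo) & (top.resnums <= hi)
                else:
                    try:
                        mask |= top.resnums == int(v)
                    except ValueError:
                        self._err(f"bad residue number {v!r}", pos)
            return mask
        arr = {
            "name": top.names,
            "resname": top.resnames,
            "role": top.roles,
            "element": top.elements,
            "chain": top.chains,
        }[fld]
        if fld == "role":
            vals = [v.lower() for v in values]
        else:
            vals = [v.upper() for v in values]
            arr = np.char.upper(arr.astype(str))
        return np.isin(arr, vals)


def select(topology: Topology, expression: str) -> Selection:
    """Evaluate a selection expression; an empty result is not an error."""
    mask = _Parser(expression, topology).parse()
    return Selection(label=expression, indices=np.flatnonzero(mask))
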
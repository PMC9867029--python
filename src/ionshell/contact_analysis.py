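"""Residue-pair distances, distance distributions, and salt bridges.

The open-to-closed transition of a lid-gated enzyme is monitored through a
single residue-pair Euclidean distance (C-alpha to C-alpha by default); its
histogram along a trajectory is unimodal for a one-state ensemble and
bimodal when open and closed conformers coexist. Salt bridges between an
acidic (Asp/Glu) and a basic (Arg/Lys) side chain are scored as the mean of
one or two carboxyl-oxygen / amine-nitrogen atom-pair distances, and two
structures (e.g. open vs closed conformers) can be compared contact by
contact to find the ionic tethers broken along the transition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core_io import Frame, Topology, Trajectory

__all__ = [
    "DistanceSeries",
    "DistanceDistribution",
    "SaltBridgePair",
    "residue_pair_distance",
    "distance_distribution",
    "pair_polar_atoms",
    "make_salt_bridge",
    "salt_bridge_distance",
    "enumerate_ionic_contacts",
]

ACID_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASE_NITROGENS = {"ARG": ("NH1", "NH2"), "LYS": ("NZ",)}


@dataclass
class DistanceSeries:
    label: str
    values: np.ndarray  # per-frame distance, nm
    atom_rule: str  # "ca", "min-heavy", or "custom"


@dataclass
class DistanceDistribution:
    bin_edges: np.ndarray  # nm, uniform width
    frequencies: np.ndarray  # normalised to sum to 1
    modes: list[tuple[float, float]]  # (bin centre nm, height)


@dataclass
class SaltBridgePair:
    res_acid: int
    res_base: int
    atom_pairs: list[tuple[int, int]]  # (acid O index, base N index), 1 or 2
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.atom_pairs) <= 2:
            raise ValueError("a salt bridge carries 1 or 2 atom pairs")


def _pair_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    d = a - b
    if box is not None:
        d -= box * np.round(d / box)
    return np.linalg.norm(np.atleast_2d(d), axis=1)


def _residue_atoms(top: Topology, resnum: int) -> np.ndarray:
    idx = np.flatnonzero(top.resnums == resnum)
    if idx.size == 0:
        raise ValueError(f"residue {resnum} not found in topology")
    return idx


def _atom_in_residue(top: Topology, resnum: int, name: str) -> int:
    idx = _residue_atoms(top, resnum)
    hit = idx[top.names[idx] == name]
    if hit.size == 0:
        resname = top.atoms[idx[0]].resname
        raise ValueError(
            f"residue {resname} {resnum} has no atom {name!r} "
            f"(candidates: {sorted(set(top.names[idx]))})"
        )
    return int(hit[0])


def residue_pair_distance(
    traj: Trajectory,
    resA: int,
    resB: int,
    atom_rule: str | list[tuple[int, int]] = "ca",
) -> DistanceSeries:
    """Per-frame Euclidean distance between two residues.

    ``atom_rule``: ``"ca"`` uses the two C-alpha atoms; ``"min-heavy"`` takes,
    per frame, the minimum over all heavy-atom (non-hydrogen) pairs; a list
    of (atom index, atom index) pairs averages those fixed pair distances.
    Minimum-image convention applies whenever the frame carries a box.
    """
    top = traj.topology
    label = f"{resA}-{resB}"
    if isinstance(atom_rule, str) and atom_rule.lower() in ("ca", "ca-ca"):
        i = _atom_in_residue(top, resA, "CA")
        j = _atom_in_residue(top, resB, "CA")
        vals = np.array(
            [
                _pair_dist(f.coordinates[i], f.coordinates[j], f.box)[0]
                for f in traj.frames
            ]
        )
        rule = "ca"
    elif isinstance(atom_rule, str) and atom_rule.lower() == "min-heavy":
        ia = _residue_atoms(top, resA)
        ib = _residue_atoms(top, resB)
        ia = ia[top.elements[ia] != "H"]
        ib = ib[top.elements[ib] != "H"]
        vals = np.empty(traj.n_frames)
        for t, f in enumerate(traj.frames):
            diff = f.coordinates[ia][:, None, :] - f.coordinates[ib][None, :, :]
            if f.box is not None:
                diff -= f.box * np.round(diff / f.box)
            vals[t] = float(np.sqrt(np.sum(diff**2, axis=2)).min())
        rule = "min-heavy"
    elif not isinstance(atom_rule, str):
        pairs = list(atom_rule)
        vals = np.empty(traj.n_frames)
        for t, f in enumerate(traj.frames):
            vals[t] = float(
                np.mean(
                    [_pair_dist(f.coordinates[i], f.coordinates[j], f.box)[0] for i, j in pairs]
                )
            )
        rule = "custom"
    else:
        raise ValueError(f"unknown atom_rule {atom_rule!r}")
    return DistanceSeries(label=label, values=vals, atom_rule=rule)


def distance_distribution(
    series: DistanceSeries,
    bin_width: float = 0.05,
    prominence: float = 0.05,
) -> DistanceDistribution:
    """Uniform-width histogram with mode detection.

    Modes are strict local maxima of the normalised histogram whose
    prominence is at least ``prominence`` times the tallest bin; the
    histogram is zero-padded so boundary maxima count.
    """
    v = np.asarray(series.values, float)
    if v.size == 0:
        raise ValueError("empty distance series")
    if v.size < 100:
        raise ValueError("mode detection needs at least 100 samples")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = float(v.min()), float(v.max())
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)  # guard against round-off dropping the max
    counts, edges = np.histogram(v, bins=edges)
    freq = counts / counts.sum()
    padded = np.concatenate([[0.0], freq, [0.0]])
    peaks, _ = find_peaks(padded, prominence=prominence * freq.max())
    centers = 0.5 * (edges[:-1] + edges[1:])
    modes = [(float(centers[p - 1]), float(freq[p - 1])) for p in peaks]
    return DistanceDistribution(bin_edges=edges, frequencies=freq, modes=modes)


def pair_polar_atoms(
    topology: Topology,
    frame: Frame,
    res_acid: int,
    res_base: int,
) -> list[tuple[int, int]]:
    """Carboxyl-O / amine-N atom pairing for an acid-base residue couple.

    Arg offers two guanidinium nitrogens: the O-N assignment minimising the
    summed pair distance in the given frame is chosen (ties break toward the
    lower-index pairing) and is meant to stay fixed for the rest of a
    trajectory. Lys has a single NZ, to which both carboxyl oxygens pair.
    """
    top = topology
    acid_name = top.atoms[_residue_atoms(top, res_acid)[0]].resname.upper()
    base_name = top.atoms[_residue_atoms(top, res_base)[0]].resname.upper()
    if acid_name not in ACID_OXYGENS:
        raise ValueError(f"residue {res_acid} ({acid_name}) is not Asp/Glu")
    if base_name not in BASE_NITROGENS:
        raise ValueError(f"residue {res_base} ({base_name}) is not Arg/Lys")
    o_idx = [_atom_in_residue(top, res_acid, nm) for nm in ACID_OXYGENS[acid_name]]
    n_idx = [_atom_in_residue(top, res_base, nm) for nm in BASE_NITROGENS[base_name]]

    if len(n_idx) == 1:  # Lys: both oxygens to NZ
        return [(o_idx[0], n_idx[0]), (o_idx[1], n_idx[0])]

    xyz = frame.coordinates
    straight = [(o_idx[0], n_idx[0]), (o_idx[1], n_idx[1])]
    crossed = [(o_idx[0], n_idx[1]), (o_idx[1], n_idx[0])]

    def total(pairs):
        return sum(float(_pair_dist(xyz[i], xyz[j], frame.box)[0]) for i, j in pairs)

    return straight if total(straight) <= total(crossed) else crossed


def make_salt_bridge(
    traj: Trajectory, res_acid: int, res_base: int, label: str = ""
) -> SaltBridgePair:
    """Resolve a salt bridge's atom pairs on the first frame."""
    pairs = pair_polar_atoms(traj.topology, traj.frames[0], res_acid, res_base)
    return SaltBridgePair(
        res_acid=res_acid,
        res_base=res_base,
        atom_pairs=pairs,
        label=label or f"{res_acid}-{res_base}",
    )


def salt_bridge_distance(traj: Trajectory, bridge: SaltBridgePair) -> DistanceSeries:
    """Per-frame mean of the bridge's fixed atom-pair distances."""
    vals = np.empty(traj.n_frames)
    for t, f in enumerate(traj.frames):
        vals[t] = float(
            np.mean(
                [
                    _pair_dist(f.coordinates[i], f.coordinates[j], f.box)[0]
                    for i, j in bridge.atom_pairs
                ]
            )
        )
    return DistanceSeries(label=bridge.label, values=vals, atom_rule="salt-bridge")


def _protein_sequence(top: Topology) -> list[tuple[int, str]]:
    seq = []
    seen = set()
    for a in top.atoms:
        if a.role != "protein":
            continue
        key = (a.resnum, a.chain)
        if key not in seen:
            seen.add(key)
            seq.append((a.resnum, a.resname.upper()))
    return seq


def enumerate_ionic_contacts(
    structA: tuple[Topology, Frame],
    structB: tuple[Topology, Frame],
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Compare the ionic contacts of two conformers of one sequence.

    Every Asp/Glu x Arg/Lys residue pair is scored in both structures by its
    mean polar atom-pair distance (pairing resolved per structure); a contact
    exists where that mean is <= cutoff (nm). Rows cover pairs in contact in
    at least one structure, with status ``both``, ``A-only`` (broken going
    A -> B) or ``B-only`` (formed going A -> B).
    """
    topA, frameA = structA
    topB, frameB = structB
    seqA, seqB = _protein_sequence(topA), _protein_sequence(topB)
    if seqA != seqB:
        raise ValueError("structures have different residue sequences")

    acids = [r for r, nm in seqA if nm in ACID_OXYGENS]
    bases = [r for r, nm in seqA if nm in BASE_NITROGENS]

    def mean_dist(top, frame, ra, rb):
        pairs = pair_polar_atoms(top, frame, ra, rb)
        return float(
            np.mean(
                [_pair_dist(frame.coordinates[i], frame.coordinates[j], frame.box)[0] for i, j in pairs]
            )
        )

    rows = []
    for ra, rb in product(acids, bases):
        dA = mean_dist(topA, frameA, ra, rb)
        dB = mean_dist(topB, frameB, ra, rb)
        inA, inB = dA <= cutoff, dB <= cutoff
        if not (inA or inB):
            continue
        status = "both" if (inA and inB) else ("A-only" if inA else "B-only")
        rows.append(
            {"acid": ra, "base": rb, "dist_A_nm": dA, "dist_B_nm": dB, "status": status}
        )
    return pd.DataFrame(rows, columns=["acid", "base", "dist_A_nm", "dist_B_nm", "status"])
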
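"""Residue contact and hydrogen-bond quantification over coordinate frames.

Criteria:

* a residue-residue *contact* in a frame requires at least two distinct atom
  pairs (one atom from each residue) at a distance strictly below 3.5 A;
* a *hydrogen bond* requires donor-acceptor heavy-atom distance <= 3.0 A and
  a deviation of the D-H...A arrangement from linearity <= 20 degrees
  (i.e. the D-H-A angle >= 160 degrees).

Frames come from multi-model PDB files (one MODEL per frame). Fractions are
reported as percent of frames, with the conventional reporting thresholds of
20% for generic contacts and 2% for hydrogen bonds.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import ContactResult

CONTACT_CUTOFF = 3.5  # A, strict
CONTACT_MIN_PAIRS = 2
HBOND_DIST_CUTOFF = 3.0  # A, inclusive, donor-acceptor heavy atoms
HBOND_ANGLE_CUTOFF = 20.0  # degrees deviation from D-H...A linearity
BACKBONE_ATOMS = {"N", "CA", "C", "O", "H", "HA"}
HBOND_ELEMENTS = {"N", "O", "S"}
_DH_BOND_MAX = 1.25  # A, hydrogen-to-heavy covalent assignment


@dataclass
class FrameSet:
    """Multi-frame coordinate set with per-atom metadata."""

    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    chain: np.ndarray
    resid: np.ndarray
    resname: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = self.coords.shape[1]
        for arr_name in ("chain", "resid", "resname", "atom_name", "element"):
            arr = np.asarray(getattr(self, arr_name))
            if arr.shape != (n,):
                raise ValueError(f"{arr_name} must have one entry per atom")
            setattr(self, arr_name, arr)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> "Frame":
        return Frame(self, i)

    def residue_key(self, atom_index: int) -> str:
        return f"{self.chain[atom_index]}:{self.resid[atom_index]}"

    def atoms_of(self, residue: str) -> np.ndarray:
        chain, resid = residue.split(":")
        mask = (self.chain == chain) & (self.resid == int(resid))
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise KeyError(f"residue {residue!r} not present")
        return idx

    def select(self, selection: str) -> np.ndarray:
        """Atom indices for a selection ``chain``, ``chain:res`` or
        ``chain:start-end``."""
        if ":" not in selection:
            mask = self.chain == selection
        else:
            chain, rng = selection.split(":")
            if "-" in rng:
                a, b = (int(v) for v in rng.split("-"))
            else:
                a = b = int(rng)
            mask = (self.chain == chain) & (self.resid >= a) & (self.resid <= b)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(f"selection {selection!r} matches no atoms")
        return idx


@dataclass
class Frame:
    """A single snapshot of a :class:`FrameSet`."""

    parent: FrameSet
    index: int

    @property
    def coords(self) -> np.ndarray:
        return self.parent.coords[self.index]


def read_frames(path) -> FrameSet:
    """Read a multi-model PDB file (one MODEL per frame) into a FrameSet."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("frames", str(path))
    models = list(structure)
    if not models:
        raise ValueError("no models in PDB file")

    meta = None
    frames = []
    for model in models:
        chain, resid, resname, name, element, xyz = [], [], [], [], [], []
        for ch in model:
            for res in ch:
                for atom in res:
                    chain.append(ch.id)
                    resid.append(res.id[1])
                    resname.append(res.get_resname())
                    name.append(atom.get_name())
                    element.append((atom.element or "").strip().upper() or atom.get_name()[0])
                    xyz.append(atom.get_coord())
        this_meta = (tuple(chain), tuple(resid), tuple(name))
        if meta is None:
            meta = this_meta
            chain0, resid0, resname0, name0, element0 = chain, resid, resname, name, element
        elif this_meta != meta:
            raise ValueError("atom composition differs between models")
        frames.append(np.asarray(xyz, dtype=float))

    return FrameSet(
        coords=np.stack(frames),
        chain=np.array(chain0), resid=np.array(resid0, dtype=int),
        resname=np.array(resname0), atom_name=np.array(name0),
        element=np.array(element0),
    )


def residue_contact(frame: Frame, res_a: str, res_b: str,
                    cutoff: float = CONTACT_CUTOFF,
                    min_pairs: int = CONTACT_MIN_PAIRS) -> bool:
    """True iff >= ``min_pairs`` atom pairs (one atom per residue) lie at a
    distance strictly below ``cutoff``."""
    fs = frame.parent
    ia = fs.atoms_of(res_a)
    ib = fs.atoms_of(res_b)
    xyz = frame.coords
    d = np.linalg.norm(xyz[ia][:, None, :] - xyz[ib][None, :, :], axis=2)
    return int(np.count_nonzero(d < cutoff)) >= min_pairs


def hydrogen_bond(frame: Frame, donor: int, hydrogen: int, acceptor: int,
                  dist_cutoff: float = HBOND_DIST_CUTOFF,
                  angle_cutoff: float = HBOND_ANGLE_CUTOFF) -> bool:
    """Geometric hydrogen-bond test for a donor/hydrogen/acceptor triplet.

    ``donor``, ``hydrogen`` and ``acceptor`` are atom indices. True iff the
    donor-acceptor distance is <= ``dist_cutoff`` and the D-H...A deviation
    from linearity is <= ``angle_cutoff`` degrees.
    """
    xyz = frame.coords
    d_da = float(np.linalg.norm(xyz[donor] - xyz[acceptor]))
    if d_da > dist_cutoff:
        return False
    v1 = xyz[donor] - xyz[hydrogen]
    v2 = xyz[acceptor] - xyz[hydrogen]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return False
    cos_dha = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    deviation = 180.0 - np.degrees(np.arccos(cos_dha))
    return deviation <= angle_cutoff


def _donor_triplets(fs: FrameSet, indices: np.ndarray, coords: np.ndarray) -> list[tuple[int, int]]:
    """(heavy donor, hydrogen) pairs within one atom subset of a frame."""
    idx = np.asarray(indices)
    heavy = idx[np.isin(fs.element[idx], list(HBOND_ELEMENTS))]
    hydros = idx[fs.element[idx] == "H"]
    out = []
    for h in hydros:
        same_res = heavy[(fs.chain[heavy] == fs.chain[h]) & (fs.resid[heavy] == fs.resid[h])]
        if same_res.size == 0:
            continue
        d = np.linalg.norm(coords[same_res] - coords[h], axis=1)
        j = int(np.argmin(d))
        if d[j] <= _DH_BOND_MAX:
            out.append((int(same_res[j]), int(h)))
        else:
            warnings.warn("hydrogen atom without a bonded donor heavy atom; skipped")
    return out


def _is_backbone(fs: FrameSet, atom_index: int) -> bool:
    return fs.atom_name[atom_index] in BACKBONE_ATOMS


def contact_table(
    frames: FrameSet,
    sel_a: str,
    sel_b: str,
    contact_threshold: float = 20.0,
    hbond_threshold: float = 2.0,
    contact_cutoff: float = CONTACT_CUTOFF,
    hbond_dist_cutoff: float = HBOND_DIST_CUTOFF,
    hbond_angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> list[ContactResult]:
    """Per-residue-pair contact and hydrogen-bond fractions over all frames.

    Neighbour search is accelerated with a k-d tree; rows are filtered at the
    reporting thresholds (percent of frames). Classification letters mark
    side-chain (s) or backbone (b) involvement of the most frequent
    hydrogen-bonding atoms, first letter for ``sel_a``.
    """
    ia = frames.select(sel_a)
    ib = frames.select(sel_b)

    contact_counts: Counter = Counter()
    hbond_counts: Counter = Counter()
    class_counts: dict[tuple[str, str], Counter] = {}

    res_a_of = {int(i): frames.residue_key(int(i)) for i in ia}
    res_b_of = {int(i): frames.residue_key(int(i)) for i in ib}

    for f in range(frames.n_frames):
        xyz = frames.coords[f]
        tree_b = cKDTree(xyz[ib])
        # contacts: count atom pairs under the cutoff per residue pair
        pair_counts: Counter = Counter()
        neighbours = tree_b.query_ball_point(xyz[ia], r=contact_cutoff)
        for a_pos, hits in zip(ia, neighbours):
            ra = res_a_of[int(a_pos)]
            for hit in hits:
                b_pos = int(ib[hit])
                d = np.linalg.norm(xyz[a_pos] - xyz[b_pos])
                if d < contact_cutoff:  # strict inequality
                    pair_counts[(ra, res_b_of[b_pos])] += 1
        for pair, cnt in pair_counts.items():
            if cnt >= CONTACT_MIN_PAIRS:
                contact_counts[pair] += 1

        # hydrogen bonds, both donor directions
        frame = frames.frame(f)
        hb_pairs = set()
        for donors, acceptors, a_first in (((ia, ib, True)), ((ib, ia, False))):
            acc = np.asarray(acceptors)
            acc = acc[np.isin(frames.element[acc], list(HBOND_ELEMENTS))]
            if acc.size == 0:
                continue
            tree_acc = cKDTree(xyz[acc])
            for d_heavy, d_h in _donor_triplets(frames, np.asarray(donors), xyz):
                for hit in tree_acc.query_ball_point(xyz[d_heavy], r=hbond_dist_cutoff):
                    a_idx = int(acc[hit])
                    if (frames.chain[a_idx] == frames.chain[d_heavy]
                            and frames.resid[a_idx] == frames.resid[d_heavy]):
                        continue
                    if hydrogen_bond(frame, d_heavy, d_h, a_idx,
                                     hbond_dist_cutoff, hbond_angle_cutoff):
                        if a_first:
                            pair = (frames.residue_key(d_heavy), frames.residue_key(a_idx))
                            cls = (
                                "b" if _is_backbone(frames, d_heavy) else "s",
                                "b" if _is_backbone(frames, a_idx) else "s",
                            )
                        else:
                            pair = (frames.residue_key(a_idx), frames.residue_key(d_heavy))
                            cls = (
                                "b" if _is_backbone(frames, a_idx) else "s",
                                "b" if _is_backbone(frames, d_heavy) else "s",
                            )
                        hb_pairs.add(pair)
                        class_counts.setdefault(pair, Counter())[cls[0] + cls[1]] += 1
        for pair in hb_pairs:
            hbond_counts[pair] += 1

    results = []
    nf = frames.n_frames
    for pair in sorted(set(contact_counts) | set(hbond_counts)):
        cf = 100.0 * contact_counts.get(pair, 0) / nf
        hf = 100.0 * hbond_counts.get(pair, 0) / nf
        if cf <= contact_threshold and hf <= hbond_threshold:
            continue
        cls = None
        if pair in class_counts:
            cls = class_counts[pair].most_common(1)[0][0]
        results.append(ContactResult(
            res_a=pair[0], res_b=pair[1],
            contact_fraction=cf, hbond_fraction=hf, classification=cls,
        ))
    return results
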
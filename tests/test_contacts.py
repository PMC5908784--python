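"""Contact and hydrogen-bond criteria on constructed coordinate fixtures."""

import numpy as np
import pytest

from conftest import make_frameset
from ctrpharm.contacts import (
    contact_table,
    hydrogen_bond,
    read_frames,
    residue_contact,
)


def two_residue_frame(offsets):
    """Residue A:1 (N, CA) and B:2 (O, C); B placed at given x-offsets."""
    coords = [
        [0.0, 0.0, 0.0],       # A:1 N
        [0.0, 1.5, 0.0],       # A:1 CA
        [offsets[0], 0.0, 0.0],  # B:2 O
        [offsets[1], 1.5, 0.0],  # B:2 C
    ]
    return make_frameset(
        coords,
        chain=["A", "A", "B", "B"], resid=[1, 1, 2, 2],
        atom_name=["N", "CA", "O", "C"], element=["N", "C", "O", "C"],
    )


class TestResidueContact:
    def test_multiple_close_pairs_is_contact(self):
        fs = two_residue_frame([3.0, 3.0])
        assert residue_contact(fs.frame(0), "A:1", "B:2")

    def test_single_close_pair_is_not_a_contact(self):
        # one pair at 3.0 A, everything else >= 5 A
        coords = [
            [0.0, 0.0, 0.0], [0.0, 8.0, 0.0],
            [3.0, 0.0, 0.0], [3.0, 8.0, 5.0],
        ]
        fs = make_frameset(coords, ["A", "A", "B", "B"], [1, 1, 2, 2],
                           ["N", "CA", "O", "C"], ["N", "C", "O", "C"])
        d = np.linalg.norm(np.array(coords[0]) - np.array(coords[2]))
        assert d == pytest.approx(3.0)
        assert not residue_contact(fs.frame(0), "A:1", "B:2")

    def test_cutoff_is_strict(self):
        fs = two_residue_frame([3.5, 3.5])
        assert not residue_contact(fs.frame(0), "A:1", "B:2")
        fs = two_residue_frame([3.4999, 3.4999])
        assert residue_contact(fs.frame(0), "A:1", "B:2")

    def test_symmetry(self):
        fs = two_residue_frame([3.2, 3.2])
        f = fs.frame(0)
        assert residue_contact(f, "A:1", "B:2") == residue_contact(f, "B:2", "A:1")

    def test_missing_residue_errors(self):
        fs = two_residue_frame([3.0, 3.0])
        with pytest.raises(KeyError):
            residue_contact(fs.frame(0), "A:9", "B:2")


def hbond_frame(deviation_deg, dh_to_acceptor):
    """Donor N at origin, H on +x; acceptor O at given H-A distance and
    deviation from D-H...A linearity."""
    th = np.radians(deviation_deg)
    a = np.array([1.0, 0.0, 0.0]) + dh_to_acceptor * np.array([np.cos(th), np.sin(th), 0.0])
    coords = [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], list(a)]
    fs = make_frameset(coords, ["A", "A", "B"], [1, 1, 2],
                       ["N", "H", "O"], ["N", "H", "O"])
    return fs, float(np.linalg.norm(a))


class TestHydrogenBond:
    def test_close_and_linear_is_hbond(self):
        fs, d = hbond_frame(5.0, 1.9)
        assert d <= 3.0
        assert hydrogen_bond(fs.frame(0), donor=0, hydrogen=1, acceptor=2)

    def test_distance_cutoff(self):
        fs, d = hbond_frame(5.0, 2.25)
        assert d > 3.0
        assert not hydrogen_bond(fs.frame(0), donor=0, hydrogen=1, acceptor=2)

    def test_angle_cutoff(self):
        fs, d = hbond_frame(30.0, 1.5)
        assert d <= 3.0
        assert not hydrogen_bond(fs.frame(0), donor=0, hydrogen=1, acceptor=2)

    def test_distance_cutoff_is_inclusive(self):
        fs, d = hbond_frame(0.0, 2.0)  # D-A exactly 3.0
        assert d == pytest.approx(3.0)
        assert hydrogen_bond(fs.frame(0), donor=0, hydrogen=1, acceptor=2)


def brute_force_contact_fractions(fs, ia, ib, cutoff=3.5, min_pairs=2):
    """All-pairs oracle, independent of the k-d-tree implementation."""
    counts = {}
    for f in range(fs.n_frames):
        xyz = fs.coords[f]
        pair_hits = {}
        for i in ia:
            for j in ib:
                if np.sqrt(((xyz[i] - xyz[j]) ** 2).sum()) < cutoff:
                    key = (fs.residue_key(i), fs.residue_key(j))
                    pair_hits[key] = pair_hits.get(key, 0) + 1
        for key, c in pair_hits.items():
            if c >= min_pairs:
                counts[key] = counts.get(key, 0) + 1
    return {k: 100.0 * v / fs.n_frames for k, v in counts.items()}


def random_frameset(n_frames=10, atoms_per_res=10, n_res=10, box=15.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_res * atoms_per_res
    chain = ["A"] * (n // 2) + ["B"] * (n // 2)
    resid = list(np.repeat(np.arange(1, n_res + 1), atoms_per_res)) * 2
    names = [f"C{i % atoms_per_res}" for i in range(n)]
    elem = ["C"] * n
    coords = rng.uniform(0, box, size=(n_frames, n, 3))
    return make_frameset(coords, chain, resid, names, elem)


class TestContactTable:
    def test_fraction_over_frames(self):
        close = two_residue_frame([3.0, 3.0]).coords[0]
        far = two_residue_frame([9.0, 9.0]).coords[0]
        fs = make_frameset(np.stack([close, close, far, far]),
                           ["A", "A", "B", "B"], [1, 1, 2, 2],
                           ["N", "CA", "O", "C"], ["N", "C", "O", "C"])
        rows = contact_table(fs, "A", "B")
        assert len(rows) == 1
        assert rows[0].contact_fraction == pytest.approx(50.0)
        # equals the mean of per-frame booleans
        frac = np.mean([residue_contact(fs.frame(i), "A:1", "B:2") for i in range(4)])
        assert rows[0].contact_fraction == pytest.approx(100.0 * frac)

    def test_reporting_threshold_excludes_low_fractions(self):
        close = two_residue_frame([3.0, 3.0]).coords[0]
        far = two_residue_frame([9.0, 9.0]).coords[0]
        stack = np.stack([close] * 19 + [far] * 81)  # 19% contact fraction
        fs = make_frameset(stack, ["A", "A", "B", "B"], [1, 1, 2, 2],
                           ["N", "CA", "O", "C"], ["N", "C", "O", "C"])
        assert contact_table(fs, "A", "B") == []
        rows = contact_table(fs, "A", "B", contact_threshold=10.0)
        assert rows[0].contact_fraction == pytest.approx(19.0)

    def test_agrees_with_brute_force_on_random_frames(self):
        fs = random_frameset(n_frames=10, seed=3)
        ia, ib = fs.select("A"), fs.select("B")
        oracle = brute_force_contact_fractions(fs, ia, ib)
        rows = contact_table(fs, "A", "B", contact_threshold=-1.0, hbond_threshold=-1.0)
        got = {(r.res_a, r.res_b): r.contact_fraction for r in rows if r.contact_fraction > 0}
        assert got == pytest.approx(oracle)

    def test_rigid_motion_invariance(self):
        fs = random_frameset(n_frames=4, seed=11)
        rows = contact_table(fs, "A", "B", contact_threshold=-1.0)
        # arbitrary rotation + translation
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        moved = make_frameset(fs.coords @ R.T + np.array([5.0, -3.0, 2.0]),
                              fs.chain, fs.resid, fs.atom_name, fs.element)
        rows_m = contact_table(moved, "A", "B", contact_threshold=-1.0)
        a = {(r.res_a, r.res_b): r.contact_fraction for r in rows}
        b = {(r.res_a, r.res_b): r.contact_fraction for r in rows_m}
        assert a == pytest.approx(b, abs=1e-9)

    def test_hbond_classification_sidechain_backbone(self):
        # donor is a side-chain amine (NZ/HZ), acceptor is a backbone carbonyl O
        coords = [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.9, 0.0, 0.0]]
        fs = make_frameset(coords, ["A", "A", "B"], [1, 1, 2],
                           ["NZ", "HZ1", "O"], ["N", "H", "O"])
        rows = contact_table(fs, "A", "B", contact_threshold=-1.0, hbond_threshold=-1.0)
        hb = [r for r in rows if r.hbond_fraction > 0]
        assert len(hb) == 1
        assert hb[0].hbond_fraction == pytest.approx(100.0)
        assert hb[0].classification == "sb"

    def test_empty_selection_errors(self):
        fs = two_residue_frame([3.0, 3.0])
        with pytest.raises(ValueError):
            contact_table(fs, "Z", "B")


class TestReadFrames:
    def test_multi_model_pdb_round_trip(self, tmp_path):
        def atom_line(i, name, res, ch, resid, xyz, el):
            return (f"ATOM  {i:5d} {name:<4s} {res:>3s} {ch}{resid:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"          {el:>2s}")

        lines = []
        for m, dx in ((1, 0.0), (2, 1.0)):
            lines.append(f"MODEL     {m}")
            lines.append(atom_line(1, "N", "ALA", "A", 1, (0, 0, 0), "N"))
            lines.append(atom_line(2, "CA", "ALA", "A", 1, (0, 1.5, 0), "C"))
            lines.append(atom_line(3, "O", "GLY", "B", 2, (3.0 + dx, 0, 0), "O"))
            lines.append(atom_line(4, "C", "GLY", "B", 2, (3.0 + dx, 1.5, 0), "C"))
            lines.append("ENDMDL")
        lines.append("END")
        p = tmp_path / "frames.pdb"
        p.write_text("\n".join(lines) + "\n")

        fs = read_frames(p)
        assert fs.n_frames == 2
        assert fs.coords.shape == (2, 4, 3)
        assert residue_contact(fs.frame(0), "A:1", "B:2")
        assert not residue_contact(fs.frame(1), "A:1", "B:2")  # 4.0 A gap
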
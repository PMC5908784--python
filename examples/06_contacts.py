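"""Residue-contact and hydrogen-bond analysis over an ensemble of frames.

A contact requires at least two atom pairs closer than 3.5 A; a hydrogen
bond requires donor-acceptor distance <= 3.0 A and <= 20 degrees deviation
from donor-H-acceptor linearity. Fractions are reported over frames.
This example builds a tiny two-model PDB on the fly.
"""

import tempfile
from pathlib import Path

from ctrpharm import contact_table, read_frames


def atom(i, name, res, ch, resid, xyz, el):
    return (f"ATOM  {i:5d} {name:<4s} {res:>3s} {ch}{resid:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {el:>2s}")


lines = []
for model, dx in ((1, 0.0), (2, 1.5)):  # residues drift apart in model 2
    lines.append(f"MODEL     {model}")
    lines.append(atom(1, "N", "LYS", "A", 1, (0.0, 0.0, 0.0), "N"))
    lines.append(atom(2, "NZ", "LYS", "A", 1, (0.0, 1.4, 0.0), "N"))
    lines.append(atom(3, "HZ1", "LYS", "A", 1, (1.0, 1.4, 0.0), "H"))
    lines.append(atom(4, "O", "ASP", "B", 2, (2.9 + dx, 1.4, 0.0), "O"))
    lines.append(atom(5, "C", "ASP", "B", 2, (2.9 + dx, 0.0, 0.0), "C"))
    lines.append("ENDMDL")
lines.append("END")

with tempfile.TemporaryDirectory() as td:
    pdb = Path(td) / "ensemble.pdb"
    pdb.write_text("\n".join(lines) + "\n")
    frames = read_frames(pdb)
    print(f"{frames.n_frames} frames, {frames.coords.shape[1]} atoms")
    for row in contact_table(frames, "A", "B",
                             contact_threshold=0.0, hbond_threshold=0.0):
        print(f"{row.res_a} -- {row.res_b}: contact {row.contact_fraction:.0f}%"
              f", H-bond {row.hbond_fraction:.0f}%, class {row.classification}")
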
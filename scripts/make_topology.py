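"""Regenerate the internal-coordinate topology template.

Derives a per-residue z-matrix (bond lengths, bond angles, torsion
offsets and chi-dof mapping) for the 20 standard amino acids from the
ideal-geometry residue templates bundled with biotite, and writes it to
``src/gradff/data/topology.yaml``.  Run from the repository root:

    python scripts/make_topology.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
import biotite.structure.info as struc_info

AA = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

# rotatable side-chain torsions: quadruple of atom names per slot
CHI_DEFS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ"),
            ("CD", "NE", "CZ", "NH1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# side-chain polar hydrogens to keep (all others dropped)
POLAR_H = {
    "ARG": ["HE", "HH11", "HH12", "HH21", "HH22"],
    "ASN": ["HD21", "HD22"],
    "GLN": ["HE21", "HE22"],
    "HIS": ["HE2"],  # N-epsilon tautomer of neutral His
    "LYS": ["HZ1", "HZ2", "HZ3"],
    "SER": ["HG"],
    "THR": ["HG1"],
    "TRP": ["HE1"],
    "TYR": ["HH"],
    "CYS": ["HG"],
}

# rotatable hydroxyl / thiol hydrogens: torsion pinned trans instead of CCD value
TRANS_H = {("SER", "HG"), ("THR", "HG1"), ("TYR", "HH"), ("CYS", "HG")}

BACKBONE = {"N", "CA", "C", "O"}


def dihedral(p0, p1, p2, p3):
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    c12, c23 = np.cross(b1, b2), np.cross(b2, b3)
    return float(np.degrees(np.arctan2(
        np.dot(np.cross(c12, c23), b2 / np.linalg.norm(b2)), np.dot(c12, c23))))


def angle(p0, p1, p2):
    u, v = p0 - p1, p2 - p1
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))


def build_residue(resname: str) -> dict:
    tmpl = struc_info.residue(resname)
    names = [str(n) for n in tmpl.atom_name]
    coord = {n: tmpl.coord[i] for i, n in enumerate(names)}
    elem = {n: str(e).capitalize() for n, e in zip(names, tmpl.element)}

    keep_h = set(POLAR_H.get(resname, []))
    keep = [n for n in names
            if (elem[n] != "H" and n not in ("OXT",)) or n in keep_h]

    bonds = set()
    for i, j, _ in tmpl.bonds.as_array():
        a, b = names[i], names[j]
        if a in keep and b in keep:
            bonds.add((a, b))
            bonds.add((b, a))
    neighbors = {n: sorted({b for a, b in bonds if a == n},
                           key=lambda x: (elem[x] == "H", x)) for n in keep}

    # BFS over the side chain rooted at CA; ring-closing bonds are ignored
    parent = {"CA": "N", "N": None, "C": "CA", "O": "C"}
    order = []
    queue = ["CA"]
    visited = set(BACKBONE)
    while queue:
        cur = queue.pop(0)
        for nb in neighbors.get(cur, []):
            if nb in visited or nb in BACKBONE:
                continue
            visited.add(nb)
            parent[nb] = cur
            order.append(nb)
            queue.append(nb)

    chi_defs = CHI_DEFS.get(resname, [])
    chi_tip = {q[3]: k for k, q in enumerate(chi_defs)}

    entries = []
    primary_tau: dict[tuple, tuple] = {}  # (parent, grand) -> (dof index, tau)
    default_chi = [0.0] * len(chi_defs)
    for name in order:
        p = parent[name]
        if p == "CA":
            refs = ("CA", "N", "C")  # improper keeps L-chirality
        else:
            g = parent[p]
            gg = parent[g] if parent[g] is not None else "C"
            refs = (p, g, gg)
        r = float(np.linalg.norm(coord[name] - coord[refs[0]]))
        th = angle(coord[name], coord[refs[0]], coord[refs[1]])
        tau = dihedral(coord[refs[2]], coord[refs[1]], coord[refs[0]], coord[name])
        entry = {"name": name, "element": elem[name], "refs": list(refs),
                 "r": round(r, 4), "theta": round(th, 3)}
        key = (refs[0], refs[1])
        if name in chi_tip:
            k = chi_tip[name]
            entry["tau"] = {"dof": f"chi{k + 1}"}
            default_chi[k] = round(tau, 3)
            primary_tau[key] = (k, tau)
        elif (resname, name) in TRANS_H:
            entry["tau"] = {"fixed": 180.0}
        else:
            entry["tau"] = {"fixed": round(tau, 3)}
            entry["_raw_tau"] = tau
        entries.append(entry)

    # second pass: atoms sharing a rotation axis with a chi tip co-rotate
    # with that chi (e.g. CD2 of His/aromatics placed before the tip)
    for entry in entries:
        key = (entry["refs"][0], entry["refs"][1])
        raw = entry.pop("_raw_tau", None)
        if raw is not None and key in primary_tau:
            k, t0 = primary_tau[key]
            off = (raw - t0 + 180.0) % 360.0 - 180.0
            entry["tau"] = {"dof": f"chi{k + 1}", "offset": round(off, 3)}

    bb = {
        "r_N_CA": round(float(np.linalg.norm(coord["CA"] - coord["N"])), 4),
        "r_CA_C": round(float(np.linalg.norm(coord["C"] - coord["CA"])), 4),
        "r_C_O": round(float(np.linalg.norm(coord["O"] - coord["C"])), 4),
        "ang_N_CA_C": round(angle(coord["N"], coord["CA"], coord["C"]), 3),
        "ang_CA_C_O": round(angle(coord["CA"], coord["C"], coord["O"]), 3),
    }
    return {
        "backbone": bb,
        "sidechain": entries,
        "chi": [list(q) for q in chi_defs],
        "default_chi": default_chi,
        "has_amide_h": resname != "PRO",
    }


def main() -> None:
    topo = {
        "peptide": {
            "r_C_N": 1.329,
            "ang_CA_C_N": 116.2,
            "ang_C_N_CA": 121.7,
            "r_N_H": 1.01,
            "ang_H_N_C": 119.15,
        },
        "residues": {resname: build_residue(resname) for resname in AA},
    }
    out = Path(__file__).resolve().parents[1] / "src" / "gradff" / "data" / "topology.yaml"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        yaml.safe_dump(topo, fh, sort_keys=False, default_flow_style=None)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
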
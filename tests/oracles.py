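"""Independent oracles used by the test suite.

These deliberately avoid all package code: raw PDB text parsing and plain
O(N^2) loops, so they can serve as a second, independent route to the
similarity index.
"""

import math

import numpy as np

CHARGES = {"LYS": 1, "ARG": 1, "ASP": -1, "GLU": -1}
BACKBONE = {"P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'",
            "C3'", "O3'", "C2'", "O2'", "C1'"}


def _parse_pdb(path):
    residues = {}
    for line in open(path):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        key = (line[21], int(line[22:26]))
        residues.setdefault(key, {"name": line[17:20].strip(), "atoms": []})
        residues[key]["atoms"].append(
            (line[12:16].strip(), line[76:78].strip(),
             (float(line[30:38]), float(line[38:46]), float(line[46:54]))))
    return residues


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def brute_force_chi(path, protein_chain="A", dna_chain="B",
                    a=5.0, r_c=8.0, contact_cutoff=3.5):
    """(protein chi, number of contact residues) by exhaustive loops.

    Default charge scheme, base-polar contact rule, minimum-heavy-atom
    distances, self included at weight 1.
    """
    residues = _parse_pdb(path)
    prot = {k: v for k, v in residues.items() if k[0] == protein_chain}
    dna = {k: v for k, v in residues.items() if k[0] == dna_chain}
    base_no = [at[2] for r in dna.values() for at in r["atoms"]
               if at[0] not in BACKBONE and at[1] in ("N", "O")]
    contact_res = [
        k for k, r in prot.items()
        if any(_dist(at[2], b) <= contact_cutoff for at in r["atoms"]
               if at[1] in ("N", "O") for b in base_no)]

    def min_dist(r1, r2):
        return min(_dist(x[2], y[2])
                   for x in r1["atoms"] for y in r2["atoms"])

    chis = []
    for k in contact_res:
        num = float(CHARGES.get(prot[k]["name"], 0))
        den = 1.0
        for k2, other in prot.items():
            if k2 == k:
                continue
            d = min_dist(prot[k], other)
            if d < r_c:
                w = math.exp(-a * d / r_c)
                num += CHARGES.get(other["name"], 0) * w
                den += w
        chis.append(num / den)
    return float(np.mean(chis)), len(contact_res)
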
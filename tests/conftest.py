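"""Shared fixtures and independent brute-force oracles."""
import numpy as np
import pytest

from thermoshift import comparative_design as cd
from thermoshift import synthetic_data as sd


def brute_force_distance_map(pdb_text: str, ligand_names: list[str]) -> dict:
    """All-pairs heavy-atom distance oracle with its own PDB column parser.

    Independent of gemmi: fixed-column parsing of ATOM/HETATM records only.
    Returns {(chain, resnum, resname): {ligand: min distance}}.
    """
    polymer: dict[tuple, list] = {}
    ligands: dict[str, list] = {n: [] for n in ligand_names}
    for line in pdb_text.splitlines():
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        element = line[76:78].strip()
        if element in ("H", "D"):
            continue
        resname = line[17:20].strip()
        chain = line[21]
        resnum = int(line[22:26])
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        if rec == "HETATM" and resname in ligands:
            ligands[resname].append(xyz)
        elif rec == "ATOM":
            polymer.setdefault((chain, resnum, resname), []).append(xyz)
    out = {}
    for key, atoms in polymer.items():
        a = np.asarray(atoms)
        out[key] = {}
        for name, latoms in ligands.items():
            la = np.asarray(latoms)
            d = np.sqrt(((a[:, None, :] - la[None, :, :]) ** 2).sum(-1))
            out[key][name] = float(d.min())
    return out


def random_alignment_and_structure(rng: np.random.Generator, n_residues: int = 10):
    """Random ungapped pairwise alignment matched to a random toy structure."""
    pdb_text, specs = sd.random_toy_structure(rng, n_residues=n_residues)
    seq_a = "".join(sd.AA1[s.resname] for s in specs)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    seq_b = list(seq_a)
    for i in range(n_residues):
        if rng.random() < 0.5:
            seq_b[i] = aa[int(rng.integers(20))]
    cols = [cd.AlignmentColumn(a, b, i + 1, i + 1)
            for i, (a, b) in enumerate(zip(seq_a, seq_b))]
    aln = cd.PairwiseAlignmentMap("A", "B", cols)
    return aln, pdb_text, specs


@pytest.fixture(scope="session")
def tt_truth():
    return sd.preset_truth("thermophile-like")


@pytest.fixture(scope="session")
def ec_truth():
    return sd.preset_truth("mesophile-like")


@pytest.fixture(scope="session")
def printed_constants():
    from thermoshift.kinetics_fit import load_printed_constants
    return load_printed_constants()
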
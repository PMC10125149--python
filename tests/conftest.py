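"""Shared fixtures: toy proteins, the packaged energy table, and a tiny
programmatic PDB writer (all fixtures are generated at test time)."""

from __future__ import annotations

import numpy as np
import pytest

from porepass import AAEnergyTable, neighbors
from porepass.synthetic import gen_toy_protein


def write_pdb(path, residues):
    """Write minimal ATOM records.

    ``residues`` is a list of (resname, atoms) with atoms a list of
    (atom_name, element, (x, y, z)).
    """
    lines = []
    serial = 1
    for resseq, (resname, atoms) in enumerate(residues, start=1):
        for name, element, (x, y, z) in atoms:
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad_name:4s} {resname:>3s} A{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def table() -> AAEnergyTable:
    return AAEnergyTable.default()


@pytest.fixture(scope="session")
def hetero_toy():
    """8-residue random-cloud toy with distinct energies and varied RSA."""
    codes = ["CYS", "ARG", "GLY", "HIS", "LYS", "ASP", "SER", "TRP"]
    rsa = list(np.linspace(0.2, 1.0, 8))
    protein, _ = gen_toy_protein(8, codes, rsa, geometry="random", seed=3)
    return protein


@pytest.fixture(scope="session")
def hetero_nbrs(hetero_toy):
    return neighbors(hetero_toy, 5)


@pytest.fixture(scope="session")
def homopolymer():
    """All-CYS line toy: zero-variance patch energies."""
    protein, _ = gen_toy_protein(6, ["CYS"] * 6, [1.0] * 6, geometry="line", seed=0)
    return protein
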
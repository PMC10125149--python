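"""Per-residue protein model consumed by the contact-patch selection model.

Each residue carries a representative coordinate (alpha carbon by default,
heavy-atom centroid when no CA is present), a relative surface accessibility
(RSA) in [0, 1], and its 3-letter code.  The model also records the net
charge (units of e) and mass (kDa), which the kinetics module needs; both
must be supplied explicitly.

RSA is normally read from a user-supplied table (e.g. a structure-prediction
tool's output); :func:`compute_rsa` is an offline convenience that computes
Shrake–Rupley accessible surface areas and normalises them by theoretical
per-residue maxima.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley

__all__ = [
    "Residue",
    "ProteinModel",
    "NeighborList",
    "load_protein",
    "load_rsa_table",
    "compute_rsa",
    "neighbors",
]


@dataclass(frozen=True)
class Residue:
    index: int
    code: str
    coord: np.ndarray  # (3,) Å
    rsa: float

    def __post_init__(self):
        c = np.asarray(self.coord, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"residue {self.index}: coordinate must be a finite 3-vector")
        if not 0.0 <= self.rsa <= 1.0:
            raise ValueError(f"residue {self.index}: RSA {self.rsa} outside [0, 1]")
        object.__setattr__(self, "coord", c)


@dataclass
class ProteinModel:
    name: str
    residues: list[Residue]
    net_charge: int  # multiples of e
    mass_kda: float

    def __post_init__(self):
        idx = [r.index for r in self.residues]
        if idx != list(range(len(idx))):
            raise ValueError("residue indices must be unique and contiguous from 0")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.coord for r in self.residues])

    @property
    def rsa(self) -> np.ndarray:
        return np.array([r.rsa for r in self.residues])

    @property
    def codes(self) -> list[str]:
        return [r.code for r in self.residues]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "name": self.name,
            "net_charge": self.net_charge,
            "mass_kda": self.mass_kda,
            "residues": [
                {"index": r.index, "code": r.code, "coord": r.coord.tolist(), "rsa": r.rsa}
                for r in self.residues
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProteinModel":
        obj = json.loads(Path(path).read_text())
        residues = [
            Residue(r["index"], r["code"], np.array(r["coord"]), r["rsa"])
            for r in obj["residues"]
        ]
        return cls(obj["name"], residues, obj["net_charge"], obj["mass_kda"])


@dataclass(frozen=True)
class NeighborList:
    """L nearest residues per residue, Euclidean on representative coordinates.

    ``indices[i]`` lists residue i's neighbours nearest-first; distance ties
    are broken by ascending residue index.  Self is excluded.
    """

    indices: np.ndarray  # (n, L) int
    distances: np.ndarray  # (n, L) Å

    @property
    def L(self) -> int:
        return self.indices.shape[1]


def neighbors(protein: ProteinModel, L: int) -> NeighborList:
    """Exact L-nearest-neighbour lists (deterministic under input ordering)."""
    if L < 1:
        raise ValueError("L must be >= 1")
    n = len(protein)
    if n < 2:
        raise ValueError("need at least 2 residues for a neighbour list")
    L_eff = min(L, n - 1)
    xyz = protein.coords
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    idx_rows = np.empty((n, L_eff), dtype=int)
    dist_rows = np.empty((n, L_eff))
    all_idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((all_idx, d[i]))[:L_eff]  # distance, then index
        idx_rows[i] = order
        dist_rows[i] = d[i, order]
    return NeighborList(indices=idx_rows, distances=dist_rows)


def load_rsa_table(path: str | Path) -> list[tuple[int, str, float]]:
    """Read an ``index<TAB>code<TAB>rsa`` table."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("index"):
            continue
        i, code, rsa = line.split("\t")[:3]
        rows.append((int(i), code.upper(), float(rsa)))
    return rows


def _representative_coord(residue) -> np.ndarray:
    if "CA" in residue:
        return np.asarray(residue["CA"].coord, dtype=float)
    heavy = [a.coord for a in residue.get_atoms() if a.element != "H"]
    if not heavy:
        raise ValueError(f"residue {residue.get_id()} has no heavy atoms")
    return np.mean(np.asarray(heavy, dtype=float), axis=0)


def load_protein(
    pdb_path: str | Path,
    rsa_table_path: str | Path,
    net_charge: int,
    mass_kda: float,
    name: str | None = None,
    chain_id: str | None = None,
) -> ProteinModel:
    """Build a :class:`ProteinModel` from a PDB file and an RSA table.

    The representative coordinate is the alpha carbon, falling back to the
    heavy-atom centroid for residues without one.  The RSA table must have
    exactly one row per residue, in sequence order.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(name or Path(pdb_path).stem, str(pdb_path))
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise ValueError(f"chain {chain_id!r} not found")
    elif len(chains) > 1:
        raise ValueError(
            f"structure has {len(chains)} chains; select one with chain_id"
        )
    chain = chains[0]
    pdb_residues = [r for r in chain.get_residues() if r.id[0] == " "]
    if not pdb_residues:
        raise ValueError("selected chain contains no standard residues")

    rsa_rows = load_rsa_table(rsa_table_path)
    if len(rsa_rows) != len(pdb_residues):
        raise ValueError(
            f"RSA table has {len(rsa_rows)} rows but structure has "
            f"{len(pdb_residues)} residues"
        )

    residues = []
    for i, (pdb_res, (_, code, rsa)) in enumerate(zip(pdb_residues, rsa_rows)):
        pdb_code = pdb_res.get_resname().upper()
        if code != pdb_code:
            warnings.warn(
                f"residue {i}: RSA table says {code}, structure says {pdb_code}; "
                "using the structure's code",
                stacklevel=2,
            )
        residues.append(Residue(i, pdb_code, _representative_coord(pdb_res), rsa))
    return ProteinModel(
        name=name or Path(pdb_path).stem,
        residues=residues,
        net_charge=int(net_charge),
        mass_kda=float(mass_kda),
    )


def _max_asa_table() -> dict[str, float]:
    path = resources.files("porepass.data") / "max_asa.tsv"
    table = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("code"):
            continue
        code, asa = line.split("\t")
        table[code.upper()] = float(asa)
    return table


def compute_rsa(
    pdb_path: str | Path,
    probe_radius: float = 1.4,
    n_points: int = 960,
    chain_id: str | None = None,
) -> list[tuple[int, str, float]]:
    """Per-residue RSA via Shrake–Rupley rolling-probe sampling.

    Accessible surface areas are computed with a fixed deterministic point
    count per atom and normalised by theoretical per-residue maximum ASA;
    values are clipped at 1.  Returns ``(index, code, rsa)`` rows in the same
    format :func:`load_rsa_table` reads.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("rsa", str(pdb_path))
    model = next(structure.get_models())
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points)
    sr.compute(model, level="R")

    chains = list(model.get_chains())
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise ValueError(f"chain {chain_id!r} not found")
    max_asa = _max_asa_table()
    rows = []
    i = 0
    for chain in chains:
        for res in chain.get_residues():
            if res.id[0] != " ":
                continue
            if not any(True for _ in res.get_atoms()):
                raise ValueError(f"residue {res.get_id()} has no atoms")
            code = res.get_resname().upper()
            denom = max_asa.get(code)
            if denom is None:
                warnings.warn(f"no max-ASA entry for {code}; RSA set to 0", stacklevel=2)
                rsa = 0.0
            else:
                rsa = min(res.sasa / denom, 1.0)
            rows.append((i, code, float(rsa)))
            i += 1
    return rows


def write_rsa_table(rows, path: str | Path) -> None:
    lines = ["index\tcode\trsa"]
    lines += [f"{i}\t{c}\t{r:.6f}" for i, c, r in rows]
    Path(path).write_text("\n".join(lines) + "\n")
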
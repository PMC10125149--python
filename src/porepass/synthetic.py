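"""Synthetic fixture generators for every pipeline input.

These stand in for the upstream electronic-structure scans, structure/RSA
inputs and MD ion trajectories, with known ground truth recorded in the
returned metadata so tests can check the analysis chain against it.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .current_analysis import IonTrajectory
from .energy_curves import EnergyCurve, morse
from .protein_model import ProteinModel, Residue
from .units import E_PER_PS_IN_NA

__all__ = ["default_scan_grid", "gen_energy_curve", "gen_toy_protein", "gen_ion_trajectory"]


def default_scan_grid(s0: float = 2.5, far: float = 15.0) -> np.ndarray:
    """Separation grid mimicking a real scan: 0.1–0.2 Å steps near the well,
    1.0 Å steps far away, extending past 10 Å."""
    near = np.arange(max(s0 - 1.0, 0.2), s0 + 1.0, 0.1)
    mid = np.arange(s0 + 1.0, s0 + 3.0, 0.2)
    far_pts = np.arange(s0 + 3.0, far + 0.5, 1.0)
    return np.unique(np.round(np.concatenate([near, mid, far_pts]), 6))


def gen_energy_curve(
    D: float = 1.0,
    a: float = 1.2,
    s0: float = 2.5,
    C: float = -3.0,
    noise_sd: float = 0.0,
    grid: np.ndarray | None = None,
    seed: int = 0,
    residue_code: str = "XXX",
) -> tuple[EnergyCurve, dict]:
    """Morse-shaped scan V(s) = C + D(1 - e^(-a(s-s0)))^2 with optional noise.

    Returns ``(curve, metadata)``; metadata records the generating parameters
    and the true interaction energy ``-D``.
    """
    s = default_scan_grid(s0) if grid is None else np.asarray(grid, dtype=float)
    if s.min() > s0 or s.max() < 10.0:
        raise ValueError("grid must cover the well (s0) and reach past 10 Å")
    e = morse(s, D, a, s0, C)
    if noise_sd > 0:
        e = e + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(s))
    curve = EnergyCurve(residue_code, s, e, orientation_note="synthetic Morse scan")
    meta = {"D": D, "a": a, "s0": s0, "C": C, "noise_sd": noise_sd, "seed": seed,
            "true_delta_e": -D, "true_asymptote": C + D}
    return curve, meta


def gen_toy_protein(
    n: int,
    codes: list[str],
    rsa: list[float],
    geometry: str = "line",
    spacing: float = 3.8,
    seed: int = 0,
    name: str = "toy",
    net_charge: int = 1,
    mass_kda: float = 3.9,
) -> tuple[ProteinModel, dict]:
    """Toy protein with deterministic (line/ring) or seeded random coordinates."""
    if len(codes) != n or len(rsa) != n:
        raise ValueError("codes and rsa must both have length n")
    if geometry == "line":
        coords = np.column_stack([spacing * np.arange(n), np.zeros(n), np.zeros(n)])
    elif geometry == "ring":
        r = n * spacing / (2.0 * np.pi)
        theta = 2.0 * np.pi * np.arange(n) / n
        coords = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(n)])
    elif geometry == "random":
        rng = np.random.default_rng(seed)
        coords = rng.normal(0.0, spacing * n ** (1.0 / 3.0), size=(n, 3))
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    residues = [Residue(i, codes[i].upper(), coords[i], float(rsa[i])) for i in range(n)]
    protein = ProteinModel(name=name, residues=residues,
                           net_charge=net_charge, mass_kda=mass_kda)
    meta = {"geometry": geometry, "spacing": spacing, "seed": seed}
    return protein, meta


def gen_ion_trajectory(
    n_ions: int = 22,
    drift: float = 2.0,  # Å/ps along +z for cations, -z for anions
    diffusion: float = 0.5,  # Å^2/ps
    frames: int = 2000,
    box: tuple[float, float, float] = (40.0, 40.0, 80.0),
    lz: float = 36.0,
    delta_t: float = 1.0,  # ps
    seed: int = 0,
) -> tuple[IonTrajectory, dict]:
    """Drift–diffusion electrolyte with field-driven +/- populations.

    Each step updates z by ``q * drift * dt + sqrt(2 D dt) * N(0,1)`` with
    periodic wrapping in the box; the box height stays larger than the pore
    slab so in-slab per-step displacements remain physical, and ``box_z`` is
    recorded on the trajectory so the current sum can minimum-image any
    wrapped step.  Both charge signs add to the current, so the expected
    instantaneous current is ``E[n_slab] * drift / lz`` in e/ps with
    ``E[n_slab] = n_ions * lz / box_z`` for the uniform initial placement.
    """
    bx, by, bz = box
    if bz <= lz:
        raise ValueError("box height must exceed the pore slab length")
    if abs(drift) * delta_t > bz / 4:
        raise ValueError("drift per step too large for the box")
    rng = np.random.default_rng(seed)
    charges = np.where(np.arange(n_ions) < (n_ions + 1) // 2, 1, -1)
    pos = np.column_stack([
        rng.uniform(-bx / 2, bx / 2, n_ions),
        rng.uniform(-by / 2, by / 2, n_ions),
        rng.uniform(-bz / 2, bz / 2, n_ions),
    ])
    sigma = np.sqrt(2.0 * diffusion * delta_t)

    times = delta_t * np.arange(frames)
    ids_f, charges_f, pos_f = [], [], []
    ion_ids = np.arange(n_ions)
    for _ in range(frames):
        ids_f.append(ion_ids.copy())
        charges_f.append(charges.copy())
        pos_f.append(pos.copy())
        step = charges * drift * delta_t
        if diffusion > 0:
            step = step + rng.normal(0.0, sigma, n_ions)
        pos = pos.copy()
        pos[:, 2] += step
        # wrap into (-bz/2, bz/2]
        pos[:, 2] -= bz * np.round(pos[:, 2] / bz)

    traj = IonTrajectory(times, ids_f, charges_f, pos_f, lz=lz, box_z=bz)
    expected_e_per_ps = n_ions * (lz / bz) * drift / lz
    meta = {
        "n_ions": n_ions, "drift": drift, "diffusion": diffusion,
        "frames": frames, "box": box, "lz": lz, "seed": seed,
        "expected_current_e_per_ps": expected_e_per_ps,
        "expected_current_na": expected_e_per_ps * E_PER_PS_IN_NA,
        "expected_slab_count": n_ions * lz / bz,
    }
    return traj, meta
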
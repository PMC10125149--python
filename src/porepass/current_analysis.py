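"""Occupied-pore ionic current from ion trajectories.

The instantaneous current through the pore region (an axial slab of length
l_z, default 36 Å) is computed from per-ion displacements:

    I(t) = 1 / (dt * l_z) * sum_i q_i * (z_i(t + dt) - z_i(t)),

summing over ions inside the slab at frame t, with q_i = +/-1 e and dt the
frame spacing (1 ps in the reference trajectories).  Currents are reported
in nA using 1 e/ps = 160.2177 nA.  The module also provides pore-slab ion
counting, zero-phase Butterworth low-pass filtering (cutoffs of 1 GHz for
smoothing and 5 GHz for current histograms are typical), current
histogramming with time-window exclusion, dipole-alignment conditioning of
histograms, and centre-of-mass tracking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .units import E_PER_PS_IN_NA

__all__ = [
    "IonTrajectory",
    "CurrentTrace",
    "FilterSpec",
    "DipoleTrace",
    "instantaneous_current",
    "count_pore_ions",
    "lowpass",
    "current_histogram",
    "dipole_conditioned_histograms",
    "com_track",
]


@dataclass
class IonTrajectory:
    """Frames of (ion id, charge, position) with uniform time spacing.

    ``box_z`` (Å), when set, is the periodic box height used to minimum-image
    per-step displacements so that wrapped coordinates still yield physical
    displacements in the current sum.
    """

    times: np.ndarray  # (F,) ps, uniform spacing
    ids: list[np.ndarray]  # per frame, int ion ids
    charges: list[np.ndarray]  # per frame, +/-1 e
    positions: list[np.ndarray]  # per frame, (n_i, 3) Å
    lz: float = 36.0  # pore-region length, Å
    center_z: float = 0.0  # membrane centre, Å
    box_z: float | None = None  # periodic box height, Å

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if len(t) < 1:
            raise ValueError("trajectory needs at least one frame")
        if len(t) > 1:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame times must be uniformly spaced")
        for q in self.charges:
            if q.size and not np.all(np.isin(q, (-1, 1))):
                raise ValueError("ion charges must be +1 or -1 e")
        self.times = t

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def delta_t(self) -> float:
        if self.n_frames < 2:
            raise ValueError("delta_t undefined for a single frame")
        return float(self.times[1] - self.times[0])

    @classmethod
    def from_tsv(cls, path: str | Path, lz: float = 36.0, center_z: float = 0.0,
                 box_z: float | None = None) -> "IonTrajectory":
        """Read ``time_ps ion_id charge x y z`` rows (whitespace separated)."""
        df = pd.read_csv(
            path, sep=r"\s+", comment="#",
            names=["time_ps", "ion_id", "charge", "x", "y", "z"],
        )
        times, ids, charges, positions = [], [], [], []
        for t, grp in df.groupby("time_ps", sort=True):
            times.append(t)
            ids.append(grp["ion_id"].to_numpy(dtype=int))
            charges.append(grp["charge"].to_numpy(dtype=int))
            positions.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
        return cls(np.array(times), ids, charges, positions,
                   lz=lz, center_z=center_z, box_z=box_z)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for t, fid, q, pos in zip(self.times, self.ids, self.charges, self.positions):
            for j in range(len(fid)):
                rows.append(
                    f"{t:.6g} {fid[j]} {q[j]:+d} "
                    f"{pos[j, 0]:.6f} {pos[j, 1]:.6f} {pos[j, 2]:.6f}"
                )
        Path(path).write_text("# time_ps ion_id charge x y z\n" + "\n".join(rows) + "\n")


@dataclass(frozen=True)
class FilterSpec:
    cutoff_ghz: float
    order: int = 4
    kind: str = "butterworth"


@dataclass
class CurrentTrace:
    times: np.ndarray  # ps, one value per frame pair (length frames - 1)
    current: np.ndarray  # nA
    delta_t: float  # ps
    filter_applied: FilterSpec | None = None
    skipped_ions: int = 0  # displacement terms dropped for missing partner frames

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.times.shape != self.current.shape:
            raise ValueError("times and current must have equal length")


@dataclass
class DipoleTrace:
    """Per-frame protein dipole vectors (e Å) with field-alignment flags."""

    times: np.ndarray  # ps
    dipoles: np.ndarray  # (F, 3) e Å
    field_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    threshold_deg: float = 90.0  # aligned iff angle to field axis < threshold

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        if self.dipoles.shape != (len(self.times), 3):
            raise ValueError("dipoles must be (n_frames, 3)")
        ax = np.asarray(self.field_axis, dtype=float)
        self.field_axis = ax / np.linalg.norm(ax)

    @property
    def aligned(self) -> np.ndarray:
        proj = self.dipoles @ self.field_axis
        norm = np.linalg.norm(self.dipoles, axis=1)
        with np.errstate(invalid="ignore"):
            cosang = np.where(norm > 0, proj / norm, 0.0)
        return cosang > np.cos(np.deg2rad(self.threshold_deg))

    @staticmethod
    def from_point_charges(times, charges, positions, **kwargs) -> "DipoleTrace":
        """Dipole = sum_i q_i r_i per frame, for (F, n) charges and (F, n, 3) positions."""
        q = np.asarray(charges, dtype=float)
        r = np.asarray(positions, dtype=float)
        dip = np.einsum("fi,fij->fj", q, r)
        return DipoleTrace(np.asarray(times, dtype=float), dip, **kwargs)


def _in_slab(traj: IonTrajectory, z: np.ndarray) -> np.ndarray:
    return np.abs(z - traj.center_z) < traj.lz / 2.0


def count_pore_ions(traj: IonTrajectory) -> np.ndarray:
    """Per-frame count of ions strictly inside the pore slab |z - c| < l_z/2."""
    return np.array([int(_in_slab(traj, pos[:, 2]).sum()) for pos in traj.positions])


def instantaneous_current(traj: IonTrajectory) -> CurrentTrace:
    """Displacement-sum ionic current, one value per consecutive frame pair.

    Slab membership is judged at the earlier frame of each pair.  Ions that
    vanish before the next frame are skipped and counted in
    ``skipped_ions``.  With ``box_z`` set, displacements are minimum-imaged
    so box wrapping does not corrupt the sum.
    """
    if traj.n_frames < 2:
        raise ValueError("current needs at least two frames")
    dt = traj.delta_t
    F = traj.n_frames
    current = np.zeros(F - 1)
    skipped = 0
    for k in range(F - 1):
        ids0, q0, pos0 = traj.ids[k], traj.charges[k], traj.positions[k]
        next_z = dict(zip(traj.ids[k + 1].tolist(), traj.positions[k + 1][:, 2]))
        inside = _in_slab(traj, pos0[:, 2])
        total = 0.0
        for j in np.nonzero(inside)[0]:
            z1 = next_z.get(int(ids0[j]))
            if z1 is None:
                skipped += 1
                continue
            dz = z1 - pos0[j, 2]
            if traj.box_z:
                dz -= traj.box_z * np.round(dz / traj.box_z)
            total += q0[j] * dz
        current[k] = total / (dt * traj.lz)
    if skipped:
        warnings.warn(
            f"skipped {skipped} displacement terms whose ion vanished at the "
            "next frame", stacklevel=2,
        )
    return CurrentTrace(
        times=traj.times[:-1], current=current * E_PER_PS_IN_NA,
        delta_t=dt, skipped_ions=skipped,
    )


def lowpass(trace, spec: FilterSpec, delta_t_ps: float | None = None):
    """Zero-phase (forward-backward) Butterworth low pass.

    Accepts a :class:`CurrentTrace` (returns a new filtered trace) or a bare
    series with ``delta_t_ps`` supplied.  DC is preserved; the effective gain
    at the cutoff is 1/2 (two passes of a 1/sqrt(2) design).
    """
    if isinstance(trace, CurrentTrace):
        y = trace.current
        dt = trace.delta_t
    else:
        if delta_t_ps is None:
            raise ValueError("delta_t_ps required for a bare series")
        y = np.asarray(trace, dtype=float)
        dt = delta_t_ps
    nyquist_ghz = 1000.0 / (2.0 * dt)  # dt in ps
    if spec.cutoff_ghz >= nyquist_ghz:
        raise ValueError(
            f"cutoff {spec.cutoff_ghz} GHz >= Nyquist {nyquist_ghz} GHz"
        )
    if spec.kind != "butterworth":
        raise ValueError(f"unsupported filter kind {spec.kind!r}")
    sos = butter(spec.order, spec.cutoff_ghz / nyquist_ghz, output="sos")
    filtered = sosfiltfilt(sos, y)
    if isinstance(trace, CurrentTrace):
        return CurrentTrace(times=trace.times, current=filtered, delta_t=dt,
                            filter_applied=spec, skipped_ions=trace.skipped_ions)
    return filtered


def current_histogram(
    trace: CurrentTrace,
    bins=50,
    exclude_windows: list[tuple[float, float]] | None = None,
):
    """Histogram of current values; optional exclusion of time windows (ps).

    Windows are [t0, t1) intervals of trace time, e.g. unfolding episodes
    whose currents should not enter the histogram.
    """
    if len(trace.current) == 0:
        raise ValueError("empty current trace")
    mask = np.ones(len(trace.current), dtype=bool)
    for t0, t1 in exclude_windows or []:
        mask &= ~((trace.times >= t0) & (trace.times < t1))
    if not mask.any():
        raise ValueError("all frames excluded by the requested windows")
    counts, edges = np.histogram(trace.current[mask], bins=bins)
    return counts, edges


def dipole_conditioned_histograms(trace: CurrentTrace, dipole: DipoleTrace, bins=50):
    """Split the current histogram by dipole alignment with the field axis.

    Returns ``(counts_aligned, counts_anti, edges)`` on a shared binning.
    """
    if len(dipole.times) != len(trace.times) or not np.allclose(
            dipole.times, trace.times, rtol=1e-6, atol=1e-9):
        raise ValueError("dipole and current time axes are not aligned")
    flags = dipole.aligned
    edges = np.histogram_bin_edges(trace.current, bins=bins)
    counts_al, _ = np.histogram(trace.current[flags], bins=edges)
    counts_anti, _ = np.histogram(trace.current[~flags], bins=edges)
    return counts_al, counts_anti, edges


def com_track(times, masses, z, smooth_cutoff_ghz: float | None = None) -> np.ndarray:
    """Mass-weighted mean z per frame; optionally low-pass smoothed.

    ``z`` is (F, n_atoms) in Å, ``masses`` length n_atoms.  A smoothing
    cutoff (e.g. 1 GHz) applies the same zero-phase filter used for currents.
    """
    m = np.asarray(masses, dtype=float)
    zz = np.asarray(z, dtype=float)
    if m.sum() <= 0:
        raise ValueError("total mass must be positive")
    com = zz @ m / m.sum()
    if smooth_cutoff_ghz is not None:
        t = np.asarray(times, dtype=float)
        com = lowpass(com, FilterSpec(cutoff_ghz=smooth_cutoff_ghz),
                      delta_t_ps=float(t[1] - t[0]))
    return com
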
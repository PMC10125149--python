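"""Per-amino-acid pore-wall interaction energies from energy-vs-separation scans.

A scan of the total energy of one amino acid against a silicon nitride slab,
as a function of their separation, is reduced to a single interaction energy

    dE_AA = E_eq - E_asymp

where ``E_eq`` is the energy at the equilibrium separation (quadratic spline
interpolation through the sampled points, with a lowest-sampled-value fallback
when the interpolated vertex is not below the data) and ``E_asymp`` is the
large-separation plateau pinned by a Morse-potential fit

    V(s) = C + D * (1 - exp(-a (s - s0)))**2,   E_asymp = C + D.

Attractive residues give dE_AA < 0.  The packaged table of interaction
energies for 18 residue types (stored as positive magnitudes, negated on
load) is exposed through :class:`AAEnergyTable`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline, PPoly
from scipy.optimize import curve_fit

__all__ = [
    "EnergyCurve",
    "MorseFit",
    "AAEnergyTable",
    "MorseFitError",
    "fit_morse",
    "equilibrium_energy",
    "interaction_energy",
]


class MorseFitError(RuntimeError):
    """Morse fit failed to converge; carries the best residuals seen."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class EnergyCurve:
    """Total energy (eV) of one amino-acid / pore-wall system vs separation (Å)."""

    residue_code: str
    separations: np.ndarray
    energies: np.ndarray
    orientation_note: str = ""

    def __post_init__(self):
        s = np.asarray(self.separations, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        if s.ndim != 1 or s.shape != e.shape:
            raise ValueError("separations and energies must be 1-D and equal length")
        if len(s) < 2:
            raise ValueError("an energy curve needs at least two points")
        if not np.all(np.diff(s) > 0):
            raise ValueError("separations must be strictly increasing")
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(e))):
            raise ValueError("non-finite values in energy curve")
        object.__setattr__(self, "separations", s)
        object.__setattr__(self, "energies", e)

    def validate(self) -> None:
        """Enforce the full scan invariants (point count, asymptotic sampling)."""
        if len(self.separations) < 6:
            raise ValueError(
                f"{self.residue_code}: need >= 6 scan points, got {len(self.separations)}"
            )
        if self.separations[-1] <= 10.0:
            raise ValueError(
                f"{self.residue_code}: scan must sample beyond 10 Å separation "
                f"(last point at {self.separations[-1]:.2f} Å)"
            )

    @classmethod
    def from_tsv(cls, path: str | Path, residue_code: str | None = None) -> "EnergyCurve":
        """Read a ``separation_angstrom<TAB>energy_ev`` scan file.

        The residue code is taken from a ``# residue: XXX`` comment line if
        present, else from the filename stem's first three-letter token.
        """
        path = Path(path)
        code = residue_code
        note = ""
        seps, eners = [], []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*residue:\s*(\w{3})", line, re.IGNORECASE)
                if m:
                    code = m.group(1).upper()
                m = re.match(r"#\s*orientation:\s*(.+)", line, re.IGNORECASE)
                if m:
                    note = m.group(1)
                continue
            if line.lower().startswith("separation_angstrom"):
                continue
            a, b = line.split("\t")[:2]
            seps.append(float(a))
            eners.append(float(b))
        if code is None:
            m = re.search(r"([A-Za-z]{3})", path.stem)
            if m is None:
                raise ValueError(f"cannot infer residue code from {path.name}")
            code = m.group(1).upper()
        return cls(code, np.array(seps), np.array(eners), orientation_note=note)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        lines = [f"# residue: {self.residue_code}"]
        if self.orientation_note:
            lines.append(f"# orientation: {self.orientation_note}")
        lines.append("separation_angstrom\tenergy_ev")
        lines += [f"{s:.6g}\t{e:.10g}" for s, e in zip(self.separations, self.energies)]
        path.write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class MorseFit:
    """Least-squares Morse parameters; the asymptote ``C + D`` pins E_asymp."""

    D: float  # well depth, eV (> 0)
    a: float  # inverse width, 1/Å (> 0)
    s0: float  # equilibrium separation, Å
    C: float  # energy offset, eV
    rmse: float  # eV

    @property
    def asymptote(self) -> float:
        return self.C + self.D

    def __call__(self, s):
        return morse(np.asarray(s, dtype=float), self.D, self.a, self.s0, self.C)


def morse(s, D, a, s0, C):
    return C + D * (1.0 - np.exp(-a * (s - s0))) ** 2


def fit_morse(curve: EnergyCurve, max_restarts: int = 10) -> MorseFit:
    """Fit the Morse potential to all scan points by bounded least squares.

    Initial guesses come from the data (s0 at the sampled minimum, C at the
    minimum energy, D the plateau-minus-minimum, a = 1/Å) with a deterministic
    multi-start jitter on failure.
    """
    s, e = curve.separations, curve.energies
    if len(s) < 4:
        raise ValueError(
            f"{curve.residue_code}: Morse fit needs at least 4 points (free "
            f"parameters D, a, s0, C), got {len(s)}"
        )
    if s[-1] <= 10.0:
        warnings.warn(
            f"{curve.residue_code}: no scan point beyond 10 Å; "
            "asymptote is poorly constrained",
            stacklevel=2,
        )

    imin = int(np.argmin(e))
    plateau = float(e[-1])
    d0 = max(plateau - float(e[imin]), 1e-6)
    p0 = np.array([d0, 1.0, float(s[imin]), float(e[imin])])
    span = float(e.max() - e.min()) or 1.0
    lo = [1e-9, 1e-4, s[0] - 5.0, e.min() - 10.0 * span]
    hi = [np.inf, 50.0, s[-1] + 5.0, e.max() + 10.0 * span]

    rng = np.random.default_rng(20211228)
    best = None
    best_rmse = np.inf
    for attempt in range(max_restarts):
        if attempt == 0:
            guess = p0
        else:
            jitter = rng.normal(0.0, 0.2, size=4)
            guess = p0 * (1.0 + jitter)
            guess = np.clip(guess, lo, hi)
        try:
            popt, _ = curve_fit(morse, s, e, p0=guess, bounds=(lo, hi), maxfev=20000)
        except RuntimeError:
            continue
        rmse = float(np.sqrt(np.mean((morse(s, *popt) - e) ** 2)))
        if rmse < best_rmse:
            best, best_rmse = popt, rmse
        if rmse < 1e-3 * span:
            break
    if best is None:
        raise MorseFitError(
            f"{curve.residue_code}: Morse fit did not converge after "
            f"{max_restarts} restarts",
            residuals=e - morse(s, *p0),
        )
    D, a, s0, C = (float(v) for v in best)
    return MorseFit(D=D, a=a, s0=s0, C=C, rmse=best_rmse)


def equilibrium_energy(curve: EnergyCurve) -> tuple[float, float, str]:
    """Equilibrium separation and energy from quadratic spline interpolation.

    Returns ``(s_eq, E_eq, method)`` with ``method`` either ``"spline"``
    (interpolated stationary minimum) or ``"lowest_point"`` (fallback to the
    lowest sampled energy, used when the spline vertex does not undercut the
    data or the sampled minimum sits on the scan boundary).
    """
    s, e = curve.separations, curve.energies
    imin = int(np.argmin(e))
    lowest_s, lowest_e = float(s[imin]), float(e[imin])

    if imin in (0, len(s) - 1):
        warnings.warn(
            f"{curve.residue_code}: sampled minimum at scan boundary; "
            "using lowest computed value",
            stacklevel=2,
        )
        return lowest_s, lowest_e, "lowest_point"

    spline = InterpolatedUnivariateSpline(s, e, k=2)
    poly = PPoly.from_spline(spline._eval_args)
    roots = poly.derivative().roots(extrapolate=False)
    roots = np.unique(roots[np.isreal(roots)].real)
    roots = roots[(roots > s[0]) & (roots < s[-1])]
    if len(roots):
        vals = spline(roots)
        j = int(np.argmin(vals))
        s_eq, e_eq = float(roots[j]), float(vals[j])
        # require a genuine undercut: ties at rounding level are spurious
        tol = 1e-10 * max(float(e.max() - e.min()), 1.0)
        if e_eq < lowest_e - tol:
            return s_eq, e_eq, "spline"
    warnings.warn(
        f"{curve.residue_code}: spline minimum does not undercut the lowest "
        "sampled energy; using lowest computed value",
        stacklevel=2,
    )
    return lowest_s, lowest_e, "lowest_point"


def interaction_energy(curve: EnergyCurve) -> float:
    """dE_AA = E_eq - E_asymp (eV); negative when the residue is attracted.

    Invariant under a constant shift of all scan energies: both the spline
    minimum and the Morse asymptote shift by the same amount.
    """
    fit = fit_morse(curve)
    _, e_eq, _ = equilibrium_energy(curve)
    delta = e_eq - fit.asymptote
    if delta > 0:
        warnings.warn(
            f"{curve.residue_code}: repulsive interaction energy "
            f"({delta:+.4f} eV); attraction is expected for pore-wall scans",
            stacklevel=2,
        )
    return float(delta)


@dataclass
class AAEnergyTable:
    """Residue code -> signed interaction energy dE_AA (eV, <= 0 for attraction)."""

    entries: dict[str, float]
    provenance: str = ""
    r_group_class: dict[str, str] = field(default_factory=dict)

    def energy(self, code: str, substitutes: dict[str, str] | None = None) -> float:
        """Signed dE_AA for a 3-letter code; substitutes map absent codes."""
        code = code.upper()
        if code not in self.entries and substitutes and code in substitutes:
            code = substitutes[code].upper()
        if code not in self.entries:
            raise KeyError(
                f"residue {code!r} has no interaction energy in this table "
                "(supply a substitute mapping to reuse another residue's value)"
            )
        return self.entries[code]

    def __contains__(self, code: str) -> bool:
        return code.upper() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def default(cls) -> "AAEnergyTable":
        """The packaged 18-residue table (printed magnitudes negated on load)."""
        path = resources.files("porepass.data") / "aa_interaction_energies.tsv"
        return cls.from_tsv(path, provenance="packaged default")

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "AAEnergyTable":
        entries: dict[str, float] = {}
        classes: dict[str, str] = {}
        text = Path(path).read_text() if not hasattr(path, "read_text") else path.read_text()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("code"):
                continue
            parts = line.split("\t")
            code = parts[0].upper()
            entries[code] = -abs(float(parts[1]))
            if len(parts) > 2:
                classes[code] = parts[2]
        return cls(entries=entries, provenance=provenance or str(path), r_group_class=classes)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["code\tminus_delta_e_ev\tr_group_class"]
        for code, de in self.entries.items():
            lines.append(f"{code}\t{-de:.4f}\t{self.r_group_class.get(code, '')}")
        Path(path).write_text("\n".join(lines) + "\n")
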
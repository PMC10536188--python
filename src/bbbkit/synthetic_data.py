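"""Seeded generators for every input format the analysis modules consume.

Each generator is a pure function of its arguments (explicit integer seed
included): identical calls give byte-identical output.  Defaults mirror the
study conditions the rest of the package assumes — the three membrane-like
retention systems (log kw, s) of the lipophilicity study, the 40-compound /
sigma 0.436 structure of the logBB training data, the printed densitometric
calibration line, viability anchors for the MTT plate, and the 40-window
umbrella-sampling layout over a membrane-like double-minimum potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chromatography import RetentionMeasurement, RetentionSeries
from .free_energy import KT_310K, UmbrellaWindow
from .qsar import EQ2

# ---------------------------------------------------------------------------
# Packaged study-condition defaults

#: (logkw, s, phi grid) per membrane-like system, as reported for the
#: triterpenoid solute on each stationary phase.
TABLE2_SYSTEMS: dict[str, dict] = {
    "IAM": {"logkw": 1.656, "s": 1.515, "phis": (0.75, 0.80, 0.85, 0.90)},
    "CHOL": {"logkw": 2.361, "s": 2.037, "phis": (0.70, 0.75, 0.80, 0.85)},
    "ISRP": {"logkw": 0.637, "s": 1.853, "phis": (0.60, 0.65, 0.70, 0.75)},
}

#: Printed densitometric calibration line (peak area vs applied volume).
CALIBRATION_SLOPE = 12491.0
CALIBRATION_INTERCEPT = -12671.0

#: Printed MTT viability anchors: % viable at µg/mL after 48 h.
MTT_ANCHORS: tuple[tuple[float, float], ...] = (
    (100.0, 71.5), (300.0, 61.0), (1000.0, 43.0))

#: Default 4PL parameters of the MTT generator (bottom 0, top 100), from a
#: least-squares fit of the midpoint/Hill pair to the three printed anchors;
#: reproduces the anchors within 1.6 percentage points.
MTT_DEFAULT_IC50 = 620.0     # µg/mL, 50%-viability crossing
MTT_DEFAULT_HILL = 0.5299

#: Umbrella-sampling layout: 40 windows spanning -5..5 nm,
#: kappa = 1000 kJ mol^-1 nm^-2, at 310 K.
UMBRELLA_FORCE_CONSTANT = 1000.0
UMBRELLA_WINDOWS_DEFAULT = tuple(np.linspace(-5.0, 5.0, 40))

#: Densitometry applied-volume set, µL.
DENSITOMETRY_VOLUMES = (2.0, 4.0, 6.0, 8.0, 10.0)


# ---------------------------------------------------------------------------
# Retention tables

def gen_retention_table(logkw: float | None = None, s: float | None = None,
                        phis: Sequence[float] | None = None,
                        noise_sd: float = 0.01, seed: int = 0,
                        system: str = "IAM", t_dead: float = 1.0,
                        n_replicates: int = 3,
                        ) -> tuple[RetentionSeries, pd.DataFrame]:
    """Synthetic retention series: log k = logkw - s*phi + N(0, noise_sd).

    Noise is applied per replicate in log k space and converted back to a
    consistent retention time t_R = t0 * (1 + k).  Returns the
    replicate-averaged series plus the raw times table (columns system,
    phi, t_retention, t_dead, replicate).  Defaults to the packaged
    parameters of ``system``.
    """
    defaults = TABLE2_SYSTEMS.get(system, TABLE2_SYSTEMS["IAM"])
    logkw = defaults["logkw"] if logkw is None else logkw
    s = defaults["s"] if s is None else s
    phis = defaults["phis"] if phis is None else tuple(phis)
    if len(phis) == 0:
        raise ValueError("phis is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for phi in phis:
        for rep in range(n_replicates):
            logk = logkw - s * phi + rng.normal(scale=noise_sd) if noise_sd \
                else logkw - s * phi
            t_r = t_dead * (1.0 + 10.0 ** logk)
            rows.append({"system": system, "phi": phi, "t_retention": t_r,
                         "t_dead": t_dead, "replicate": rep})
    raw = pd.DataFrame(rows)
    measurements = [RetentionMeasurement(phi=r["phi"],
                                         t_retention=r["t_retention"],
                                         t_dead=r["t_dead"],
                                         replicate_id=r["replicate"])
                    for r in rows]
    return RetentionSeries.from_measurements(system, measurements), raw


# ---------------------------------------------------------------------------
# QSAR training tables

DEFAULT_DESCRIPTOR_RANGES: dict[str, tuple[float, float]] = {
    "delta_logp": (2.0, 10.0),
    "logkw": (0.0, 3.0),
    "E": (0.5, 2.5),
}


def gen_qsar_dataset(n: int = 40,
                     coefficients: Mapping[str, float] | None = None,
                     intercept: float | None = None,
                     sigma: float = 0.436,
                     descriptor_ranges: Mapping[str, tuple[float, float]] | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Training table with the linear logBB structure of the built-in model.

    Descriptors are uniform over ``descriptor_ranges``;
    logBB = intercept + sum(coef * descriptor) + N(0, sigma).  Defaults:
    n = 40 compounds, the published coefficient set, residual scale 0.436.
    """
    coefficients = dict(EQ2.coefficients if coefficients is None else coefficients)
    intercept = EQ2.intercept if intercept is None else intercept
    ranges = dict(DEFAULT_DESCRIPTOR_RANGES if descriptor_ranges is None
                  else descriptor_ranges)
    missing = [k for k in coefficients if k not in ranges]
    if missing:
        raise ValueError(f"no descriptor range for {missing}")
    for name, (lo, hi) in ranges.items():
        if not hi > lo:
            raise ValueError(f"degenerate range for {name!r}: ({lo}, {hi})")
    if n <= len(coefficients) + 1:
        raise ValueError(f"need n > p + 1 = {len(coefficients) + 1}, got {n}")
    rng = np.random.default_rng(seed)
    data = {name: rng.uniform(lo, hi, size=n)
            for name, (lo, hi) in ranges.items()}
    df = pd.DataFrame(data)
    y = intercept + sum(coef * df[name] for name, coef in coefficients.items())
    if sigma:
        y = y + rng.normal(scale=sigma, size=n)
    df["logBB"] = y
    return df


# ---------------------------------------------------------------------------
# Densitometry and MTT plates

def gen_densitometry(slope: float = CALIBRATION_SLOPE,
                     intercept: float = CALIBRATION_INTERCEPT,
                     amounts: Sequence[float] = DENSITOMETRY_VOLUMES,
                     noise_sd: float = 0.0, seed: int = 0,
                     n_replicates: int = 3) -> pd.DataFrame:
    """Densitometric lanes (lane, amount, peak_area) on a linear response."""
    if not len(amounts):
        raise ValueError("amounts is empty")
    rng = np.random.default_rng(seed)
    rows = []
    lane = 0
    for amount in amounts:
        for _ in range(n_replicates):
            area = slope * amount + intercept
            if noise_sd:
                area += rng.normal(scale=noise_sd)
            rows.append({"lane": lane, "amount": amount, "peak_area": area})
            lane += 1
    return pd.DataFrame(rows)


def gen_mtt_plate(ic50: float = MTT_DEFAULT_IC50, hill: float = MTT_DEFAULT_HILL,
                  doses: Sequence[float] = (100, 200, 300, 400, 500, 600,
                                            700, 800, 900, 1000),
                  noise_sd: float = 0.0, seed: int = 0,
                  od_control: float = 0.9, od_blank: float = 0.08,
                  n_replicates: int = 4) -> pd.DataFrame:
    """Microplate table (well, dose, od) with 4PL viabilities plus OD noise.

    Viability follows 100 / (1 + (dose/ic50)^hill); default parameters are
    the packaged anchor fit, so generated viabilities at 100/300/1000 µg/mL
    fall within ~1.6 percentage points of the 71.5/61/43 % anchors.
    Control and blank wells are emitted alongside treated wells.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        rows.append({"well": f"control_{rep}", "dose": 0.0,
                     "od": od_control + (rng.normal(scale=noise_sd)
                                         if noise_sd else 0.0)})
        rows.append({"well": f"blank_{rep}", "dose": 0.0,
                     "od": od_blank + (rng.normal(scale=noise_sd)
                                       if noise_sd else 0.0)})
    for i, dose in enumerate(doses):
        viability = 100.0 / (1.0 + (dose / ic50) ** hill)
        od_true = od_blank + (od_control - od_blank) * viability / 100.0
        for rep in range(n_replicates):
            od = od_true + (rng.normal(scale=noise_sd) if noise_sd else 0.0)
            rows.append({"well": f"d{i}_{rep}", "dose": float(dose), "od": od})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Umbrella-sampling trajectories

@dataclass(frozen=True)
class MembranePotential:
    """Symmetric membrane-like 1D potential (kJ/mol, coordinate nm).

    Two Gaussian wells at +-``well_position`` of depth ``well_depth`` below
    bulk, separated by a central hump ``central_barrier`` above the wells;
    flat (0) in bulk water.  Defaults shape a phosphatidylcholine-like
    profile: 43 kJ/mol wells with a 13 kJ/mol central hump.
    """

    well_depth: float = 43.0
    central_barrier: float = 13.0
    well_position: float = 1.5
    well_width: float = 0.5
    barrier_width: float = 0.6

    def _amplitudes(self) -> tuple[float, float]:
        # solve the 2x2 linear system pinning U(well_position) = -depth and
        # U(0) = -(depth - barrier); U is linear in the two amplitudes
        x0, sw, sc = self.well_position, self.well_width, self.barrier_width
        g = lambda d, s: math.exp(-d * d / (2 * s * s))
        # U = aw * W + ah * H with W the two-well Gaussian sum, H the hump
        a11 = 1.0 + g(2 * x0, sw)              # W at x0
        a12 = g(x0, sc)                        # H at x0
        a21 = 2.0 * g(x0, sw)                  # W at 0
        a22 = 1.0
        b1 = -self.well_depth
        b2 = -(self.well_depth - self.central_barrier)
        det = a11 * a22 - a12 * a21
        amp_well = (b1 * a22 - a12 * b2) / det
        amp_hump = (a11 * b2 - b1 * a21) / det
        return amp_well, amp_hump

    def __call__(self, xi) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        aw, ah = self._amplitudes()
        x0, sw, sc = self.well_position, self.well_width, self.barrier_width
        wells = (np.exp(-(xi - x0) ** 2 / (2 * sw * sw))
                 + np.exp(-(xi + x0) ** 2 / (2 * sw * sw)))
        hump = np.exp(-xi ** 2 / (2 * sc * sc))
        return aw * wells + ah * hump


def double_well(barrier: float = 6.0, well_position: float = 1.0) -> Callable:
    """Quartic double well U = barrier * ((xi/x0)^2 - 1)^2 (kJ/mol)."""
    def u(xi):
        xi = np.asarray(xi, dtype=float)
        return barrier * ((xi / well_position) ** 2 - 1.0) ** 2
    return u


def harmonic(kappa: float, center: float = 0.0) -> Callable:
    def u(xi):
        xi = np.asarray(xi, dtype=float)
        return 0.5 * kappa * (xi - center) ** 2
    return u


def flat() -> Callable:
    return lambda xi: np.zeros_like(np.asarray(xi, dtype=float))


def sample_umbrella(potential: Callable, window_centers: Sequence[float],
                    force_constant: float = UMBRELLA_FORCE_CONSTANT,
                    n_steps: int = 10_000, seed: int = 0,
                    kT: float = KT_310K, step_size: float | None = None,
                    bounds: tuple[float, float] | None = None,
                    ) -> list[UmbrellaWindow]:
    """Metropolis Monte Carlo sampling of each biased window.

    Each window runs an independent chain in U(xi) + kappa/2 (xi - c)^2,
    started at the window centre, with Gaussian proposals.  The default
    proposal width is ~2 sd of the biased well (sqrt(kT/kappa)), which
    keeps acceptance near 50%.  ``bounds`` confines the chain to an
    interval (proposals outside are rejected), turning an unbiased flat
    potential into uniform sampling.  An acceptance rate below 1% in any
    window raises with advice to change the step size.  Chains are
    returned raw; equilibration discard is the consumer's job.
    """
    if n_steps < 1000:
        raise ValueError("n_steps must be >= 1000 for meaningful histograms")
    if step_size is None:
        step_size = (2.0 * math.sqrt(kT / force_constant)
                     if force_constant > 0 else 0.5)
    rng = np.random.default_rng(seed)
    windows = []
    for center in window_centers:
        proposals = rng.normal(scale=step_size, size=n_steps)
        uniforms = rng.random(n_steps)
        samples = np.empty(n_steps)
        x = float(center)
        if bounds is not None:
            x = float(np.clip(x, *bounds))

        def energy(pos):
            bias = 0.5 * force_constant * (pos - center) ** 2
            return float(potential(pos)) + bias

        e = energy(x)
        accepted = 0
        for i in range(n_steps):
            x_new = x + proposals[i]
            if bounds is not None and not bounds[0] <= x_new <= bounds[1]:
                samples[i] = x
                continue
            e_new = energy(x_new)
            if e_new <= e or uniforms[i] < math.exp(-(e_new - e) / kT):
                x, e = x_new, e_new
                accepted += 1
            samples[i] = x
        rate = accepted / n_steps
        if rate < 0.01:
            raise ValueError(
                f"acceptance rate {rate:.3%} in window {center}: decrease "
                "step_size (or check the potential scale)")
        windows.append(UmbrellaWindow(center=center,
                                      force_constant=force_constant,
                                      samples=samples))
    return windows


def write_window_files(windows: Sequence[UmbrellaWindow], directory,
                       prefix: str = "win") -> str:
    """Write xvg-like window files plus a WHAM metadata file; returns the
    metadata path."""
    import os

    os.makedirs(directory, exist_ok=True)
    meta_lines = []
    for i, w in enumerate(windows):
        fname = f"{prefix}{i:03d}.dat"
        with open(os.path.join(directory, fname), "w") as fh:
            fh.write("# time_ps xi_nm\n")
            for t, xi in enumerate(w.samples):
                fh.write(f"{t} {xi:.6f}\n")
        meta_lines.append(f"{fname} {w.center} {w.force_constant}")
    meta_path = os.path.join(directory, "meta.txt")
    with open(meta_path, "w") as fh:
        fh.write("\n".join(meta_lines) + "\n")
    return meta_path


# ---------------------------------------------------------------------------
# Toy ligand-protein complexes (PDB text)

_RING_TEMPLATES: dict[str, tuple[tuple[str, str], ...]] = {
    # (atom name, element) in ring order; hexagon/pentagon built on the fly
    "PHE": (("CG", "C"), ("CD1", "C"), ("CE1", "C"), ("CZ", "C"),
            ("CE2", "C"), ("CD2", "C")),
    "TYR": (("CG", "C"), ("CD1", "C"), ("CE1", "C"), ("CZ", "C"),
            ("CE2", "C"), ("CD2", "C")),
    "TRP": (("CD2", "C"), ("CE2", "C"), ("CZ2", "C"), ("CH2", "C"),
            ("CZ3", "C"), ("CE3", "C")),
    "HIS": (("CG", "C"), ("ND1", "N"), ("CE1", "C"), ("NE2", "N"),
            ("CD2", "C")),
}

_AROMATIC_RING_RADIUS = 0.139  # nm, benzene-like
_IMIDAZOLE_RING_RADIUS = 0.115  # nm


def _basis_from_normal(normal) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _place_residue(resname: str, center, normal) -> list[tuple[str, str, np.ndarray]]:
    """Atoms (name, element, xyz nm) of one residue template.

    Ring residues get a planar ring perpendicular to ``normal`` centred at
    ``center``; SER exposes its OG hydroxyl at ``center``; GLY its backbone
    N at ``center`` (both with the rest of the backbone trailing away along
    ``normal``).
    """
    center = np.asarray(center, dtype=float)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    if resname in _RING_TEMPLATES:
        atoms = _RING_TEMPLATES[resname]
        radius = (_IMIDAZOLE_RING_RADIUS if resname == "HIS"
                  else _AROMATIC_RING_RADIUS)
        u, v = _basis_from_normal(n)
        placed = []
        for i, (name, element) in enumerate(atoms):
            angle = 2.0 * math.pi * i / len(atoms)
            xyz = center + radius * (math.cos(angle) * u + math.sin(angle) * v)
            placed.append((name, element, xyz))
        return placed
    if resname == "SER":
        return [("OG", "O", center),
                ("CB", "C", center + 0.143 * n),
                ("CA", "C", center + 0.295 * n),
                ("N", "N", center + 0.39 * n + 0.12 * _basis_from_normal(n)[0])]
    if resname == "GLY":
        return [("N", "N", center),
                ("CA", "C", center + 0.146 * n),
                ("C", "C", center + 0.30 * n),
                ("O", "O", center + 0.36 * n + 0.1 * _basis_from_normal(n)[0])]
    raise ValueError(f"no template for residue {resname!r}")


def _ligand_atoms(center, with_hydroxyl: bool = True
                  ) -> list[tuple[str, str, np.ndarray]]:
    """Aliphatic six-carbon ring ligand, optionally with a hydroxyl oxygen
    bonded to C1 (making C1 polar-bonded)."""
    center = np.asarray(center, dtype=float)
    atoms = []
    radius = 0.15
    for i in range(6):
        angle = 2.0 * math.pi * i / 6
        xyz = center + radius * np.array([math.cos(angle), math.sin(angle), 0.0])
        atoms.append((f"C{i + 1}", "C", xyz))
    if with_hydroxyl:
        c1 = atoms[0][2]
        direction = c1 - center
        direction /= np.linalg.norm(direction)
        atoms.append(("O1", "O", c1 + 0.143 * direction))
    return atoms


def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resseq: int, xyz_nm: np.ndarray, element: str) -> str:
    x, y, z = (float(c) * 10.0 for c in xyz_nm)  # nm -> Angstrom
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"{record:<6s}{serial:>5d} {name_field} {resname:<3s} {chain}"
            f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


def default_cage_spec(n_aromatic: int = 6, cage_radius: float = 0.45,
                      with_polar_probe: bool = True) -> dict:
    """Aromatic cage around an aliphatic ligand, qualitatively mirroring a
    triterpenoid core buried in an acetylcholinesterase-like aromatic
    cluster, plus an optional serine hydroxyl probe near the ligand oxygen.
    """
    resnames = ["PHE", "TYR", "TRP", "PHE", "HIS", "PHE"][:n_aromatic]
    residues = []
    for i, resname in enumerate(resnames):
        theta = math.acos(1 - 2 * (i + 0.5) / n_aromatic)
        phi_ang = math.pi * (1 + 5 ** 0.5) * (i + 0.5)
        direction = np.array([math.sin(theta) * math.cos(phi_ang),
                              math.sin(theta) * math.sin(phi_ang),
                              math.cos(theta)])
        residues.append({"resname": resname, "chain": "A", "resseq": 100 + i,
                         "center": (cage_radius * direction).tolist(),
                         "normal": direction.tolist()})
    if with_polar_probe:
        # OG placed 0.30 nm beyond the ligand O1 (which sits at ~0.293 nm
        # from the ligand centre along +x)
        residues.append({"resname": "SER", "chain": "A", "resseq": 200,
                         "center": [0.293 + 0.30, 0.0, 0.0],
                         "normal": [1.0, 0.0, 0.0]})
    return {"ligand": {"resname": "OLA", "chain": "L", "resseq": 1,
                       "center": [0.0, 0.0, 0.0], "with_hydroxyl": True},
            "residues": residues}


def probe_pair_spec(distance_nm: float, ligand_element: str = "C",
                    residue: str = "GLY") -> dict:
    """Minimal two-body fixture: a one-heavy-atom ligand at the origin and a
    residue whose nearest template atom sits exactly ``distance_nm`` away."""
    return {"ligand": {"resname": "OLA", "chain": "L", "resseq": 1,
                       "center": [0.0, 0.0, 0.0], "single_atom": True,
                       "element": ligand_element},
            "residues": [{"resname": residue, "chain": "A", "resseq": 10,
                          "center": [distance_nm, 0.0, 0.0],
                          "normal": [1.0, 0.0, 0.0]}]}


def gen_toy_complex(geometry_spec: Mapping | None = None) -> str:
    """Emit PDB text for a toy ligand-protein complex.

    ``geometry_spec`` follows :func:`default_cage_spec`'s layout: a ligand
    record plus residue placements (resname, chain, resseq, center nm,
    normal).  Raises if any two atoms end up closer than 0.05 nm.
    """
    spec = default_cage_spec() if geometry_spec is None else geometry_spec
    lig = spec["ligand"]
    lig_center = np.asarray(lig.get("center", (0, 0, 0)), dtype=float)
    if lig.get("single_atom"):
        lig_atoms = [("X1", lig.get("element", "C"), lig_center)]
    else:
        lig_atoms = _ligand_atoms(lig_center, lig.get("with_hydroxyl", True))

    lines = []
    serial = 1
    all_xyz = []
    for name, element, xyz in lig_atoms:
        lines.append(_pdb_line("HETATM", serial, name, lig.get("resname", "OLA"),
                               lig.get("chain", "L"), lig.get("resseq", 1),
                               xyz, element))
        all_xyz.append(xyz)
        serial += 1
    for res in spec.get("residues", []):
        for name, element, xyz in _place_residue(res["resname"], res["center"],
                                                 res["normal"]):
            lines.append(_pdb_line("ATOM", serial, name, res["resname"],
                                   res["chain"], res["resseq"], xyz, element))
            all_xyz.append(xyz)
            serial += 1
    coords = np.array(all_xyz)
    diff = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    np.fill_diagonal(diff, np.inf)
    if diff.min() < 0.05:
        raise ValueError(f"overlapping atoms: min pair distance "
                         f"{diff.min():.4f} nm < 0.05 nm")
    lines.append("END")
    return "\n".join(lines) + "\n"
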
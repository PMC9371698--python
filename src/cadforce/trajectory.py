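"""MD/SMD trajectory statistics for protein–protein interfaces.

Implements the analyses used to characterise cadherin dimer mechanics:
optimal rigid-body superposition (Kabsch), per-residue α-carbon RMSF over an
equilibrated window, charged-atom minimum-distance traces with the
salt-bridge median criterion (formed when the median distance over frames is
strictly below 4.0 Å), Shrake–Rupley solvent-accessible surface area and the
buried interface area ΔSASA = SASA(A) + SASA(B) − SASA(A∪B), dimer
rupture-frame detection (first frame where ΔSASA decays to zero), and
centre-of-mass distances such as Trp2 to its hydrophobic docking pocket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .constants import CHARGED_ATOMS
from .structures import Selection, Structure, Trajectory, concatenate

logger = logging.getLogger(__name__)

__all__ = [
    "SaltBridgeTrace",
    "SASAResult",
    "kabsch_superpose",
    "backbone_rmsd",
    "rmsf",
    "min_pair_distance_trace",
    "salt_bridge_formed",
    "salt_bridge_trace",
    "shrake_rupley_sasa",
    "delta_sasa",
    "delta_sasa_trace",
    "rupture_frame",
    "com_distance",
    "rmsd_timeseries",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Salt-bridge distance criterion (Å): formed iff median distance < cutoff.
SALT_BRIDGE_CUTOFF = 4.0


@dataclass
class SaltBridgeTrace:
    """Per-frame charged-atom minimum distance and its median verdict."""

    label: str
    distances: np.ndarray  # Å, per frame
    median: float
    formed: bool

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)


class SASAResult(NamedTuple):
    per_atom: np.ndarray  # Å² per atom
    total: float  # Å²


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rigid-body superposition of two point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the (weighted) RMSD to
    ``reference``.  The rotation is proper (det = +1); reflections are
    corrected by flipping the smallest singular vector.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    a = mobile - mc
    b = reference - rc
    h = (w[:, None] * a).T @ b
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = a @ rot.T
    rmsd = float(np.sqrt((w[:, None] * (moved - b) ** 2).sum()))
    trans = rc - mc @ rot.T
    return rot, trans, rmsd


def backbone_rmsd(
    a: Structure,
    b: Structure,
    selection: Selection | str | None = None,
) -> float:
    """Backbone RMSD (Å) between two structures after superposition.

    Backbone atoms (N, CA, C, O), optionally restricted by ``selection``
    applied to both structures, are matched 1:1 by (residue number, atom
    name); unmatched atoms are dropped and their counts logged.
    """
    def backbone_map(s: Structure) -> dict[tuple[int, str], np.ndarray]:
        idx = np.flatnonzero(np.isin(s.atom_name, BACKBONE_ATOMS))
        if selection is not None:
            idx = np.intersect1d(idx, s.select(selection))
        return {
            (int(s.res_id[i]), str(s.atom_name[i])): s.coords[i] for i in idx
        }

    ma, mb = backbone_map(a), backbone_map(b)
    common = sorted(set(ma) & set(mb))
    dropped = (len(ma) - len(common)) + (len(mb) - len(common))
    if dropped:
        logger.info(
            "backbone_rmsd: matched %d atom pairs, dropped %d unmatched",
            len(common),
            dropped,
        )
    if len(common) < 3:
        raise ValueError(f"only {len(common)} matched backbone atoms (need >= 3)")
    pa = np.array([ma[k] for k in common])
    pb = np.array([mb[k] for k in common])
    _, _, rmsd = kabsch_superpose(pa, pb)
    return rmsd


def _window_frames(traj: Trajectory, window: tuple[int, int] | None) -> np.ndarray:
    if window is None:
        # default analysis window: the final sixth of the trajectory,
        # mirroring "final 10 ns of 60 ns" equilibrated-statistics practice
        start = traj.n_frames - max(2, traj.n_frames // 6)
        window = (start, traj.n_frames - 1)
    lo, hi = window
    if not (0 <= lo <= hi < traj.n_frames):
        raise ValueError(f"window {window} outside trajectory of {traj.n_frames}")
    return traj.frames[lo : hi + 1]


def rmsf(
    traj: Trajectory,
    selection: Selection | str | None = None,
    window: tuple[int, int] | None = None,
):
    """Per-residue RMSF (Å) of selected atoms over an analysis window.

    Frames are superposed onto their mean coordinates, iterating
    superpose → re-average until the mean structure converges, then
    RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩) — the SD of each atom's position.
    Default selection: α-carbons of residues 1–100; default window: the
    final sixth of the frames.  Returns a pandas Series indexed by residue
    number (mean over selected atoms per residue).
    """
    import pandas as pd

    if selection is None:
        selection = Selection(residue_ranges=[(1, 100)], atom_names=("CA",))
    idx = traj.topology.select(selection)
    frames = _window_frames(traj, window)
    if frames.shape[0] < 2:
        raise ValueError("RMSF needs at least 2 frames in the window")
    coords = frames[:, idx, :]
    ref = coords.mean(axis=0)
    for _ in range(20 if len(idx) >= 3 else 0):  # <3 atoms: no superposition
        aligned = np.empty_like(coords)
        for f in range(coords.shape[0]):
            rot, trans, _ = kabsch_superpose(coords[f], ref)
            aligned[f] = coords[f] @ rot.T + trans
        coords = aligned
        new_ref = coords.mean(axis=0)
        shift = float(np.abs(new_ref - ref).max())
        ref = new_ref
        if shift < 1e-10:
            break
    fluct = np.sqrt(((coords - ref) ** 2).sum(axis=2).mean(axis=0))
    res = traj.topology.res_id[idx]
    return pd.Series(fluct, index=res, name="rmsf_A").groupby(level=0).mean()


def min_pair_distance_trace(
    traj: Trajectory,
    group_a: Selection | str | np.ndarray,
    group_b: Selection | str | np.ndarray,
) -> np.ndarray:
    """Per-frame minimum distance (Å) over all A×B atom pairs.

    The groups must be disjoint atom sets.
    """
    ia = group_a if isinstance(group_a, np.ndarray) else traj.topology.select(group_a)
    ib = group_b if isinstance(group_b, np.ndarray) else traj.topology.select(group_b)
    if len(np.intersect1d(ia, ib)):
        raise ValueError("groups must be disjoint")
    a = traj.frames[:, ia, :]
    b = traj.frames[:, ib, :]
    diff = a[:, :, None, :] - b[:, None, :, :]
    dist = np.sqrt((diff**2).sum(axis=3))
    return dist.reshape(traj.n_frames, -1).min(axis=1)


def salt_bridge_formed(
    trace: np.ndarray,
    cutoff: float = SALT_BRIDGE_CUTOFF,
    label: str = "",
) -> SaltBridgeTrace:
    """Median-distance salt-bridge verdict over a per-frame distance trace.

    Formed iff median(distance) < cutoff, strictly: a median of exactly
    4.0 Å is *not* formed.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 1:
        raise ValueError("trace must contain at least one frame")
    median = float(np.median(trace))
    return SaltBridgeTrace(
        label=label, distances=trace, median=median, formed=median < cutoff
    )


def salt_bridge_trace(
    traj: Trajectory,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    cutoff: float = SALT_BRIDGE_CUTOFF,
    charged_atoms: dict[str, tuple[str, ...]] | None = None,
) -> SaltBridgeTrace:
    """Charged-atom minimum-distance trace between two residues.

    ``res_a``/``res_b`` are ``(chain_id, residue_number)``.  Charged atoms
    are selected from the residue's side chain via the ``charged_atoms``
    table (default: carboxylate oxygens of Glu/Asp, amine nitrogen of Lys,
    guanidinium nitrogens of Arg).
    """
    table = charged_atoms or CHARGED_ATOMS
    top = traj.topology

    def charged_indices(chain: str, resid: int) -> np.ndarray:
        mask = (top.chain_id == chain) & (top.res_id == resid)
        if not mask.any():
            raise ValueError(f"residue {chain}/{resid} not found")
        res_name = top.res_name[mask][0].upper()
        if res_name not in table:
            raise ValueError(
                f"residue {chain}/{resid} ({res_name}) has no charged atoms "
                "in the lookup table"
            )
        idx = np.flatnonzero(mask & np.isin(top.atom_name, table[res_name]))
        if len(idx) == 0:
            raise ValueError(
                f"no charged atoms {table[res_name]} present in {chain}/{resid}"
            )
        return idx

    ia = charged_indices(*res_a)
    ib = charged_indices(*res_b)
    trace = min_pair_distance_trace(traj, ia, ib)
    label = f"{res_a[0]}{res_a[1]}-{res_b[0]}{res_b[1]}"
    return salt_bridge_formed(trace, cutoff=cutoff, label=label)


def _golden_spiral(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(
    s: Structure, probe: float = 1.4, n_points: int = 960
) -> SASAResult:
    """Shrake–Rupley solvent-accessible surface area (Å²).

    Each atom's sphere is expanded by the probe radius and covered with
    ``n_points`` golden-spiral test points; the accessible fraction (points
    not inside any neighbour's expanded sphere) times 4π(r+probe)² gives the
    per-atom area.
    """
    if n_points < 92:
        raise ValueError("n_points must be at least 92")
    if np.any(~np.isfinite(s.radius)) or np.any(s.radius <= 0):
        bad = int(np.flatnonzero(~np.isfinite(s.radius) | (s.radius <= 0))[0])
        raise ValueError(
            f"missing/invalid vdW radius for atom "
            f"{s.chain_id[bad]}/{s.res_id[bad]}/{s.atom_name[bad]} "
            f"(element {s.element[bad]!r})"
        )
    sphere = _golden_spiral(n_points)
    radii = s.radius + probe
    tree = cKDTree(s.coords)
    max_r = radii.max()
    per_atom = np.empty(s.n_atoms)
    for i in range(s.n_atoms):
        pts = s.coords[i] + radii[i] * sphere
        neighbours = tree.query_ball_point(s.coords[i], radii[i] + max_r)
        neighbours = [j for j in neighbours if j != i]
        if neighbours:
            nb = np.asarray(neighbours)
            d2 = ((pts[:, None, :] - s.coords[nb][None, :, :]) ** 2).sum(axis=2)
            r2 = (radii[nb] ** 2)[None, :]
            # strictly inside buries; exact-boundary points (coincident
            # spheres) are assigned to the lower-indexed atom only
            tie = np.abs(d2 - r2) <= 1e-9 * r2
            buried = ((d2 < r2 - 1e-9 * r2) | (tie & (nb < i)[None, :])).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return SASAResult(per_atom=per_atom, total=float(per_atom.sum()))


def delta_sasa(
    a: Structure, b: Structure, probe: float = 1.4, n_points: int = 960
) -> float:
    """Buried interface area ΔSASA = SASA(A) + SASA(B) − SASA(A∪B), Å².

    Non-negative up to quadrature tolerance; zero for contact-free bodies.
    The two bodies must have disjoint (chain, residue, atom-name) identifiers.
    """
    if set(a.atom_keys()) & set(b.atom_keys()):
        raise ValueError("bodies share atom identifiers; they must be disjoint")
    sasa_a = shrake_rupley_sasa(a, probe, n_points).total
    sasa_b = shrake_rupley_sasa(b, probe, n_points).total
    sasa_ab = shrake_rupley_sasa(concatenate([a, b]), probe, n_points).total
    return sasa_a + sasa_b - sasa_ab


def delta_sasa_trace(
    traj: Trajectory,
    group_a: Selection | str | np.ndarray,
    group_b: Selection | str | np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-frame ΔSASA (Å²) between two atom groups of a trajectory."""
    top = traj.topology
    ia = group_a if isinstance(group_a, np.ndarray) else top.select(group_a)
    ib = group_b if isinstance(group_b, np.ndarray) else top.select(group_b)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        sa = top.subset(ia)
        sb = top.subset(ib)
        sa.coords = traj.frames[f, ia, :]
        sb.coords = traj.frames[f, ib, :]
        out[f] = delta_sasa(sa, sb, probe, n_points)
    return out


def rupture_frame(trace: np.ndarray, tolerance: float = 1.0) -> int | None:
    """First frame (1-based) where ΔSASA ≤ tolerance, or None if never.

    The default 1 Å² tolerance absorbs the quadrature noise floor of the
    surface-area estimate.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 1:
        raise ValueError("trace must contain at least one frame")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    hits = np.flatnonzero(trace <= tolerance)
    return int(hits[0]) + 1 if len(hits) else None


def com_distance(
    traj: Trajectory,
    sel_a: Selection | str | np.ndarray,
    sel_b: Selection | str | np.ndarray,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame distance (Å) between the centres of mass of two groups."""
    top = traj.topology
    ia = sel_a if isinstance(sel_a, np.ndarray) else top.select(sel_a)
    ib = sel_b if isinstance(sel_b, np.ndarray) else top.select(sel_b)
    if mass_weighted:
        masses = top.masses()
        wa, wb = masses[ia], masses[ib]
    else:
        wa = np.ones(len(ia))
        wb = np.ones(len(ib))
    coma = (traj.frames[:, ia, :] * wa[None, :, None]).sum(axis=1) / wa.sum()
    comb = (traj.frames[:, ib, :] * wb[None, :, None]).sum(axis=1) / wb.sum()
    return np.sqrt(((coma - comb) ** 2).sum(axis=1))


def rmsd_timeseries(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: Selection | str | None = None,
) -> np.ndarray:
    """Per-frame superposed RMSD (Å) against a reference frame.

    Default selection: backbone atoms (N, CA, C, O) when present, else all
    atoms.
    """
    if not (0 <= reference_frame < traj.n_frames):
        raise ValueError("reference frame outside trajectory")
    if selection is None:
        mask = np.isin(traj.topology.atom_name, BACKBONE_ATOMS)
        idx = np.flatnonzero(mask) if mask.any() else np.arange(traj.topology.n_atoms)
    else:
        idx = traj.topology.select(selection)
    ref = traj.frames[reference_frame, idx, :]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = kabsch_superpose(traj.frames[f, idx, :], ref)
    return out
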
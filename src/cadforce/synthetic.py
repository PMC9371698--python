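"""Synthetic-data generators with known ground truth.

Every downstream stage of the package has a recovery test driven by these
generators: AFM retract curves with a PEG-tether WLC stretch terminated by a
rupture drawn from a 1- or 2-component Gaussian mixture (optionally
contaminated with short-tether or high-noise events that the acceptance
filters must reject), fluctuation trajectories with prescribed per-residue
amplitudes, positive distance traces with a prescribed median, and
rigid-body dimer-separation trajectories whose interface area first reaches
zero at a chosen frame.

The module-level ``STUDY_CONDITIONS`` table holds the rupture-force
distributions of the five experimental conditions of the cadherin/19A11
study (wild type and K14E mutant, with and without antibody).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K
from .force_spectroscopy import (
    ForceCurve,
    wlc_extension_at_force,
    wlc_force,
)
from .structures import Structure, Trajectory, concatenate

__all__ = [
    "RuptureForceModel",
    "CurveGenSpec",
    "FluctuationSpec",
    "SyntheticCurveSet",
    "STUDY_CONDITIONS",
    "sample_rupture_forces",
    "generate_force_curve",
    "generate_curve_set",
    "generate_fluctuation_trajectory",
    "generate_distance_trace",
    "generate_separating_dimer",
]


@dataclass
class RuptureForceModel:
    """A 1+ component Gaussian mixture of rupture forces (pN).

    ``components`` is a list of ``(weight, mean, sd)`` tuples; weights must
    sum to 1 and SDs must be non-negative (zero SD gives a point mass).
    """

    components: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("model needs at least one component")
        w = np.array([c[0] for c in self.components], dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if any(c[2] < 0 for c in self.components):
            raise ValueError("component sds must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])

    def mean(self) -> float:
        """Analytic mixture mean (pN)."""
        return float((self.weights * self.means).sum())


#: Rupture-force distributions of the five experimental conditions
#: (peak forces ± SD in pN; the two-component conditions put 40% of the
#: weight on the strengthened, higher-force population).
STUDY_CONDITIONS: dict[str, RuptureForceModel] = {
    "wt_no_ab": RuptureForceModel([(1.0, 49.4, 12.0)]),
    "wt_ab_20nM": RuptureForceModel([(0.6, 48.6, 17.3), (0.4, 73.1, 27.5)]),
    "wt_ab_150nM": RuptureForceModel([(0.6, 51.7, 14.5), (0.4, 69.6, 25.5)]),
    "k14e_no_ab": RuptureForceModel([(1.0, 41.2, 17.3)]),
    "k14e_ab_150nM": RuptureForceModel([(1.0, 40.3, 24.1)]),
}


@dataclass
class CurveGenSpec:
    """Instrument and tether parameters for synthetic force curves.

    Defaults emulate a soft-cantilever AFM pulling a PEG tether at 1 µm/s:
    spring constant 80 pN/nm, 10 samples per nm of piezo travel, 5 pN force
    noise, persistence length 0.38 nm and contour length 40 nm.
    """

    spring_constant: float = 80.0  # pN/nm
    velocity: float = 1.0  # µm/s
    sampling_rate: float = 10.0  # points per nm
    noise_sd: float = 5.0  # pN
    temperature: float = DEFAULT_TEMPERATURE_K
    tether_Lp: float = 0.38  # nm
    tether_Lc: float = 40.0  # nm
    contaminant_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "spring_constant",
            "velocity",
            "sampling_rate",
            "temperature",
            "tether_Lp",
            "tether_Lc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            raise ValueError("contaminant_fraction must lie in [0, 1]")


@dataclass
class FluctuationSpec:
    """Prescription for a synthetic equilibrium-fluctuation trajectory.

    ``per_residue_sd`` maps residue numbers to per-axis displacement SDs in
    nm; unlisted residues are static.
    """

    reference: Structure
    per_residue_sd: dict[int, float]
    n_frames: int = 1000
    timestep: float = 1.0  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if any(sd < 0 for sd in self.per_residue_sd.values()):
            raise ValueError("per-residue sds must be non-negative")
        present = set(self.reference.res_id.tolist())
        missing = set(self.per_residue_sd) - present
        if missing:
            raise ValueError(
                f"residues {sorted(missing)} not present in reference structure"
            )


def sample_rupture_forces(
    model: RuptureForceModel,
    n: int,
    seed: int | None = None,
    truncate_negative: bool = False,
) -> np.ndarray:
    """Draw ``n`` rupture forces (pN) from a Gaussian mixture.

    Reproducible for a fixed seed.  With ``truncate_negative`` the rare
    negative draws are redrawn from their component; the default leaves the
    mixture untruncated so that the drawn sample follows exactly the
    Gaussian-mixture model that the recovery analyses fit (at the study
    parameters fewer than 0.5% of draws are negative either way).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(model.components), size=n, p=model.weights)
    mu = model.means[comp]
    sd = model.sds[comp]
    x = rng.normal(mu, sd)
    if truncate_negative:
        bad = x < 0
        while bad.any():
            x[bad] = rng.normal(mu[bad], sd[bad])
            bad = x < 0
    return x


def generate_force_curve(
    rupture_force: float,
    spec: CurveGenSpec,
    rng: np.random.Generator | None = None,
    tether_Lp: float | None = None,
    tether_Lc: float | None = None,
    noise_sd: float | None = None,
) -> ForceCurve:
    """Construct one approach/retract cycle with a single unbinding event.

    The retract force follows the tether's WLC force–extension relation
    (deflection-corrected: piezo = extension + force/k) up to the extension
    where the WLC force equals ``rupture_force``, then drops to the
    baseline within one sample.  The approach segment is noisy baseline.
    Gaussian noise of SD ``spec.noise_sd`` is added throughout.
    """
    lp = spec.tether_Lp if tether_Lp is None else tether_Lp
    lc = spec.tether_Lc if tether_Lc is None else tether_Lc
    sd = spec.noise_sd if noise_sd is None else noise_sd
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ceiling = wlc_force(0.99 * lc, lp, lc, spec.temperature)
    if not 0 < rupture_force < ceiling:
        raise ValueError(
            f"rupture force {rupture_force:.3g} pN unreachable: the WLC force "
            f"at 0.99·Lc is {ceiling:.3g} pN"
        )
    x_rupture = wlc_extension_at_force(rupture_force, lp, lc, spec.temperature)
    # parametrise by extension, map to piezo, then resample on a uniform grid
    x_dense = np.linspace(0.0, x_rupture, 2048)
    f_dense = wlc_force(x_dense, lp, lc, spec.temperature)
    z_dense = x_dense + f_dense / spec.spring_constant
    z_rupture = float(z_dense[-1])
    z_end = z_rupture + 10.0
    n_points = max(2, int(round(z_end * spec.sampling_rate)))
    z = np.linspace(0.0, z_end, n_points)
    force = np.where(
        z <= z_rupture, np.interp(z, z_dense, f_dense), 0.0
    )
    force = force + rng.normal(0.0, sd, n_points)
    approach_force = rng.normal(0.0, sd, n_points)
    piezo = np.concatenate([z[::-1], z])
    f = np.concatenate([approach_force, force])
    labels = np.array(["approach"] * n_points + ["retract"] * n_points)
    return ForceCurve(
        piezo_position=piezo,
        force=f,
        segment_labels=labels,
        spring_constant=spec.spring_constant,
        velocity=spec.velocity,
        temperature=spec.temperature,
    )


@dataclass
class SyntheticCurveSet:
    """Generated curves with their per-curve ground truth."""

    curves: list[ForceCurve]
    truth: "object"  # pandas DataFrame: kind, rupture_force_pN, Lc_nm, Lp_nm

    def n_specific(self) -> int:
        return int((self.truth["kind"] == "specific").sum())


def generate_curve_set(
    model: RuptureForceModel,
    n: int,
    spec: CurveGenSpec,
) -> SyntheticCurveSet:
    """Generate ``n`` curves, ⌊contaminant_fraction·n⌋ of them contaminants.

    Contaminants alternate between the two failure modes the acceptance
    filters target: short-tether events (contour length drawn uniformly in
    5–25 nm, below the 30 nm cutoff) and high-noise events (noise SD
    inflated 5×, which the rmse outlier rule must catch).  Ground truth per
    curve is retained for tests.
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(spec.seed)
    n_contaminant = int(np.floor(spec.contaminant_fraction * n))
    kinds = ["specific"] * (n - n_contaminant) + [
        ("short_tether" if i % 2 == 0 else "high_noise")
        for i in range(n_contaminant)
    ]
    rng.shuffle(kinds)
    forces = sample_rupture_forces(model, n, seed=rng.integers(2**31))
    curves: list[ForceCurve] = []
    rows = []
    for kind, f_rupt in zip(kinds, forces):
        lc = spec.tether_Lc
        noise = spec.noise_sd
        if kind == "short_tether":
            lc = float(rng.uniform(5.0, 25.0))
        elif kind == "high_noise":
            noise = 5.0 * spec.noise_sd
        f_rupt = float(np.clip(f_rupt, 1.0, None))  # keep the WLC reachable
        curves.append(
            generate_force_curve(
                f_rupt, spec, rng=rng, tether_Lc=lc, noise_sd=noise
            )
        )
        rows.append(
            {
                "kind": kind,
                "rupture_force_pN": f_rupt,
                "Lc_nm": lc,
                "Lp_nm": spec.tether_Lp,
                "noise_sd_pN": noise,
            }
        )
    return SyntheticCurveSet(curves=curves, truth=pd.DataFrame(rows))


def generate_fluctuation_trajectory(spec: FluctuationSpec) -> Trajectory:
    """Reference structure plus iid isotropic Gaussian displacements.

    Every atom of a residue listed in ``per_residue_sd`` receives an
    independent Gaussian displacement with the residue's SD (nm, converted
    to Å) on each axis in each frame, emulating uncorrelated equilibrium
    fluctuations; the measured RMSF of such a residue converges to σ·√3.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference
    sd_a = np.array(
        [10.0 * spec.per_residue_sd.get(int(r), 0.0) for r in ref.res_id]
    )
    frames = ref.coords[None, :, :] + rng.normal(
        0.0, 1.0, (spec.n_frames, ref.n_atoms, 3)
    ) * sd_a[None, :, None]
    return Trajectory(topology=ref, frames=frames, timestep=spec.timestep)


def generate_distance_trace(
    median_target: float,
    spread: float,
    n: int,
    seed: int | None = None,
) -> np.ndarray:
    """Positive distance trace (Å) with the prescribed sample median.

    Draws are log-normal with median exactly ``median_target`` and log-SD
    ``spread/median_target``, so every value is positive and the sample
    median converges to the target at the usual 1/√n rate.
    """
    if median_target <= 0:
        raise ValueError("median_target must be positive")
    if spread < 0:
        raise ValueError("spread must be non-negative")
    if n < 1:
        raise ValueError("n must be at least 1")
    if spread == 0:
        return np.full(n, float(median_target))
    rng = np.random.default_rng(seed)
    sigma = spread / median_target
    return median_target * np.exp(rng.normal(0.0, sigma, n))


def generate_separating_dimer(
    body_a: Structure,
    body_b: Structure,
    rupture_frame_target: int,
    n_frames: int,
    probe: float = 1.4,
    n_points: int = 960,
    tolerance: float = 1.0,
    timestep: float = 1.0,
    verify: bool = True,
) -> Trajectory:
    """Rigid-body separation trajectory rupturing at a chosen frame.

    Body B is translated along the A→B centre axis with a linear schedule
    scaled so that the buried interface area ΔSASA first falls to
    ``tolerance`` (Å²) exactly at frame ``rupture_frame_target`` (1-based).
    Bodies must be in contact (ΔSASA > tolerance) at the start.
    """
    from .trajectory import delta_sasa

    if not 1 <= rupture_frame_target <= n_frames:
        raise ValueError("rupture_frame_target must lie in [1, n_frames]")
    axis = body_b.coords.mean(axis=0) - body_a.coords.mean(axis=0)
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 0 else np.array([1.0, 0.0, 0.0])

    def interface(d: float) -> float:
        return delta_sasa(body_a, body_b.translated(d * axis), probe, n_points)

    if interface(0.0) <= tolerance:
        raise ValueError("bodies are not in contact at the start")
    # bracket then bisect the smallest displacement with ΔSASA <= tolerance
    hi = 2.0 * (body_a.radius.max() + body_b.radius.max() + 2 * probe)
    while interface(hi) > tolerance:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("failed to separate the bodies")
    lo = 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if interface(mid) > tolerance:
            lo = mid
        else:
            hi = mid
    x_star = hi
    disp = x_star * np.arange(1, n_frames + 1) / rupture_frame_target
    topology = concatenate([body_a, body_b])
    na = body_a.n_atoms
    frames = np.repeat(topology.coords[None, :, :], n_frames, axis=0)
    frames[:, na:, :] += disp[:, None, None] * axis[None, None, :]
    traj = Trajectory(topology=topology, frames=frames, timestep=timestep)
    if verify:
        from .trajectory import delta_sasa_trace, rupture_frame

        trace = delta_sasa_trace(
            traj, np.arange(na), np.arange(na, topology.n_atoms), probe, n_points
        )
        got = rupture_frame(trace, tolerance)
        if got != rupture_frame_target:
            raise RuntimeError(
                f"constructed rupture frame {got} != target {rupture_frame_target}"
                " (non-monotonic interface decay for these bodies)"
            )
    return traj
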
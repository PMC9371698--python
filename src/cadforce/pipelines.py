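"""End-to-end pipelines tying the analysis stages together.

``run_force_pipeline`` maps a directory of force-curve TSVs to a
mixture-model peak report (detection → WLC fitting → filtering → FD
binning → EM/BIC selection); ``run_traj_pipeline`` maps a topology plus
trajectory to the MD statistics (RMSD series, per-residue RMSF, salt-bridge
verdicts, ΔSASA trace with rupture frame, centre-of-mass distances).  Both
write a manifest capturing the configuration, input digests, and record
counts so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .constants import DEFAULT_TEMPERATURE_K
from .force_spectroscopy import CurveEventExtractor
from .io import read_curve_tsv, read_pdb, read_xyz_traj, write_report
from .mixture import (
    freedman_diaconis_bin_width,
    make_histogram,
    peak_report,
    select_model,
)
from .structures import Selection
from .trajectory import (
    SALT_BRIDGE_CUTOFF,
    com_distance,
    delta_sasa_trace,
    rmsd_timeseries,
    rmsf,
    rupture_frame,
    salt_bridge_trace,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_force_pipeline", "run_traj_pipeline"]


@dataclass
class RunConfig:
    """Analysis settings; defaults are the study's printed constants.

    Force pipeline: detection drop threshold 20 pN, contour-length cutoff
    30 nm, persistence-length bounds 0.1–1 nm, rmse rule mean + 1·SD,
    mixture k_max 3.  Trajectory pipeline: final-sixth analysis window,
    probe radius 1.4 Å, salt-bridge cutoff 4.0 Å.
    """

    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE_K
    drop_threshold: float = 20.0  # pN
    smooth_window: int = 5
    lc_min: float = 30.0  # nm
    lp_bounds: tuple[float, float] = (0.1, 1.0)  # nm
    rmse_sd_mult: float = 1.0
    k_max: int = 3
    n_init: int = 5
    window_fraction: float = 1.0 / 6.0
    probe_radius: float = 1.4  # Å
    sasa_points: int = 960
    salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF  # Å
    salt_bridge_pairs: list[tuple[str, int, str, int]] = field(default_factory=list)
    delta_sasa_tolerance: float = 1.0  # Å²

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load overrides from a flat key=value file; every override logged."""
        config = cls()
        defaults = dataclasses.asdict(cls())
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key == "salt_bridge_pairs":
                    pairs = []
                    for item in raw.split(","):
                        if not item:
                            continue
                        a, b = item.split(":")
                        pairs.append((a[0], int(a[1:]), b[0], int(b[1:])))
                    value = pairs
                elif key == "lp_bounds":
                    lo, hi = raw.split(",")
                    value = (float(lo), float(hi))
                elif not hasattr(config, key):
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                else:
                    current = getattr(config, key)
                    value = type(current)(raw) if not isinstance(current, int) else int(raw)
                logger.info(
                    "config override %s = %r (default %r)", key, value, defaults.get(key)
                )
                setattr(config, key, value)
        return config


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _manifest(config: RunConfig, inputs: list[Path], counts: dict) -> dict:
    cfg = dataclasses.asdict(config)
    cfg["lp_bounds"] = list(config.lp_bounds)
    cfg["salt_bridge_pairs"] = [list(p) for p in config.salt_bridge_pairs]
    return {
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "inputs": {str(p): _digest(p) for p in inputs},
        "counts": counts,
    }


def run_force_pipeline(
    config: RunConfig,
    curves_dir: str | Path,
    out: str | Path | None = None,
) -> dict:
    """Force-curve directory → filtered events → mixture peak report.

    Returns (and optionally writes) a JSON-serialisable report; a run that
    yields zero accepted events returns ``status="empty"`` rather than
    raising.
    """
    curves_dir = Path(curves_dir)
    paths = sorted(curves_dir.glob("*.tsv"))
    curves = [read_curve_tsv(p) for p in paths]
    extractor = CurveEventExtractor(
        drop_threshold=config.drop_threshold,
        smooth_window=config.smooth_window,
        lc_min=config.lc_min,
        rmse_sd_mult=config.rmse_sd_mult,
        temperature=config.temperature,
    )
    events = extractor.fit_transform(curves)
    accepted = events[events["accepted"]] if len(events) else events
    counts = {
        "curves": len(curves),
        "events_detected": int(len(events)),
        "events_accepted": int(len(accepted)),
    }
    if len(accepted) < 2:
        report = {
            "status": "empty",
            "reason": "fewer than 2 accepted events",
            "counts": counts,
            "manifest": _manifest(config, paths, counts),
        }
    else:
        forces = accepted["rupture_force_pN"].to_numpy()
        width = freedman_diaconis_bin_width(forces)
        hist = make_histogram(forces, width)
        selection = select_model(
            forces, k_max=config.k_max, seed=config.seed, n_init=config.n_init
        )
        report = {
            "status": "ok",
            "counts": counts,
            **peak_report(selection, hist),
            "manifest": _manifest(config, paths, counts),
        }
    if out is not None:
        write_report(report, out)
    return report


def run_traj_pipeline(
    config: RunConfig,
    traj_path: str | Path,
    topology_path: str | Path,
    out: str | Path | None = None,
) -> dict:
    """Topology (PDB) + trajectory (XYZ) → MD statistics report.

    Computes the backbone RMSD series against the first frame, per-residue
    α-carbon RMSF over the final window, salt-bridge verdicts for the
    configured pairs, and — when the topology has exactly two chains — the
    ΔSASA trace with its rupture frame and the inter-chain centre-of-mass
    distance.
    """
    topology = read_pdb(topology_path)
    traj = read_xyz_traj(traj_path, topology)
    n = traj.n_frames
    window = (n - max(2, int(np.ceil(n * config.window_fraction))), n - 1)

    # toy systems may lack enough superposable atoms; degrade gracefully
    try:
        rmsd_series = rmsd_timeseries(traj, reference_frame=0)
    except ValueError:
        rmsd_series = np.zeros(0)
    rmsf_series = None
    for sel in (None, Selection(atom_names=("CA",)), Selection()):
        try:
            rmsf_series = rmsf(traj, selection=sel, window=window)
            break
        except ValueError:
            continue

    bridges = []
    for chain_a, res_a, chain_b, res_b in config.salt_bridge_pairs:
        trace = salt_bridge_trace(
            traj,
            (chain_a, res_a),
            (chain_b, res_b),
            cutoff=config.salt_bridge_cutoff,
        )
        bridges.append(
            {
                "pair": trace.label,
                "median_A": trace.median,
                "formed": bool(trace.formed),
            }
        )

    chains = sorted(set(topology.chain_id.tolist()))
    interface = None
    if len(chains) == 2:
        sel_a = np.flatnonzero(topology.chain_id == chains[0])
        sel_b = np.flatnonzero(topology.chain_id == chains[1])
        dsasa = delta_sasa_trace(
            traj, sel_a, sel_b, config.probe_radius, config.sasa_points
        )
        interface = {
            "delta_sasa_A2": [float(v) for v in dsasa],
            "rupture_frame": rupture_frame(dsasa, config.delta_sasa_tolerance),
            "com_distance_A": [
                float(v) for v in com_distance(traj, sel_a, sel_b)
            ],
        }

    report = {
        "status": "ok",
        "n_frames": n,
        "analysis_window": list(window),
        "rmsd_A": [float(v) for v in rmsd_series],
        "rmsf_A": (
            {str(int(r)): float(v) for r, v in rmsf_series.items()}
            if rmsf_series is not None
            else {}
        ),
        "salt_bridges": bridges,
        "interface": interface,
        "manifest": _manifest(
            config,
            [Path(traj_path), Path(topology_path)],
            {"frames": n, "atoms": topology.n_atoms},
        ),
    }
    if out is not None:
        write_report(report, out)
    return report
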
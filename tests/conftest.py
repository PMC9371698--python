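"""Shared fixtures: toy structures and synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest

from cadforce.structures import Structure


def make_structure(
    coords,
    element="C",
    atom_name="CA",
    res_name="GLY",
    res_ids=None,
    chain="A",
    radius=None,
) -> Structure:
    """Convenience constructor: one atom per coordinate row."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if res_ids is None:
        res_ids = np.arange(1, n + 1)
    return Structure(
        element=[element] * n if isinstance(element, str) else element,
        atom_name=[atom_name] * n if isinstance(atom_name, str) else atom_name,
        res_name=[res_name] * n if isinstance(res_name, str) else res_name,
        res_id=res_ids,
        chain_id=[chain] * n if isinstance(chain, str) else chain,
        coords=coords,
        radius=radius,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def carbon_sphere():
    """A single carbon-like atom with vdW radius 1.9 Å."""
    return make_structure([[0.0, 0.0, 0.0]], radius=[1.9])


@pytest.fixture
def anchor_protein():
    """A 41-residue Cα chain on a helix-like curve: superposition anchor."""
    t = np.linspace(0, 4 * np.pi, 41)
    coords = np.column_stack([10 * np.cos(t), 10 * np.sin(t), 1.5 * t])
    return make_structure(coords)


@pytest.fixture
def salt_bridge_topology():
    """Minimal two-chain topology with a Glu (chain A) and an Arg (chain B).

    Glu carboxylate oxygens sit at the origin region; Arg guanidinium
    nitrogens 3.5 Å away, so the bridge is formed in a static trajectory.
    """
    return Structure(
        element=["C", "O", "O", "C", "N", "N", "N"],
        atom_name=["CD", "OE1", "OE2", "CZ", "NH1", "NH2", "NE"],
        res_name=["GLU", "GLU", "GLU", "ARG", "ARG", "ARG", "ARG"],
        res_id=[13, 13, 13, 99, 99, 99, 99],
        chain_id=["A", "A", "A", "B", "B", "B", "B"],
        coords=[
            [-1.5, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [0.0, 1.2, 0.0],
            [5.0, 0.0, 0.0],
            [3.5, 0.0, 0.0],
            [4.5, 1.2, 0.0],
            [5.5, -1.2, 0.0],
        ],
    )
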
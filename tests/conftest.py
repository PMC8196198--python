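"""Shared fixtures: hand-built frames and small synthetic configurations."""

from __future__ import annotations

import numpy as np
import pytest

from memblens import BilayerFrame, ChainTemplate, SynthConfig, synthetic_topology
from memblens.topology import SpeciesEntry, TopologySpec


def make_frame(atoms, box=(10.0, 10.0, 10.0)):
    """Build a frame from (residue_id, species, atom_name, (x, y, z)) rows."""
    rid, sp, nm, xyz = zip(*atoms)
    return BilayerFrame(
        coords=np.array(xyz, dtype=float),
        box=np.array(box, dtype=float),
        residue_id=np.array(rid),
        species=np.array(sp, dtype=object),
        atom_name=np.array(nm, dtype=object),
    )


@pytest.fixture
def minimal_topology():
    """P-only phospholipid stub plus a sterol; enough for leaflet/depth tests."""
    return TopologySpec(
        {
            "DPPC": SpeciesEntry(
                role="phospholipid",
                chain_atoms=(("C21", "C22", "C23", "C24"),),
                phosphate_atom="P",
            ),
            "DLiPC": SpeciesEntry(
                role="phospholipid",
                chain_atoms=(("C21", "C22", "C23", "C24"),),
                phosphate_atom="P",
            ),
            "CHOL": SpeciesEntry(
                role="sterol",
                sterol_ref_atom="C3",
                sterol_axis_atoms=("C3", "C17"),
            ),
        }
    )


@pytest.fixture
def flat_bilayer(minimal_topology):
    """Four phosphates per leaflet at z = 6 (upper) and z = 2 (lower)."""
    atoms = []
    rid = 1
    for z in (6.0, 2.0):
        for i in range(4):
            atoms.append((rid, "DPPC", "P", (1.0 + 2.0 * i, 1.0, z)))
            rid += 1
    return make_frame(atoms)


@pytest.fixture
def short_template():
    """Four-carbon chains: cheapest geometry when chains are irrelevant."""
    return ChainTemplate(n_carbons=4)


@pytest.fixture
def ordered_config():
    return SynthConfig(
        lattice_nx=6,
        lattice_ny=6,
        composition={"DPPC": 1.0},
        order_noise_sigma=0.0,
        head_jitter_nm=0.0,
        seed=0,
    )


@pytest.fixture
def sterol_config():
    return SynthConfig(
        lattice_nx=8,
        lattice_ny=8,
        composition={"DPPC": 0.5, "DLiPC": 0.25, "CHOL": 0.25},
        sterol_depth_nm=-0.9,
        sterol_tilt_deg=15.0,
        seed=1,
    )


@pytest.fixture
def topology_for(request):
    return synthetic_topology
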
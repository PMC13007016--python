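import numpy as np
import pytest

from peptoidbj.junction_prep import Atom, Conformer
from peptoidbj.synthetic_data import (TraceGenParams, TrajGenParams,
                                      generate_ensemble, generate_trajectory)
from peptoidbj.trace_processing import align_ensemble


def make_hexagon(radius: float = 1.4) -> np.ndarray:
    """Planar regular hexagon in the z=0 plane (benzene-like ring)."""
    ang = np.linspace(0, 2 * np.pi, 7)[:-1]
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(6)])


def make_ring_conformer(ring_pts, seg_a, seg_b) -> Conformer:
    """A ring plus one detached two-atom bond, for piercing tests."""
    atoms = [Atom(id=i, element="C", residue=0, name=f"R{i}")
             for i in range(len(ring_pts))]
    atoms.append(Atom(id=len(ring_pts), element="C", residue=1, name="B0"))
    atoms.append(Atom(id=len(ring_pts) + 1, element="C", residue=1, name="B1"))
    coords = np.vstack([ring_pts, seg_a, seg_b])
    bonds = [(i, (i + 1) % len(ring_pts)) for i in range(len(ring_pts))]
    bonds.append((len(ring_pts), len(ring_pts) + 1))
    return Conformer(atoms=atoms, coords=coords, bonds=bonds,
                     rings=[list(range(len(ring_pts)))])


@pytest.fixture(scope="session")
def unimodal_ensemble():
    """Aligned unimodal ensemble emulating a single-anchoring-motif molecule
    with its conductance population at 10^-4.5 G/G0."""
    params = TraceGenParams(seed=101, n_traces=1200, p_molecule=1.0,
                            plateau_log_g_mean=-4.5, plateau_log_g_sd=0.3)
    aligned, _ = align_ensemble(generate_ensemble(params))
    return aligned


@pytest.fixture(scope="session")
def bimodal_ensemble():
    """Aligned bimodal ensemble with populations at 10^-2.8 and 10^-4.2."""
    params = TraceGenParams(seed=202, n_traces=1200, p_molecule=1.0,
                            populations=[(0.5, -2.8, 0.3), (0.5, -4.2, 0.3)])
    aligned, _ = align_ensemble(generate_ensemble(params))
    return aligned


@pytest.fixture(scope="session")
def anchored_trajectory():
    """Longer anchored trajectory with junction wobble, dense enough for
    free-energy surfaces of the sulfur-sulfur separation."""
    return generate_trajectory(TrajGenParams(
        seed=7, sequence_length=4, n_frames=400, dihedral_sd_deg=12.0,
        coordinate_noise_A=0.02, tilt_sd_deg=8.0))


@pytest.fixture(scope="session")
def small_trajectory():
    """Short 4-residue peptoid-like trajectory with mild fluctuations."""
    return generate_trajectory(TrajGenParams(
        seed=7, sequence_length=4, n_frames=60, dihedral_sd_deg=12.0,
        coordinate_noise_A=0.02, tilt_sd_deg=8.0))
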
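"""Structural analyses of molecular-junction trajectories.

Covers the post-processing stages applied to holding-stage conformational
ensembles: hydrogen-bond candidate distance distributions (all donor to
acceptor combinations between backbone nitrogens and carbonyl oxygens),
CH–O contact distances, backbone/side-chain dihedral statistics including
Ramachandran-style joint histograms, PCA of the upper-triangle interatomic
distance matrix of a backbone-atom selection (Z-scored, whitened), and
free-energy surfaces by direct Boltzmann inversion of 2D histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import circmean, circstd
from sklearn.decomposition import PCA

from ._geometry import measure_dihedral
from .junction_prep import Conformer

__all__ = [
    "Trajectory",
    "DonorAcceptorSet",
    "PCAEmbedding",
    "donors_acceptors_from_topology",
    "default_backbone_selection",
    "hbond_distance_series",
    "ch_o_distance_series",
    "dihedral_statistics",
    "ramachandran",
    "pca_embed",
    "free_energy_surface",
    "ss_distance_series",
]

KB_KCAL_PER_MOL_K = 0.0019872041  # Boltzmann constant in kcal/mol/K


@dataclass
class Trajectory:
    """Frame sequence over a fixed topology; coordinates in Å."""

    topology: Conformer
    frames: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology.atoms):
            raise ValueError("frame atom count does not match topology")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def atom_index(self, atom_id: int) -> int:
        return self.topology.index_of(atom_id)


@dataclass
class DonorAcceptorSet:
    """Hydrogen-bond roles: donors as (heavy atom, attached H) id pairs,
    acceptors as heavy-atom ids."""

    donors: list[tuple[int, int]]
    acceptors: list[int]

    def __post_init__(self) -> None:
        if not self.donors or not self.acceptors:
            raise ValueError("donor and acceptor sets must be non-empty")


def donors_acceptors_from_topology(conf: Conformer) -> DonorAcceptorSet:
    """Derive H-bond roles from a topology: donors are nitrogens with at
    least one bonded hydrogen (on a substituted peptoid amide there is none,
    so only terminal caps qualify); acceptors are carbonyl oxygens."""
    adj: dict[int, list[int]] = {a.id: [] for a in conf.atoms}
    for i, j in conf.bonds:
        adj[i].append(j)
        adj[j].append(i)
    elem = {a.id: a.element for a in conf.atoms}
    donors = []
    for a in conf.atoms:
        if a.element != "N":
            continue
        hs = [j for j in adj[a.id] if elem[j] == "H"]
        for h in hs:
            donors.append((a.id, h))
    acceptors = []
    for a in conf.atoms:
        if a.element != "O":
            continue
        if any(elem[j] == "C" for j in adj[a.id]):
            acceptors.append(a.id)
    return DonorAcceptorSet(donors=donors, acceptors=acceptors)


def default_backbone_selection(conf: Conformer) -> list[int]:
    """Backbone heavy atoms plus the C-terminal cap nitrogen — the shared
    molecular subgraph used for distance-matrix PCA (17 atoms for a
    4-residue oligomer, 21 for 5 residues)."""
    ids = [a.id for a in conf.atoms if a.role == "backbone" and a.element != "H"]
    ids += [a.id for a in conf.atoms if a.role == "cap" and a.element == "N"]
    return sorted(ids)


def _pair_series(traj: Trajectory, idx_a: int, idx_b: int) -> np.ndarray:
    return np.linalg.norm(traj.frames[:, idx_a] - traj.frames[:, idx_b], axis=1)


def hbond_distance_series(traj: Trajectory, das: DonorAcceptorSet,
                          heavy_threshold_A: float = 3.5,
                          h_threshold_A: float = 2.5,
                          bins: int = 50,
                          range_A: tuple[float, float] = (1.0, 12.0)) -> dict:
    """Distance series and histograms for every donor-acceptor combination.

    For each (donor heavy atom, H, acceptor) candidate, the per-frame
    heavy-atom distance (e.g. N···O) and H···O distance are computed, with
    occupancy = fraction of frames where both fall below their thresholds
    (defaults: heavy 3.5 Å, H 2.5 Å; echoed in the output).
    """
    donor_hs: dict[int, list[int]] = {}
    for dh, h in das.donors:
        donor_hs.setdefault(dh, []).append(h)
    pairs = []
    for dh in sorted(donor_hs):
        for acc in das.acceptors:
            if acc == dh:
                continue
            heavy = _pair_series(traj, traj.atom_index(dh), traj.atom_index(acc))
            # closest attached hydrogen per frame
            hdist = np.min(
                [_pair_series(traj, traj.atom_index(h), traj.atom_index(acc))
                 for h in donor_hs[dh]], axis=0)
            counts, edges = np.histogram(heavy, bins=bins, range=range_A)
            occupancy = float(
                np.mean((heavy <= heavy_threshold_A) & (hdist <= h_threshold_A))
            )
            pairs.append({
                "donor": dh,
                "hydrogens": donor_hs[dh],
                "acceptor": acc,
                "heavy_distance_A": heavy,
                "h_distance_A": hdist,
                "histogram": (counts, edges),
                "occupancy": occupancy,
            })
    return {
        "pairs": pairs,
        "n_donor_heavy": len(donor_hs),
        "n_acceptors": len(das.acceptors),
        "thresholds_A": {"heavy": heavy_threshold_A, "hydrogen": h_threshold_A},
    }


def ch_o_distance_series(traj: Trajectory, bins: int = 50,
                         range_A: tuple[float, float] = (1.0, 12.0)) -> dict:
    """C(H)···O contact distances between methylene-type carbons and carbonyl
    oxygens, identified from the topology.

    Methylene carbons are carbons bonded to two or more hydrogens or, when
    hydrogens are implicit, backbone Cα / side-chain CH2 atoms (role-tagged
    ``backbone``/``sidechain`` carbons with two heavy-atom neighbours).
    """
    conf = traj.topology
    adj: dict[int, list[int]] = {a.id: [] for a in conf.atoms}
    for i, j in conf.bonds:
        adj[i].append(j)
        adj[j].append(i)
    elem = {a.id: a.element for a in conf.atoms}
    methylenes = []
    for a in conf.atoms:
        if a.element != "C":
            continue
        n_h = sum(1 for j in adj[a.id] if elem[j] == "H")
        heavy = [j for j in adj[a.id] if elem[j] != "H"]
        if n_h >= 2 or (n_h == 0 and len(heavy) == 2 and a.name in ("CA", "CB")):
            methylenes.append(a.id)
    oxygens = [a.id for a in conf.atoms
               if a.element == "O" and any(elem[j] == "C" for j in adj[a.id])]
    if not methylenes:
        warnings.warn("no methylene carbons found in topology")
        return {"pairs": []}
    pairs = []
    for c in methylenes:
        for o in oxygens:
            if o in adj[c]:
                continue
            series = _pair_series(traj, traj.atom_index(c), traj.atom_index(o))
            counts, edges = np.histogram(series, bins=bins, range=range_A)
            pairs.append({"carbon": c, "oxygen": o, "distance_A": series,
                          "histogram": (counts, edges)})
    return {"pairs": pairs}


def dihedral_series(traj: Trajectory, quad: tuple[int, int, int, int]) -> np.ndarray:
    """Per-frame torsion angle (degrees) over four atom ids; frames with a
    collinear central bond are NaN-flagged."""
    idx = [traj.atom_index(i) for i in quad]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        try:
            out[f] = measure_dihedral(*(traj.frames[f, i] for i in idx))
        except ValueError:
            out[f] = np.nan
    return out


def dihedral_statistics(traj: Trajectory,
                        definitions: dict[str, tuple[int, int, int, int]],
                        bins: int = 36) -> dict:
    """Angle series, circular histograms and circular summary statistics for
    a set of named dihedral definitions."""
    out = {}
    for name, quad in definitions.items():
        series = dihedral_series(traj, quad)
        ok = series[np.isfinite(series)]
        counts, edges = np.histogram(ok, bins=bins, range=(-180.0, 180.0))
        out[name] = {
            "series_deg": series,
            "histogram": (counts, edges),
            "circular_mean_deg": float(circmean(ok, high=180.0, low=-180.0))
            if len(ok) else np.nan,
            "circular_std_deg": float(circstd(ok, high=180.0, low=-180.0))
            if len(ok) else np.nan,
            "n_flagged": int(np.sum(~np.isfinite(series))),
        }
    return out


def ramachandran(traj: Trajectory, bins: int = 36) -> dict:
    """Joint (φ, ψ) histogram pooled over residues with both angles defined."""
    phis, psis = [], []
    for res, defs in traj.topology.dihedrals.items():
        if "phi" in defs and "psi" in defs:
            phis.append(dihedral_series(traj, defs["phi"]))
            psis.append(dihedral_series(traj, defs["psi"]))
    if not phis:
        raise ValueError("no residue has both phi and psi defined")
    phi = np.concatenate(phis)
    psi = np.concatenate(psis)
    ok = np.isfinite(phi) & np.isfinite(psi)
    counts, xe, ye = np.histogram2d(phi[ok], psi[ok], bins=bins,
                                    range=[(-180, 180), (-180, 180)])
    return {"counts": counts, "phi_edges": xe, "psi_edges": ye}


@dataclass
class PCAEmbedding:
    """Whitened PCA of per-frame upper-triangle interatomic distances."""

    atom_ids: list[int]
    feature_dim: int
    kept_dims: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    components: np.ndarray
    projections: np.ndarray
    explained_variance_ratio: np.ndarray


def distance_features(traj: Trajectory, atom_ids: Sequence[int]) -> np.ndarray:
    """Per-frame condensed (upper-triangle) pairwise distance vectors for the
    selected atoms: n(n-1)/2 features per frame."""
    idx = [traj.atom_index(i) for i in atom_ids]
    if len(idx) < 2:
        raise ValueError("need at least two atoms")
    return np.array([pdist(traj.frames[f][idx]) for f in range(traj.n_frames)])


def pca_embed(traj: Trajectory, atom_ids: Sequence[int],
              n_components: int = 2) -> PCAEmbedding:
    """Z-score the distance features per dimension (zero-variance dimensions
    dropped with a warning), then project onto the first whitened principal
    components."""
    if traj.n_frames < 3:
        raise ValueError("need at least three frames")
    feats = distance_features(traj, atom_ids)
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not np.any(keep):
        raise ValueError("all frames identical: no variance to analyze")
    if not np.all(keep):
        warnings.warn(f"dropping {int(np.sum(~keep))} zero-variance distance "
                      "dimensions before PCA")
    z = (feats[:, keep] - mean[keep]) / sd[keep]
    n_comp = min(n_components, z.shape[0] - 1, z.shape[1])
    pca = PCA(n_components=n_comp, whiten=True, svd_solver="full")
    proj = pca.fit_transform(z)
    return PCAEmbedding(
        atom_ids=list(atom_ids),
        feature_dim=feats.shape[1],
        kept_dims=np.flatnonzero(keep),
        mean=mean,
        sd=sd,
        components=pca.components_,
        projections=proj,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def free_energy_surface(x_series, y_series, temperature_K: float,
                        bins: int = 40,
                        range_xy: Optional[list] = None) -> dict:
    """Free-energy surface F(x, y) = -kB·T·ln p̂(x, y) by Boltzmann inversion
    of the normalized 2D histogram, with the minimum shifted to zero.

    Empty bins are NaN (undefined), never an infinite sentinel. Energy is in
    kcal/mol. Returns the surface with bin edges and the kB·T used.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be equal-length 1D arrays")
    if len(x) == 0:
        raise ValueError("no samples")
    nbins = bins * bins if np.isscalar(bins) else bins[0] * bins[1]
    if len(x) < nbins:
        warnings.warn("fewer samples than bins: surface will be noisy")
    counts, xe, ye = np.histogram2d(x, y, bins=bins, range=range_xy)
    p = counts / counts.sum()
    kt = KB_KCAL_PER_MOL_K * temperature_K
    with np.errstate(divide="ignore"):
        f = np.where(p > 0, -kt * np.log(np.where(p > 0, p, 1.0)), np.nan)
    f -= np.nanmin(f)
    return {"free_energy": f, "x_edges": xe, "y_edges": ye, "kT": kt,
            "n_samples": len(x)}


def ss_distance_series(traj: Trajectory, axis=(0.0, 0.0, 1.0)) -> dict:
    """Axial (z) and perpendicular (xy) components of the anchor-sulfur
    separation per frame, relative to the pulling axis."""
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    s_ids = [a.id for a in traj.topology.atoms
             if a.element == "S" and a.role == "anchor"]
    if len(s_ids) != 2:
        raise ValueError("topology must contain exactly two anchor sulfurs")
    i0, i1 = (traj.atom_index(i) for i in s_ids)
    vec = traj.frames[:, i1] - traj.frames[:, i0]
    z = vec @ axis
    perp = vec - np.outer(z, axis)
    return {"z_A": np.abs(z), "xy_A": np.linalg.norm(perp, axis=1),
            "anchor_ids": s_ids}
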
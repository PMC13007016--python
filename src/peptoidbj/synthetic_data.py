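"""Seeded generators for break-junction trace ensembles and peptoid-like
trajectories.

The trace generator emulates the qualitative anatomy of an STM break-junction
pulling trace: a metallic contact at or above 1 G0, rupture with snap-back
past 0.5 G0, then either a bare exponential tunneling decay or — with a
per-trace Bernoulli probability, the trace-level realization of
Poisson-statistics junction formation at low analyte concentration — a
molecular conductance plateau drawn from a (possibly multimodal) log-normal
level distribution, ending in decay to the detection floor.  Every generated
trace carries its ground-truth labels so that downstream histogram,
peak-fitting and clustering stages can be validated against known inputs.

The trajectory generator builds a peptoid-like oligomer (N-substituted
glycine backbone, side chains on nitrogen, thioether sulfur anchors on the
terminal residues, NH / NH2 terminal caps) from internal coordinates and
emits multi-frame coordinate sets with controlled dihedral fluctuations.

Reproducibility contract: one root seed; per-trace child streams are derived
by counter so enlarging ``n_traces`` never reshuffles earlier traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._geometry import measure_dihedral, place_atom, rotation_about_axis
from .junction_prep import Atom, Conformer
from .traj_analysis import Trajectory

__all__ = [
    "TraceGenParams",
    "TrajGenParams",
    "GenerationError",
    "generate_trace",
    "generate_ensemble",
    "build_peptoid_conformer",
    "generate_trajectory",
]


class GenerationError(ValueError):
    """Raised for invalid generator parameters or unrealizable geometry."""


@dataclass
class TraceGenParams:
    """Parameters of the synthetic pulling-trace ensemble.

    Levels are log10(G/G0); lengths in nm.  ``populations`` optionally
    replaces the single plateau distribution with a weighted mixture of
    ``(weight, mean, sd)`` components for multimodal ensembles.  The trace
    physics not fixed by the measurement conventions (contact ceiling,
    snap-back level, tunneling slope, log-normal noise) is explicit
    configuration with documented defaults: only its qualitative shape
    matters for exercising the analysis stages.
    """

    seed: int = 0
    n_traces: int = 5000
    bias_mV: float = 250.0
    p_molecule: float = 0.4
    plateau_log_g_mean: float = -4.5
    plateau_log_g_sd: float = 0.3
    plateau_length_mean_nm: float = 0.6
    plateau_length_sd_nm: float = 0.0
    tunneling_slope_decades_per_nm: float = 5.0
    approach_slope_decades_per_nm: float = 25.0
    noise_sd_decades: float = 0.15
    noise_floor_log_g: float = -6.5
    sample_step_nm: float = 0.008
    populations: Optional[Sequence[tuple[float, float, float]]] = None
    contact_ceiling_log_g: float = 0.48
    snapback_log_g: float = -0.8
    contact_length_nm: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_molecule <= 1.0):
            raise GenerationError("p_molecule must be a probability")
        if self.sample_step_nm <= 0:
            raise GenerationError("sample step must be positive")
        if self.n_traces < 1:
            raise GenerationError("need at least one trace")
        if self.populations is not None:
            if len(self.populations) == 0:
                raise GenerationError("populations must be non-empty when given")
            w = sum(p[0] for p in self.populations)
            if abs(w - 1.0) > 1e-9:
                raise GenerationError("population weights must sum to 1")
            means = [p[1] for p in self.populations]
        else:
            means = [self.plateau_log_g_mean]
        for m in means:
            if not (self.noise_floor_log_g < m < 0.0):
                raise GenerationError(
                    "plateau level must lie between the noise floor and 0"
                )

    @property
    def mixture(self) -> list[tuple[float, float, float]]:
        if self.populations is not None:
            return [tuple(p) for p in self.populations]
        return [(1.0, self.plateau_log_g_mean, self.plateau_log_g_sd)]


def _trace_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-derived child stream for trace ``index``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def generate_trace(params: TraceGenParams, rng: np.random.Generator,
                   trace_id: str = "t0"):
    """Generate one pulling trace.

    The skeleton is: linear metallic descent from the contact ceiling to
    1 G0 over ``contact_length_nm``, snap-back to ``snapback_log_g`` at
    displacement 0, tunneling decay at the configured slope, an optional
    molecular plateau, and final decay clamped at the noise floor.
    Multiplicative (log-space Gaussian) noise is applied to the
    post-rupture segment only.
    """
    from .trace_processing import Trace

    step = params.sample_step_nm
    has_molecule = bool(rng.random() < params.p_molecule)

    pop_index = -1
    plateau_level = np.nan
    plateau_length = np.nan
    if has_molecule:
        mix = params.mixture
        weights = np.array([m[0] for m in mix])
        pop_index = int(rng.choice(len(mix), p=weights / weights.sum()))
        _, mu, sd = mix[pop_index]
        plateau_level = float(mu + sd * rng.standard_normal())
        length = params.plateau_length_mean_nm
        if params.plateau_length_sd_nm > 0:
            length += params.plateau_length_sd_nm * rng.standard_normal()
        plateau_length = float(max(step, length))

    slope = params.tunneling_slope_decades_per_nm
    floor = params.noise_floor_log_g
    snap = params.snapback_log_g

    # piecewise-linear skeleton in (displacement, log_g), post-rupture part
    if has_molecule and plateau_level < snap:
        # rapid post-rupture drop onto the molecular level, then plateau
        d_reach = (snap - plateau_level) / params.approach_slope_decades_per_nm
        knots = [
            (0.0, snap),
            (d_reach, plateau_level),
            (d_reach + plateau_length, plateau_level),
            (d_reach + plateau_length + (plateau_level - floor) / slope, floor),
        ]
    else:
        knots = [(0.0, snap), ((snap - floor) / slope, floor)]
    d_end = knots[-1][0] + 0.05  # short tail at the floor

    d_contact = np.arange(-params.contact_length_nm, 0.0, step)
    contact = np.interp(
        d_contact,
        [-params.contact_length_nm, -step],
        [params.contact_ceiling_log_g, 0.0],
    )
    d_pull = np.arange(0.0, d_end, step)
    kx = [k[0] for k in knots]
    ky = [k[1] for k in knots]
    pull = np.interp(d_pull, kx, ky)
    if params.noise_sd_decades > 0:
        pull = pull + params.noise_sd_decades * rng.standard_normal(len(pull))
    pull = np.clip(pull, floor, params.contact_ceiling_log_g)

    displacement = np.concatenate([d_contact, d_pull])
    log_g = np.concatenate([contact, pull])
    truth = {
        "has_molecule": has_molecule,
        "population": pop_index,
        "plateau_log_g": plateau_level,
        "plateau_length_nm": plateau_length,
    }
    return Trace(
        trace_id=trace_id,
        displacement_nm=displacement,
        log_g=log_g,
        bias_mV=params.bias_mV,
        truth=truth,
    )


def generate_ensemble(params: TraceGenParams):
    """Generate ``params.n_traces`` traces with unique ids, deterministic for
    a fixed seed."""
    return [
        generate_trace(params, _trace_rng(params.seed, i), trace_id=f"trace{i:05d}")
        for i in range(params.n_traces)
    ]


# ---------------------------------------------------------------------------
# peptoid-like trajectory generator


@dataclass
class TrajGenParams:
    """Parameters of the synthetic peptoid-like trajectory.

    ``dihedral_targets`` maps dihedral names (phi/psi/omega/chi1) to mean
    values in degrees, applied to every residue; ω means must be 0 (cis) or
    180 (trans).  ``anchor_separation_A`` is recorded as the holding-stage
    label in the frame metadata; the realized sulfur-sulfur distance follows
    from the backbone conformation.  ``tilt_sd_deg`` applies a random rigid
    tilt of the molecule about the anchor axis origin, emulating junction
    wobble relative to the lab-frame pulling axis.
    """

    seed: int = 0
    sequence_length: int = 4
    n_frames: int = 50
    dihedral_targets: dict = field(
        default_factory=lambda: {"phi": -90.0, "psi": 170.0, "omega": 180.0,
                                 "chi1": -65.0, "chi2": 180.0}
    )
    dihedral_sd_deg: float = 10.0
    anchor_separation_A: float = 12.0
    coordinate_noise_A: float = 0.0
    tilt_sd_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise GenerationError("need at least one frame")
        if self.sequence_length < 2:
            raise GenerationError("need at least two residues")
        if self.dihedral_sd_deg < 0 or self.coordinate_noise_A < 0:
            raise GenerationError("spreads must be non-negative")
        om = self.dihedral_targets.get("omega", 180.0)
        if om not in (0.0, 180.0, 0, 180):
            raise GenerationError("omega mean must be 0 (cis) or 180 (trans)")


# internal-coordinate constants (Å / degrees), generic amide values
_BL = {"N-CA": 1.45, "CA-C": 1.52, "C-N": 1.33, "C-O": 1.23, "N-CB": 1.47,
       "CB-S": 1.81, "CB-C": 1.52, "N-H": 1.01, "S-C": 1.79}
_BA = {"N-CA-C": 111.0, "CA-C-N": 116.0, "C-N-CA": 121.0, "CA-C-O": 121.0,
       "CA-N-CB": 117.0, "N-CB-X": 112.0, "CB-S-C": 100.0}


def _peptoid_template(L: int):
    """Atom table, bonds and dihedral definitions for an L-residue peptoid
    with thioether anchors on the terminal residues and NH / NH2 caps."""
    atoms: list[Atom] = []
    ids: dict[tuple[int, str], int] = {}

    def add(res: int, name: str, element: str, role: str) -> int:
        aid = len(atoms)
        atoms.append(Atom(id=aid, element=element, residue=res, name=name, role=role))
        ids[(res, name)] = aid
        return aid

    bonds: list[tuple[int, int]] = []
    for i in range(L):
        add(i, "N", "N", "backbone")
        add(i, "CA", "C", "backbone")
        add(i, "C", "C", "backbone")
        add(i, "O", "O", "backbone")
        add(i, "CB", "C", "sidechain")
        if i in (0, L - 1):
            add(i, "SG", "S", "anchor")   # thioether sulfur
            add(i, "CE", "C", "sidechain")  # terminal methyl on S
        else:
            add(i, "CG", "C", "sidechain")
    add(0, "H0", "H", "cap")        # N-terminal NH
    add(L - 1, "NT", "N", "cap")    # C-terminal NH2
    add(L - 1, "HT1", "H", "cap")
    add(L - 1, "HT2", "H", "cap")

    for i in range(L):
        bonds += [
            (ids[(i, "N")], ids[(i, "CA")]),
            (ids[(i, "CA")], ids[(i, "C")]),
            (ids[(i, "C")], ids[(i, "O")]),
            (ids[(i, "N")], ids[(i, "CB")]),
        ]
        tip = "SG" if i in (0, L - 1) else "CG"
        bonds.append((ids[(i, "CB")], ids[(i, tip)]))
        if tip == "SG":
            bonds.append((ids[(i, "SG")], ids[(i, "CE")]))
        if i + 1 < L:
            bonds.append((ids[(i, "C")], ids[(i + 1, "N")]))
    bonds += [
        (ids[(0, "N")], ids[(0, "H0")]),
        (ids[(L - 1, "C")], ids[(L - 1, "NT")]),
        (ids[(L - 1, "NT")], ids[(L - 1, "HT1")]),
        (ids[(L - 1, "NT")], ids[(L - 1, "HT2")]),
    ]

    dihedrals: dict[int, dict[str, tuple[int, int, int, int]]] = {}
    for i in range(L):
        defs: dict[str, tuple[int, int, int, int]] = {}
        if i > 0:
            defs["omega"] = (ids[(i - 1, "CA")], ids[(i - 1, "C")],
                             ids[(i, "N")], ids[(i, "CA")])
            defs["phi"] = (ids[(i - 1, "C")], ids[(i, "N")],
                           ids[(i, "CA")], ids[(i, "C")])
        nxt = ids[(i + 1, "N")] if i + 1 < L else ids[(L - 1, "NT")]
        defs["psi"] = (ids[(i, "N")], ids[(i, "CA")], ids[(i, "C")], nxt)
        tip = "SG" if i in (0, L - 1) else "CG"
        defs["chi1"] = (ids[(i, "CA")], ids[(i, "N")],
                        ids[(i, "CB")], ids[(i, tip)])
        if tip == "SG":
            defs["chi2"] = (ids[(i, "N")], ids[(i, "CB")],
                            ids[(i, "SG")], ids[(i, "CE")])
        dihedrals[i] = defs
    return atoms, ids, bonds, dihedrals


def build_peptoid_conformer(sequence_length: int,
                            dihedral_values: dict[int, dict[str, float]]) -> Conformer:
    """Build coordinates for the peptoid template from per-residue dihedral
    values (degrees) via sequential internal-coordinate placement.

    Raises :class:`GenerationError` when the requested torsions produce a
    steric collision (non-bonded atoms closer than 0.5 Å).
    """
    L = sequence_length
    atoms, ids, bonds, dihedrals = _peptoid_template(L)
    xyz = np.zeros((len(atoms), 3))

    def dv(res: int, name: str, default: float) -> float:
        return float(dihedral_values.get(res, {}).get(name, default))

    pos = xyz  # alias
    pos[ids[(0, "N")]] = (0.0, 0.0, 0.0)
    pos[ids[(0, "CA")]] = (_BL["N-CA"], 0.0, 0.0)
    pos[ids[(0, "C")]] = place_atom((0.0, 1.0, 0.0), pos[ids[(0, "N")]],
                                    pos[ids[(0, "CA")]], _BL["CA-C"],
                                    _BA["N-CA-C"], 0.0)

    for i in range(L):
        n_i, ca_i, c_i = ids[(i, "N")], ids[(i, "CA")], ids[(i, "C")]
        psi = dv(i, "psi", 170.0)
        nxt = ids[(i + 1, "N")] if i + 1 < L else ids[(L - 1, "NT")]
        pos[nxt] = place_atom(pos[n_i], pos[ca_i], pos[c_i],
                              _BL["C-N"], _BA["CA-C-N"], psi)
        pos[ids[(i, "O")]] = place_atom(pos[n_i], pos[ca_i], pos[c_i],
                                        _BL["C-O"], _BA["CA-C-O"], psi + 180.0)
        # side-chain branch on N: anti to the preceding carbonyl (planar N)
        if i == 0:
            cb_torsion = 80.0
        else:
            phi_meas = measure_dihedral(pos[c_i], pos[ca_i], pos[n_i],
                                        pos[ids[(i - 1, "C")]])
            cb_torsion = phi_meas + 180.0
        pos[ids[(i, "CB")]] = place_atom(pos[c_i], pos[ca_i], pos[n_i],
                                         _BL["N-CB"], _BA["CA-N-CB"], cb_torsion)
        tip = "SG" if i in (0, L - 1) else "CG"
        bl = _BL["CB-S"] if tip == "SG" else _BL["CB-C"]
        pos[ids[(i, tip)]] = place_atom(pos[ca_i], pos[n_i], pos[ids[(i, "CB")]],
                                        bl, _BA["N-CB-X"], dv(i, "chi1", -65.0))
        if tip == "SG":
            pos[ids[(i, "CE")]] = place_atom(pos[n_i], pos[ids[(i, "CB")]],
                                             pos[ids[(i, "SG")]], _BL["S-C"],
                                             _BA["CB-S-C"], dv(i, "chi2", 180.0))
        if i == 0:
            pos[ids[(0, "H0")]] = place_atom(pos[c_i], pos[ca_i], pos[n_i],
                                             _BL["N-H"], 118.0, cb_torsion + 180.0)
        if i + 1 < L:
            omega = dv(i + 1, "omega", 180.0)
            phi = dv(i + 1, "phi", -90.0)
            pos[ids[(i + 1, "CA")]] = place_atom(pos[ca_i], pos[c_i], pos[nxt],
                                                 _BL["N-CA"], _BA["C-N-CA"], omega)
            pos[ids[(i + 1, "C")]] = place_atom(pos[c_i], pos[nxt],
                                                pos[ids[(i + 1, "CA")]],
                                                _BL["CA-C"], _BA["N-CA-C"], phi)
    nt = ids[(L - 1, "NT")]
    pos[ids[(L - 1, "HT1")]] = place_atom(pos[ids[(L - 1, "CA")]],
                                          pos[ids[(L - 1, "C")]], pos[nt],
                                          _BL["N-H"], 120.0, 0.0)
    pos[ids[(L - 1, "HT2")]] = place_atom(pos[ids[(L - 1, "CA")]],
                                          pos[ids[(L - 1, "C")]], pos[nt],
                                          _BL["N-H"], 120.0, 180.0)

    conf = Conformer(atoms=atoms, coords=xyz, bonds=bonds, rings=[],
                     dihedrals=dihedrals)
    _check_collisions(conf)
    return conf


def _check_collisions(conf: Conformer, min_dist: float = 0.5) -> None:
    bonded = {frozenset(b) for b in conf.bonds}
    xyz = conf.coords
    n = len(conf.atoms)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((conf.atoms[i].id, conf.atoms[j].id)) in bonded:
                continue
            if d[i, j] < min_dist:
                raise GenerationError(
                    f"steric collision between atoms {conf.atoms[i].id} and "
                    f"{conf.atoms[j].id} ({d[i, j]:.2f} Å)"
                )


def _wrap_deg(a: float) -> float:
    return ((a + 180.0) % 360.0) - 180.0


def generate_trajectory(params: TrajGenParams) -> Trajectory:
    """Generate a multi-frame peptoid-like trajectory.

    Per frame, each defined dihedral is drawn from a wrapped normal around
    its target; coordinates are rebuilt from internal coordinates, the
    molecule is oriented with the sulfur-sulfur axis along +z (optionally
    tilted by a random angle of spread ``tilt_sd_deg``), and isotropic
    Gaussian coordinate noise is added.
    """
    rng = np.random.default_rng(params.seed)
    L = params.sequence_length
    _, ids, _, dihedral_defs = _peptoid_template(L)
    frames = []
    topology: Conformer | None = None
    s0 = (0, "SG")
    s1 = (L - 1, "SG")
    for _ in range(params.n_frames):
        values: dict[int, dict[str, float]] = {}
        for res, defs in dihedral_defs.items():
            values[res] = {}
            for name in defs:
                mean = float(params.dihedral_targets.get(
                    name, {"phi": -90.0, "psi": 170.0, "omega": 180.0,
                           "chi1": -65.0, "chi2": 180.0}[name]))
                draw = mean + params.dihedral_sd_deg * rng.standard_normal()
                values[res][name] = _wrap_deg(draw)
        conf = build_peptoid_conformer(L, values)
        xyz = conf.coords
        # orient S-S axis along +z
        v = xyz[ids[s1]] - xyz[ids[s0]]
        vn = np.linalg.norm(v)
        if vn > 1e-9:
            vhat = v / vn
            axis = np.cross(vhat, [0.0, 0.0, 1.0])
            an = np.linalg.norm(axis)
            if an > 1e-9:
                ang = np.degrees(np.arccos(np.clip(vhat[2], -1.0, 1.0)))
                rot = rotation_about_axis(axis / an, ang)
                xyz = xyz @ rot.T
        xyz = xyz - xyz[ids[s0]]
        if params.tilt_sd_deg > 0:
            taxis = rng.normal(size=3)
            taxis /= np.linalg.norm(taxis)
            tang = params.tilt_sd_deg * rng.standard_normal()
            xyz = xyz @ rotation_about_axis(taxis, tang).T
        if params.coordinate_noise_A > 0:
            xyz = xyz + params.coordinate_noise_A * rng.standard_normal(xyz.shape)
        if topology is None:
            topology = Conformer(atoms=conf.atoms, coords=xyz, bonds=conf.bonds,
                                 rings=[], dihedrals=conf.dihedrals)
        frames.append(xyz)
    return Trajectory(
        topology=topology,
        frames=np.array(frames),
        metadata={"stage_A": params.anchor_separation_A,
                  "seed": params.seed,
                  "pulling_axis": [0.0, 0.0, 1.0]},
    )
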
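"""Junction-preparation computations for molecular-junction MD setup.

This module covers the bespoke setup steps that precede a holding-stage
simulation of a thiol/thioether-anchored molecule between two electrodes:

* randomization of backbone dihedrals (φ/ψ uniform on [-180, 180), ω set
  to cis (0°) or trans (180°) with equal probability),
* detection of ring piercings — bonds threading through rings, an artifact
  of dihedral randomization — and construction of the nonbonded-exclusion
  pairs that mitigate them,
* the three custom junction restraint potentials (anchor-separation
  restraint along the pulling axis, uniform-field potential acting on
  partial charges, and a lone-pair orientation penalty on the anchoring
  sulfurs), evaluated as energies with analytic forces.

MD integration itself (thermostats, PME, solvation) is out of scope; the
module produces setup artifacts and potential evaluations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._geometry import measure_dihedral, rotation_about_axis

__all__ = [
    "Atom",
    "Conformer",
    "RestraintSpec",
    "ExclusionList",
    "set_dihedral",
    "randomize_backbone_dihedrals",
    "detect_ring_piercing",
    "mitigation_exclusions",
    "restraint_energy_forces",
    "field_from_bias",
    "campaign_duration_us",
]


@dataclass(frozen=True)
class Atom:
    """One atom: integer id, element symbol, residue index, atom name and a
    free-form role tag (``backbone``, ``sidechain``, ``cap``, ``anchor`` ...)."""

    id: int
    element: str
    residue: int
    name: str
    role: str = ""


@dataclass
class Conformer:
    """A single structure: atoms, coordinates (Å), bonds, rings and named
    rotatable-dihedral definitions.

    ``dihedrals`` maps a residue index to a dict of dihedral name
    (``phi``/``psi``/``omega``/``chi1`` ...) -> 4-tuple of atom ids.
    """

    atoms: list[Atom]
    coords: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)
    rings: list[list[int]] = field(default_factory=list)
    dihedrals: dict[int, dict[str, tuple[int, int, int, int]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError("coords must be (n_atoms, 3)")

    def index_of(self, atom_id: int) -> int:
        try:
            return self._id_index[atom_id]
        except AttributeError:
            self._id_index = {a.id: i for i, a in enumerate(self.atoms)}
            return self._id_index[atom_id]

    def position(self, atom_id: int) -> np.ndarray:
        return self.coords[self.index_of(atom_id)]

    def measure(self, quad: tuple[int, int, int, int]) -> float:
        """Dihedral angle (degrees) over four atom ids."""
        return measure_dihedral(*(self.position(i) for i in quad))

    def copy(self) -> "Conformer":
        return Conformer(
            atoms=list(self.atoms),
            coords=self.coords.copy(),
            bonds=list(self.bonds),
            rings=[list(r) for r in self.rings],
            dihedrals={k: dict(v) for k, v in self.dihedrals.items()},
        )


@dataclass
class RestraintSpec:
    """Parameters of the three junction restraint potentials.

    Units: energies in kcal/mol, lengths in Å, so ``k_anchor`` is
    kcal/mol/Å², ``k_orient`` kcal/mol (per unit 1-cosθ).  ``field_V_per_m``
    is the uniform-field magnitude; charges are elementary charges and the
    field energy is converted to kcal/mol internally.
    """

    anchor_atom_ids: tuple[int, int]
    stage_target_A: float = 6.0
    pulling_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    k_anchor: float = 10.0
    field_V_per_m: float = 0.0
    k_orient: float = 0.0
    lone_pair_reference_atoms: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pulling_axis = np.asarray(self.pulling_axis, dtype=float)
        n = np.linalg.norm(self.pulling_axis)
        if n == 0 or not np.isfinite(n):
            raise ValueError("pulling axis must be a finite nonzero vector")
        self.pulling_axis = self.pulling_axis / n
        if self.stage_target_A <= 0:
            raise ValueError("stage target must be positive")
        if not np.isfinite(self.field_V_per_m):
            raise ValueError("field magnitude must be finite")


# e * (V/m) * Å  ->  kcal/mol:  1 e·V = 23.0609 kcal/mol, 1 Å = 1e-10 m
_EV_PER_M_ANG_TO_KCAL = 23.060547830619026e-10


@dataclass
class ExclusionList:
    """Unordered unique atom-id pairs whose nonbonded terms are removed."""

    pairs: set[frozenset[int]] = field(default_factory=set)

    def add(self, i: int, j: int) -> None:
        if i != j:
            self.pairs.add(frozenset((i, j)))

    def as_sorted_tuples(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(p)) for p in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# dihedral manipulation


def _downstream_atoms(conf: Conformer, b: int, c: int) -> set[int]:
    """Atom ids on the c-side after cutting bond (b, c): the fragment rotated
    when the torsion about b-c changes."""
    adj: dict[int, set[int]] = {a.id: set() for a in conf.atoms}
    for i, j in conf.bonds:
        adj[i].add(j)
        adj[j].add(i)
    seen = {b, c}
    stack = [c]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    seen.discard(b)
    return seen


def set_dihedral(conf: Conformer, quad: tuple[int, int, int, int],
                 target_deg: float) -> Conformer:
    """Return a new conformer with the torsion over ``quad`` set to
    ``target_deg`` by rigidly rotating the downstream (d-side) fragment
    about the b-c bond.  Bond lengths and angles are preserved exactly."""
    a, b, c, d = quad
    current = conf.measure(quad)
    delta = target_deg - current
    out = conf.copy()
    if abs(((delta + 180.0) % 360.0) - 180.0) < 1e-13:
        return out
    pb = conf.position(b)
    pc = conf.position(c)
    axis = pc - pb
    if np.linalg.norm(axis) < 1e-9:
        raise ValueError("degenerate rotation axis")
    # IUPAC-positive torsion increase corresponds to rotating the d-side
    # fragment by +delta about the b->c direction.
    rot = rotation_about_axis(axis, delta)
    moving = _downstream_atoms(conf, b, c)
    idx = np.array([out.index_of(i) for i in moving], dtype=int)
    out.coords[idx] = (out.coords[idx] - pb) @ rot.T + pb
    return out


def randomize_backbone_dihedrals(conf: Conformer, seed: int) -> Conformer:
    """Randomize backbone torsions: φ and ψ drawn uniformly on [-180, 180),
    ω set to 0° (cis) or 180° (trans) with probability 1/2 each.

    Returns a new conformer; the input is not modified.
    """
    rng = np.random.default_rng(seed)
    out = conf.copy()
    for res in sorted(conf.dihedrals):
        defs = conf.dihedrals[res]
        for name in ("phi", "psi", "omega"):
            if name not in defs:
                continue
            if name == "omega":
                target = float(rng.choice([0.0, 180.0]))
            else:
                target = float(rng.uniform(-180.0, 180.0))
            out = set_dihedral(out, defs[name], target)
    return out


# ---------------------------------------------------------------------------
# ring piercing


def _segment_triangle_intersection(p0, p1, t0, t1, t2, eps=1e-9):
    """Intersection point of segment p0-p1 with triangle (t0,t1,t2), or None.

    Möller–Trumbore with inclusive edge/endpoint tolerance.
    """
    d = p1 - p0
    e1 = t1 - t0
    e2 = t2 - t0
    h = np.cross(d, e2)
    a = np.dot(e1, h)
    if abs(a) < eps:
        return None  # segment parallel to triangle plane
    f = 1.0 / a
    s = p0 - t0
    u = f * np.dot(s, h)
    if u < -eps or u > 1.0 + eps:
        return None
    q = np.cross(s, e1)
    v = f * np.dot(d, q)
    if v < -eps or u + v > 1.0 + eps:
        return None
    t = f * np.dot(e2, q)
    if t < -eps or t > 1.0 + eps:
        return None
    return p0 + t * d


def detect_ring_piercing(conf: Conformer):
    """Find bonds whose segment passes through the interior of a ring.

    Each ring is triangulated as a fan about its centroid, so puckered
    (non-planar) rings are handled. Bonds sharing an atom with the ring are
    skipped. Returns a list of ``(bond, ring, intersection_point)`` tuples.
    """
    results = []
    for ring in conf.rings:
        pts = np.array([conf.position(i) for i in ring])
        centroid = pts.mean(axis=0)
        # degenerate ring: total fan area ~ 0
        area = 0.0
        n = len(ring)
        for k in range(n):
            area += 0.5 * np.linalg.norm(
                np.cross(pts[k] - centroid, pts[(k + 1) % n] - centroid)
            )
        if area < 1e-6:
            continue
        ring_set = set(ring)
        for bond in conf.bonds:
            if bond[0] in ring_set or bond[1] in ring_set:
                continue
            p0 = conf.position(bond[0])
            p1 = conf.position(bond[1])
            for k in range(n):
                hit = _segment_triangle_intersection(
                    p0, p1, centroid, pts[k], pts[(k + 1) % n]
                )
                if hit is not None:
                    results.append((tuple(bond), list(ring), hit))
                    break
    return results


def mitigation_exclusions(conf: Conformer, piercings) -> ExclusionList:
    """Build the nonbonded-exclusion list mitigating detected piercings.

    For each piercing the two atoms of the piercing bond are paired with the
    three ring atoms closest to the intersection point: six pairs per
    piercing, de-duplicated across piercings.
    """
    excl = ExclusionList()
    for bond, ring, point in piercings:
        dists = [(np.linalg.norm(conf.position(r) - point), r) for r in ring]
        nearest = [r for _, r in sorted(dists)[:3]]
        for b in bond:
            for r in nearest:
                excl.add(b, r)
    return excl


# ---------------------------------------------------------------------------
# restraint potentials


def campaign_duration_us(n_sequences: int = 4, n_stages: int = 3,
                         n_replicates: int = 16,
                         ns_per_run: float = 100.0) -> float:
    """Aggregate simulated time (μs) of a holding-stage campaign: sequences
    × stages × replicates × run length."""
    return n_sequences * n_stages * n_replicates * ns_per_run / 1000.0


def field_from_bias(bias_mV: float, gap_nm: float) -> float:
    """Uniform-field magnitude (V/m) of a bias across an electrode gap."""
    if gap_nm <= 0:
        raise ValueError("gap must be positive")
    return (bias_mV * 1e-3) / (gap_nm * 1e-9)


def _unit_and_grad(u):
    """Unit vector of u and the Jacobian d(û)/d(u) = (I - û ûᵀ)/|u|."""
    n = np.linalg.norm(u)
    uh = u / n
    jac = (np.eye(3) - np.outer(uh, uh)) / n
    return uh, jac


def restraint_energy_forces(conf: Conformer, charges: Sequence[float] | None,
                            spec: RestraintSpec):
    """Total junction restraint energy and analytic per-atom forces.

    Three terms:

    * anchor restraint ``U = ½ k (s - d)²`` with ``s`` the anchor-anchor
      separation projected on the pulling axis (signed, anchor₀ → anchor₁),
    * field term ``U = -Σᵢ qᵢ E zᵢ`` with ``zᵢ`` the axial coordinate —
      a uniform field of magnitude E along the axis acting on partial
      charges,
    * orientation term ``U = Σ_S k_orient (1 - cos θ_S)`` where θ_S is the
      angle between the mean lone-pair direction of anchoring sulfur S
      (opposite the bisector of its two substituent bonds) and the outward
      electrode direction along the axis.

    Returns ``(energy_kcal_mol, forces)`` with forces shaped (n_atoms, 3).
    """
    n = len(conf.atoms)
    forces = np.zeros((n, 3))
    axis = spec.pulling_axis
    energy = 0.0

    # (1) anchor separation restraint
    i0 = conf.index_of(spec.anchor_atom_ids[0])
    i1 = conf.index_of(spec.anchor_atom_ids[1])
    s = float(np.dot(axis, conf.coords[i1] - conf.coords[i0]))
    dev = s - spec.stage_target_A
    energy += 0.5 * spec.k_anchor * dev * dev
    g = spec.k_anchor * dev * axis  # dU/dr1 = k dev * axis; dU/dr0 = -that
    forces[i1] -= g
    forces[i0] += g

    # (2) uniform field on partial charges
    if spec.field_V_per_m != 0.0:
        if charges is None or len(charges) != n:
            raise ValueError("a charge is required for every atom under the field term")
        q = np.asarray(charges, dtype=float)
        if not np.all(np.isfinite(q)):
            raise ValueError("charges must be finite")
        scale = spec.field_V_per_m * _EV_PER_M_ANG_TO_KCAL  # kcal/mol per Å per e
        z = conf.coords @ axis
        energy += float(-np.sum(q * scale * z))
        forces += np.outer(q * scale, axis)

    # (3) lone-pair orientation of the anchoring sulfurs
    if spec.k_orient != 0.0:
        # outward direction: the anchor with the larger axial coordinate
        # points along +axis, the other along -axis
        z0 = float(np.dot(axis, conf.coords[i0]))
        z1 = float(np.dot(axis, conf.coords[i1]))
        outward = {
            spec.anchor_atom_ids[0]: axis if z0 >= z1 else -axis,
            spec.anchor_atom_ids[1]: axis if z1 > z0 else -axis,
        }
        for s_id, (a1, a2) in spec.lone_pair_reference_atoms.items():
            e_dir = outward.get(s_id)
            if e_dir is None:
                raise ValueError(f"lone-pair reference given for non-anchor atom {s_id}")
            iS = conf.index_of(s_id)
            ia1 = conf.index_of(a1)
            ia2 = conf.index_of(a2)
            u1 = conf.coords[ia1] - conf.coords[iS]
            u2 = conf.coords[ia2] - conf.coords[iS]
            u1h, j1 = _unit_and_grad(u1)
            u2h, j2 = _unit_and_grad(u2)
            v = -(u1h + u2h)  # mean lone-pair direction (unnormalized)
            vn = np.linalg.norm(v)
            if vn < 1e-12:
                continue  # substituents antiparallel: direction undefined
            w = v / vn
            cos_t = float(np.dot(w, e_dir))
            energy += spec.k_orient * (1.0 - cos_t)
            # dcos/dv, then chain through v = -(û1 + û2)
            dcos_dv = (e_dir - cos_t * w) / vn
            g1 = -(j1 @ dcos_dv)   # dcos/d(u1)
            g2 = -(j2 @ dcos_dv)
            # F = -dU/dr = +k_orient * dcos/dr
            forces[ia1] += spec.k_orient * g1
            forces[ia2] += spec.k_orient * g2
            forces[iS] -= spec.k_orient * (g1 + g2)

    return energy, forces
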
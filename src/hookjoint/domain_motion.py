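"""Rigid-domain motion decomposition between subunit conformations.

Each of the 11 protofilaments carries its own subunit conformation; the
differences are rigid rearrangements of well-preserved domains.  Motions
are measured by least-squares (Kabsch) superposition: the inner D0–Dc
domains of two conformers are superposed, and the residual rigid transform
of each outer domain (D1, D2) is decomposed into a rotation angle ("tilt")
and a translation, whose component along the local tube axis is the axial
shift ("shift up").  The tilt is the full residual rotation angle, not a
projected angle.  Subunit length is the extent of the Cα projections onto
the local protofilament direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, DegenerateInputError
from .lattice import HelicalLattice
from .structure_io import DomainDefinition, SubunitModel, assign_domains

logger = logging.getLogger("hookjoint.domain_motion")

__all__ = [
    "RigidTransform",
    "DomainMotion",
    "ConformationClasses",
    "kabsch_superpose",
    "conformation_classes",
    "relative_domain_motion",
    "subunit_length",
    "extension",
    "domain_axis_tilt",
]


# --------------------------------------------------------------------------
# Rigid transforms
# --------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Proper rotation plus translation, y = R·x + t (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @property
    def angle_deg(self) -> float:
        """Rotation angle θ = arccos((trace − 1)/2), in [0°, 180°]."""
        cos = float(np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0))
        return float(np.degrees(np.arccos(cos)))

    @property
    def axis(self) -> np.ndarray:
        """Unit rotation axis (arbitrary for θ = 0)."""
        rv = Rotation.from_matrix(self.rotation).as_rotvec()
        n = np.linalg.norm(rv)
        return rv / n if n > 0 else np.array([0.0, 0.0, 1.0])

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray
                     ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns the transform that minimizes the RMSD of ``moving`` onto
    ``fixed`` and that RMSD (Å).  Requires ≥ 3 non-collinear points.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be equal-shape (n, 3) arrays")
    n = len(moving)
    if n < 3:
        raise DegenerateInputError("need ≥ 3 paired points")
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    m0, f0 = moving - mc, fixed - fc
    if (np.linalg.matrix_rank(m0, tol=1e-8) < 2
            or np.linalg.matrix_rank(f0, tol=1e-8) < 2):
        raise DegenerateInputError("collinear or coincident point set")
    rot, rssd = Rotation.align_vectors(f0, m0)
    R = rot.as_matrix()
    t = fc - R @ mc
    rmsd = float(rssd / np.sqrt(n))
    return RigidTransform(R, t), rmsd


# --------------------------------------------------------------------------
# Conformation classes
# --------------------------------------------------------------------------

@dataclass
class ConformationClasses:
    """Protofilament-wise grouping of subunit conformations."""

    n_classes: int
    representative: dict[int, str]          # protofilament → chain id
    within_rmsd: dict[int, float]           # max pairwise RMSD inside a class
    between_rmsd: Mapping[tuple[int, int], float]  # adjacent representatives
    conformationally_uniform: bool          # all classes mutually ~identical
    warnings: list[str] = field(default_factory=list)


def _common_ca(a: SubunitModel, b: SubunitModel) -> tuple[np.ndarray, np.ndarray]:
    common = np.intersect1d(a.residue_numbers, b.residue_numbers)
    return a.ca_of(common), b.ca_of(common)


def pairwise_rmsd(a: SubunitModel, b: SubunitModel) -> float:
    """All-Cα RMSD of two subunits after optimal superposition."""
    ca, cb = _common_ca(a, b)
    return kabsch_superpose(ca, cb)[1]


def conformation_classes(subunits: Sequence[SubunitModel],
                         lattice: HelicalLattice,
                         rmsd_tol: float = 0.8,
                         uniform_tol: float = 0.1) -> ConformationClasses:
    """Group subunits into per-protofilament conformation classes.

    Subunits of one protofilament are expected to share a conformation
    (within ``rmsd_tol`` all-Cα RMSD; violations are reported as warnings,
    not failures).  The representative of each class is the member closest
    to the segment's axial middle.  If even between-class RMSDs stay below
    ``uniform_tol`` the assembly is conformationally uniform (straight
    form) and flagged as such.
    """
    by_chain = {s.chain_id: s for s in subunits}
    chain_of_k = lattice.chain_of_k
    s_vals = lattice.axial_position
    s_mid = float(np.median(list(s_vals.values())))
    members = lattice.protofilament_members()
    reps: dict[int, str] = {}
    within: dict[int, float] = {}
    warn: list[str] = []
    for p, ks in members.items():
        reps[p] = chain_of_k[min(ks, key=lambda k: abs(s_vals[k] - s_mid))]
        worst = 0.0
        for i, ka in enumerate(ks):
            for kb in ks[i + 1:]:
                worst = max(worst, pairwise_rmsd(by_chain[chain_of_k[ka]],
                                                 by_chain[chain_of_k[kb]]))
        within[p] = worst
        if worst > rmsd_tol:
            warn.append(f"protofilament {p}: within-class RMSD "
                        f"{worst:.2f} Å exceeds {rmsd_tol} Å")
    pf_ids = sorted(reps)
    between = {}
    for i, p in enumerate(pf_ids):
        q = pf_ids[(i + 1) % len(pf_ids)]
        between[(p, q)] = pairwise_rmsd(by_chain[reps[p]], by_chain[reps[q]])
    uniform = bool(between) and max(between.values()) < uniform_tol
    for w in warn:
        logger.warning(w)
    return ConformationClasses(n_classes=len(reps), representative=reps,
                               within_rmsd=within, between_rmsd=between,
                               conformationally_uniform=uniform, warnings=warn)


# --------------------------------------------------------------------------
# Relative domain motions
# --------------------------------------------------------------------------

@dataclass
class DomainMotion:
    """Residual motion of each domain after superposing the reference domain.

    ``domains`` maps domain name → (RigidTransform, tilt °, axial shift Å);
    the reference domain's own residuals double as a sanity check (they
    must be ≈ identity).
    """

    reference_chain: str
    target_chain: str
    reference_domain: str
    domains: dict[str, dict]
    d0c_residual_angle_deg: float
    d0c_residual_shift: float

    def tilt(self, domain: str) -> float:
        return self.domains[domain]["tilt_deg"]

    def shift(self, domain: str) -> float:
        return self.domains[domain]["axial_shift"]


def relative_domain_motion(conf_a: SubunitModel, conf_b: SubunitModel,
                           defs: Sequence[DomainDefinition],
                           axis_direction: np.ndarray,
                           reference_domain: str = "D0c") -> DomainMotion:
    """Domain motions of ``conf_b`` relative to ``conf_a``.

    ``conf_b`` is superposed onto ``conf_a`` by the reference (inner)
    domain; the residual per-domain transforms then quantify how the outer
    domains move when the protofilament switches conformation.  The axial
    shift is the domain-centroid displacement projected on the local tube
    axis, positive toward the distal (+axis) end.
    """
    axis_direction = np.asarray(axis_direction, float)
    axis_direction = axis_direction / np.linalg.norm(axis_direction)
    doms_a = assign_domains(conf_a, defs)
    doms_b = assign_domains(conf_b, defs)
    names = [d.name for d in defs]
    if reference_domain not in names:
        raise ConfigurationError(f"no reference domain {reference_domain!r}")
    for name in names:
        if doms_a[name].size == 0 or doms_b[name].size == 0:
            raise ConfigurationError(f"domain {name!r} has no residues")

    ref_common = np.intersect1d(doms_a[reference_domain], doms_b[reference_domain])
    ref_tf, _ = kabsch_superpose(conf_b.ca_of(ref_common),
                                 conf_a.ca_of(ref_common))
    b_sup = conf_b.transformed(ref_tf.rotation, ref_tf.translation)

    domains: dict[str, dict] = {}
    for name in names:
        common = np.intersect1d(doms_a[name], doms_b[name])
        ca_a = conf_a.ca_of(common)
        ca_b = b_sup.ca_of(common)
        tf, rmsd = kabsch_superpose(ca_a, ca_b)   # motion taking a → b
        shift = float(np.dot(ca_b.mean(axis=0) - ca_a.mean(axis=0),
                             axis_direction))
        domains[name] = {"transform": tf, "tilt_deg": tf.angle_deg,
                         "axial_shift": shift, "superposition_rmsd": rmsd}
    ref = domains[reference_domain]
    return DomainMotion(reference_chain=conf_a.chain_id,
                        target_chain=conf_b.chain_id,
                        reference_domain=reference_domain,
                        domains=domains,
                        d0c_residual_angle_deg=ref["tilt_deg"],
                        d0c_residual_shift=abs(ref["axial_shift"]))


# --------------------------------------------------------------------------
# Subunit length
# --------------------------------------------------------------------------

def subunit_length(sub: SubunitModel, axis_direction: np.ndarray) -> float:
    """Extent (max − min) of the Cα projections on the protofilament
    direction (Å)."""
    u = np.asarray(axis_direction, float)
    u = u / np.linalg.norm(u)
    proj = sub.ca @ u
    return float(proj.max() - proj.min())


def extension(conf_a: SubunitModel, conf_b: SubunitModel,
              axis_direction: np.ndarray) -> float:
    """Length change ΔL = length(conf_b) − length(conf_a) (Å).

    With the compressed conformer as ``conf_a`` and the extended one as
    ``conf_b`` this is the overall subunit length extension.
    """
    return (subunit_length(conf_b, axis_direction)
            - subunit_length(conf_a, axis_direction))


def domain_axis_tilt(sub: SubunitModel, defs: Sequence[DomainDefinition],
                     domain: str, axis_direction: np.ndarray) -> float:
    """Angle (°) between a domain's longest principal axis (Cα inertia)
    and the local tube axis, folded into [0°, 90°]."""
    doms = assign_domains(sub, defs)
    if doms.get(domain) is None or doms[domain].size < 3:
        raise ConfigurationError(f"domain {domain!r} missing or too small")
    ca = sub.ca_of(doms[domain])
    ca = ca - ca.mean(axis=0)
    principal = np.linalg.svd(ca, full_matrices=False)[2][0]
    u = np.asarray(axis_direction, float)
    u = u / np.linalg.norm(u)
    cos = abs(float(np.dot(principal, u)))
    return float(np.degrees(np.arccos(np.clip(cos, 0.0, 1.0))))
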
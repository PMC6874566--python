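"""Coarse-grained synthetic hook assemblies with known ground truth.

The generator emulates the geometry of the flagellar hook at pseudo-atom
resolution: 11 protofilaments, a 1-start helical lattice with ≈65.45° twist
and ≈4.145 Å rise per subunit (11 subunits per axial repeat of
d0 = 45.6 Å), and three radial layers standing in for the D0–Dc "tube",
D1 "mesh" and D2 "spring" domains.  A supercoiled assembly is produced by
bending the straight lattice onto a circular-helix centerline using a
parallel-transport (twist-free) frame, with the straight axial coordinate
taken as arclength.  That mapping realizes elastic bending exactly: the
local axial stretch of a material point at radius ρ and material azimuth φ
is 1 − κ·ρ·cos(φ − φc(s)), where φc(s) = τ·s is the azimuth of the bend
center, which precesses through the material at the centerline torsion rate
(the "smoke ring" rotation of the lattice through the supercoil).

Every generated assembly comes with a :class:`GroundTruth` record (lattice
bookkeeping, centerline, closed-form expected spacings) so that each
analysis stage can be verified by parameter recovery without external data.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .structure_io import DomainDefinition, SubunitModel

__all__ = [
    "Layer",
    "Hinge",
    "SyntheticSpec",
    "GroundTruth",
    "generate_straight",
    "generate_supercoiled",
    "apply_hinge",
    "add_noise",
    "native_spec",
    "straight_spec",
    "random_spec",
]

_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


def chain_id_for(k: int) -> str:
    """Deterministic chain identifier for 1-start index ``k``."""
    if k < len(_CHAIN_ALPHABET):
        return _CHAIN_ALPHABET[k]
    return f"x{k}"


# --------------------------------------------------------------------------
# Specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Layer:
    """One radial pseudo-domain layer of the template subunit."""

    name: str
    radius: float          # Å, distance of the cluster center from the tube axis
    n_atoms: int
    spread: float          # Å, cluster diameter scale (atom SD = spread / 2)
    z_offset: float = 0.0  # Å, axial offset of the cluster center


@dataclass(frozen=True)
class Hinge:
    """Rigid rotation of one layer about a circumferential axis at its base,
    optionally combined with a pure axial shift (domain-motion fixture)."""

    layer: str
    tilt_deg: float
    axial_shift: float = 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a generated assembly (the recovery oracle).

    Defaults reproduce the hook lattice: start number 11, 1-start twist
    720/11° (11 subunits span exactly two turns), axial repeat
    d0 = 45.6 Å along each protofilament, and three layers at radii
    25/45/70 Å.  ``pitch``/``radius`` parameterize the supercoil
    (1290 Å / 165 Å for the native left-handed form).
    """

    n_subunits: int = 26
    start_number: int = 11
    twist_deg: float = 720.0 / 11.0
    rise: float = 45.6 / 11.0
    layers: tuple[Layer, ...] = (
        Layer("D0c", 25.0, 30, 6.0),
        Layer("D1", 45.0, 40, 8.0),
        Layer("D2", 70.0, 35, 8.0),
    )
    pitch: float | None = None      # Å; None → straight assembly
    radius: float | None = None     # Å; None → straight assembly
    handedness: str = "left"
    hinge: Hinge | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValidationError("n_subunits must be ≥ 1")
        if self.start_number < 2:
            raise ValidationError("start_number must be ≥ 2")
        if self.rise <= 0 or self.twist_deg <= 0:
            raise ValidationError("rise and twist must be positive")
        radii = [l.radius for l in self.layers]
        if any(r <= 0 for r in radii) or any(
                b <= a for a, b in zip(radii, radii[1:])):
            raise ValidationError("layer radii must be positive and strictly increasing")
        if (self.pitch is None) != (self.radius is None):
            raise ValidationError("pitch and radius must be given together")
        if self.pitch is not None and (self.pitch <= 0 or self.radius <= 0):
            raise ValidationError("pitch and radius must be positive")
        if self.handedness not in ("left", "right"):
            raise ValidationError("handedness must be 'left' or 'right'")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be ≥ 0")
        if self.hinge is not None and abs(self.hinge.tilt_deg) > 45.0:
            raise ValidationError("hinge angle outside [-45°, 45°]")

    # -- derived quantities --------------------------------------------

    @property
    def d0(self) -> float:
        """Straight-form axial repeat along a protofilament (Å)."""
        return self.start_number * self.rise

    @property
    def reduced_pitch(self) -> float | None:
        return None if self.pitch is None else self.pitch / (2.0 * np.pi)

    @property
    def kappa(self) -> float:
        """Centerline curvature of the supercoil (Å⁻¹); 0 for straight."""
        if self.pitch is None:
            return 0.0
        h, R = self.reduced_pitch, self.radius
        return R / (R * R + h * h)

    @property
    def tau(self) -> float:
        """Signed centerline torsion (Å⁻¹); negative for left-handed."""
        if self.pitch is None:
            return 0.0
        h, R = self.reduced_pitch, self.radius
        sign = -1.0 if self.handedness == "left" else 1.0
        return sign * h / (R * R + h * h)

    def domain_definitions(self) -> tuple[DomainDefinition, ...]:
        """Layer-wise residue ranges (layers occupy contiguous ranges)."""
        defs, start = [], 1
        for layer in self.layers:
            defs.append(DomainDefinition(layer.name,
                                         ((start, start + layer.n_atoms - 1),)))
            start += layer.n_atoms
        return tuple(defs)

    def layer_of_residue(self, residue: int) -> str:
        for d in self.domain_definitions():
            if d.contains(residue):
                return d.name
        raise KeyError(residue)


# --------------------------------------------------------------------------
# Template
# --------------------------------------------------------------------------

def _template(spec: SyntheticSpec) -> np.ndarray:
    """Pseudo-atom cloud of the reference subunit at azimuth 0, height 0.

    One atom per residue; layer ``i`` occupies the contiguous residue range
    declared by :meth:`SyntheticSpec.domain_definitions`.  The cloud is a
    frozen function of the spec seed.
    """
    rng = np.random.default_rng(int(spec.seed) % (2 ** 31))
    coords = []
    for layer in spec.layers:
        center = np.array([layer.radius, 0.0, layer.z_offset])
        coords.append(center + rng.normal(0.0, layer.spread / 2.0,
                                          size=(layer.n_atoms, 3)))
    return np.concatenate(coords, axis=0)


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _subunit_from_coords(chain_id: str, coords: np.ndarray) -> SubunitModel:
    n = len(coords)
    return SubunitModel(
        chain_id=chain_id,
        residue_numbers=np.arange(1, n + 1),
        residue_names=["ALA"] * n,
        atoms=[{"CA": coords[i].copy()} for i in range(n)],
    )


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Bookkeeping and closed-form expectations for a generated assembly."""

    spec: SyntheticSpec
    k_of_chain: dict[str, int]
    protofilament_of_chain: dict[str, int]   # raw id: (k mod S) + 1
    template: np.ndarray
    kappa: float
    tau: float
    centerline: Callable[[np.ndarray], np.ndarray] | None = None
    layer_xy_mean: dict[str, tuple[float, float]] = field(default_factory=dict)

    def expected_spacing(self, rho: float, phi_material: float,
                         s_mid: float) -> float:
        """Elastic-bending axial repeat at material radius ``rho``.

        ``phi_material`` is the azimuth in the straight material frame and
        ``s_mid`` the arclength of the pair midpoint; the bend-center
        azimuth precesses as φc(s) = τ·s.
        """
        d0 = self.spec.d0
        return d0 * (1.0 - self.kappa * rho
                     * np.cos(phi_material - self.tau * s_mid))

    def expected_layer_spacing(self, layer: str, k: int) -> float:
        """Expected layer-mean spacing for the axial pair (k, k+S)."""
        spec = self.spec
        xbar, ybar = self.layer_xy_mean[layer]
        s_mid = (k + spec.start_number / 2.0) * spec.rise
        psi = np.deg2rad(spec.twist_deg) * k - self.tau * s_mid
        return spec.d0 * (1.0 - self.kappa * (xbar * np.cos(psi) - ybar * np.sin(psi)))

    def spacing_table(self) -> pd.DataFrame:
        """Expected per-(protofilament, layer) spacing, averaged over pairs."""
        spec = self.spec
        rows = []
        for chain, k in self.k_of_chain.items():
            if k + spec.start_number not in self.k_of_chain.values():
                continue
            for layer in spec.layers:
                rows.append({
                    "protofilament_raw": k % spec.start_number + 1,
                    "k": k,
                    "layer": layer.name,
                    "expected_spacing": self.expected_layer_spacing(layer.name, k),
                })
        df = pd.DataFrame(rows)
        return (df.groupby(["protofilament_raw", "layer"], as_index=False)
                  ["expected_spacing"].mean())


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------

def generate_straight(spec: SyntheticSpec) -> tuple[list[SubunitModel], GroundTruth]:
    """Straight tubular assembly: subunit k at azimuth k·Δφ, height k·Δz."""
    template = _template(spec)
    dphi = np.deg2rad(spec.twist_deg)
    subunits = []
    k_of_chain, pf_of_chain = {}, {}
    for k in range(spec.n_subunits):
        coords = template @ _rot_z(k * dphi).T + np.array([0.0, 0.0, k * spec.rise])
        cid = chain_id_for(k)
        subunits.append(_subunit_from_coords(cid, coords))
        k_of_chain[cid] = k
        pf_of_chain[cid] = k % spec.start_number + 1
    gt = GroundTruth(spec=spec, k_of_chain=k_of_chain,
                     protofilament_of_chain=pf_of_chain, template=template,
                     kappa=0.0, tau=0.0,
                     centerline=lambda s: np.column_stack(
                         [np.zeros_like(s), np.zeros_like(s), np.asarray(s, float)]),
                     layer_xy_mean=_layer_xy_means(spec, template))
    if spec.hinge is not None:
        subunits = apply_hinge(subunits, gt, spec.hinge)
    if spec.noise_sd > 0:
        subunits = add_noise(subunits, spec.noise_sd, spec.seed + 1)
    return subunits, gt


def _layer_xy_means(spec: SyntheticSpec, template: np.ndarray) -> dict[str, tuple[float, float]]:
    out, start = {}, 0
    for layer in spec.layers:
        block = template[start:start + layer.n_atoms]
        out[layer.name] = (float(block[:, 0].mean()), float(block[:, 1].mean()))
        start += layer.n_atoms
    return out


def _helix_frame(s: np.ndarray, R: float, h: float, sigma: float):
    """Centerline point and parallel-transport frame of a circular helix.

    ``sigma`` = +1 for right-handed, −1 for left-handed.  The straight axial
    coordinate is interpreted as arclength ``s``; t = s/c is the helix phase
    with c = √(R²+h²).
    """
    c = np.hypot(R, h)
    t = np.asarray(s, float) / c
    cos_t, sin_t = np.cos(t), np.sin(t)
    C = np.column_stack([R * cos_t, sigma * R * sin_t, h * t])
    T = np.column_stack([-R * sin_t, sigma * R * cos_t, np.full_like(t, h)]) / c
    N = np.column_stack([-cos_t, -sigma * sin_t, np.zeros_like(t)])
    B = np.cross(T, N)
    tau = sigma * h / (c * c)
    theta = tau * np.asarray(s, float)
    cth, sth = np.cos(theta)[:, None], np.sin(theta)[:, None]
    E1 = cth * N - sth * B
    E2 = sth * N + cth * B
    return C, E1, E2


def generate_supercoiled(spec: SyntheticSpec) -> tuple[list[SubunitModel], GroundTruth]:
    """Bend the straight lattice onto a superhelical centerline.

    Material point (x, y, z) of the straight assembly maps to
    C(z) + x·E1(z) + y·E2(z), where C is the circular helix of pitch P and
    radius R and (E1, E2) its parallel-transport normal frame.  Because the
    frame is twist-free, the only lattice deformation is elastic bending.
    """
    if spec.pitch is None:
        raise ValidationError("spec has no supercoil parameters; use generate_straight")
    template = _template(spec)
    r_max = np.hypot(template[:, 0], template[:, 1]).max()
    if spec.kappa * r_max >= 1.0:
        raise ValidationError(
            f"unphysical compression: κ·r_max = {spec.kappa * r_max:.3f} ≥ 1")

    straight_spec_ = replace(spec, pitch=None, radius=None,
                             hinge=None, noise_sd=0.0)
    subunits, gt0 = generate_straight(straight_spec_)
    R, h = spec.radius, spec.reduced_pitch
    sigma = -1.0 if spec.handedness == "left" else 1.0

    def bend(xyz: np.ndarray) -> np.ndarray:
        C, E1, E2 = _helix_frame(xyz[:, 2], R, h, sigma)
        return C + xyz[:, 0:1] * E1 + xyz[:, 1:2] * E2

    bent = [sub.map_coords(bend) for sub in subunits]

    def centerline(s: np.ndarray) -> np.ndarray:
        C, _, _ = _helix_frame(np.asarray(s, float), R, h, sigma)
        return C

    gt = GroundTruth(spec=spec, k_of_chain=gt0.k_of_chain,
                     protofilament_of_chain=gt0.protofilament_of_chain,
                     template=template, kappa=spec.kappa, tau=spec.tau,
                     centerline=centerline,
                     layer_xy_mean=gt0.layer_xy_mean)
    if spec.noise_sd > 0:
        bent = add_noise(bent, spec.noise_sd, spec.seed + 1)
    return bent, gt


def apply_hinge(subunits: Sequence[SubunitModel], gt: GroundTruth,
                hinge: Hinge,
                target_protofilaments: Sequence[int] | None = None
                ) -> list[SubunitModel]:
    """Rotate one layer of the targeted subunits about a circumferential axis.

    The pivot sits at the layer centroid in (x, y) and at the layer's lowest
    z (its "base"), so a pure tilt leaves the layer's axial position
    essentially unchanged while reorienting it; ``hinge.axial_shift`` then
    translates the layer along the tube axis.  Defined for straight
    assemblies (the fixture geometry for domain-motion recovery).
    """
    if gt.kappa != 0.0:
        raise ValidationError("apply_hinge operates on straight assemblies")
    if abs(hinge.tilt_deg) > 45.0:
        raise ValidationError("hinge angle outside [-45°, 45°]")
    layer_names = [l.name for l in gt.spec.layers]
    if hinge.layer not in layer_names:
        raise ValidationError(f"no such layer {hinge.layer!r}")
    domain = next(d for d in gt.spec.domain_definitions() if d.name == hinge.layer)
    targets = (set(target_protofilaments) if target_protofilaments is not None
               else set(gt.protofilament_of_chain.values()))

    out = []
    for sub in subunits:
        if gt.protofilament_of_chain.get(sub.chain_id) not in targets:
            out.append(sub)
            continue
        mask = np.array([domain.contains(int(r)) for r in sub.residue_numbers])
        layer_ca = sub.ca[mask]
        cx, cy = layer_ca[:, 0].mean(), layer_ca[:, 1].mean()
        pivot = np.array([cx, cy, layer_ca[:, 2].min()])
        radial = np.array([cx, cy, 0.0])
        radial /= np.linalg.norm(radial)
        axis = np.cross([0.0, 0.0, 1.0], radial)  # circumferential direction
        axis /= np.linalg.norm(axis)
        from scipy.spatial.transform import Rotation
        Rm = Rotation.from_rotvec(np.deg2rad(hinge.tilt_deg) * axis).as_matrix()
        shift = np.array([0.0, 0.0, hinge.axial_shift])
        atoms = []
        for i, res in enumerate(sub.atoms):
            if mask[i]:
                atoms.append({name: (Rm @ (xyz - pivot)) + pivot + shift
                              for name, xyz in res.items()})
            else:
                atoms.append({name: xyz.copy() for name, xyz in res.items()})
        out.append(SubunitModel(sub.chain_id, sub.residue_numbers.copy(),
                                list(sub.residue_names), atoms))
    return out


def add_noise(subunits: Sequence[SubunitModel], sd: float,
              seed: int) -> list[SubunitModel]:
    """Isotropic Gaussian displacement of every atom; reproducible per seed."""
    if sd < 0:
        raise ValidationError("noise sd must be ≥ 0")
    if sd == 0:
        return list(subunits)
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    return [sub.map_coords(lambda xyz: xyz + rng.normal(0.0, sd, xyz.shape))
            for sub in subunits]


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------

def native_spec(n_subunits: int = 26, seed: int = 0,
               noise_sd: float = 0.0) -> SyntheticSpec:
    """Native supercoil conditions: pitch 1290 Å, radius 165 Å, left-handed."""
    return SyntheticSpec(n_subunits=n_subunits, pitch=1290.0, radius=165.0,
                         handedness="left", seed=seed, noise_sd=noise_sd)


def straight_spec(n_subunits: int = 26, seed: int = 0,
                  noise_sd: float = 0.0) -> SyntheticSpec:
    """Straight-form reference lattice."""
    return SyntheticSpec(n_subunits=n_subunits, seed=seed, noise_sd=noise_sd)


def random_spec(rng: np.random.Generator, n_subunits: int = 44,
                noise_sd: float = 0.3) -> SyntheticSpec:
    """Random supercoil in the recovery-suite parameter box."""
    return SyntheticSpec(
        n_subunits=n_subunits,
        pitch=float(rng.uniform(800.0, 1800.0)),
        radius=float(rng.uniform(80.0, 250.0)),
        handedness=str(rng.choice(["left", "right"])),
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )
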
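"""Helical-lattice indexing: 1-start ordering, neighbor maps, protofilaments.

The hook lattice is described by its 1-start helix: consecutive subunits
advance by ≈65.45° in azimuth and ≈4.15 Å along the tube axis, so subunits
k and k+11 stack axially in the same protofilament and k+5 / k+6 are the
remaining nearest lattice directions.  Indexing proceeds in three steps:
estimate the (possibly curved) tube axis as a sliding-window centroid
polyline, order subunits by arclength along that axis, and check that the
azimuthal steps are consistent with a single-start helix before assigning
protofilament identities p(k) = k mod S.

Azimuths are measured in a parallel-transported frame carried along the
axis polyline, so they remain comparable between the two ends of a curved
segment.  The axis is oriented so that the 1-start azimuthal step is
positive (right-handed 1-start), which fixes the ordering origin at the
axially lowest subunit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import IndexingError, InsufficientDataError
from .structure_io import SubunitModel

logger = logging.getLogger("hookjoint.lattice")

__all__ = [
    "HelicalLattice",
    "estimate_tube_axis",
    "index_lattice",
    "renumber_protofilaments",
    "axis_frames",
    "project_to_polyline",
]

NEIGHBOR_OFFSETS = (5, 6, 11)

#: Circular standard deviation (degrees) of consecutive 1-start azimuthal
#: steps above which the arrangement is rejected as non-lattice.  The
#: expected step is ≈65.45° with bending-induced modulation well below this.
AZIMUTH_STEP_SD_LIMIT = 15.0


# --------------------------------------------------------------------------
# Axis polyline machinery
# --------------------------------------------------------------------------

def estimate_tube_axis(subunits: Sequence[SubunitModel],
                       window: int = 11) -> np.ndarray:
    """Tube-axis polyline from sliding-window means of subunit centroids.

    With ``window`` equal to the start number, each window covers the full
    circumference (11 subunits span exactly two 1-start turns), so the
    radial components cancel and the window mean falls on the tube axis.
    Returns an (n_subunits − window + 1, 3) polyline ordered tip-to-tip.
    """
    if len(subunits) < window:
        raise InsufficientDataError(
            f"need ≥ {window} subunits for axis estimation, got {len(subunits)}")
    centroids = np.array([s.centroid() for s in subunits])
    order = _order_by_lattice(centroids)
    if len(centroids) >= window + 1:
        return _window_means(centroids[order], window)
    # degenerate single-window case: synthesize a two-vertex axis along the
    # fitted cylinder direction through the window mean
    u = _cylinder_axis_direction(centroids)
    s = centroids @ u
    v = centroids.mean(axis=0)
    half = max(0.5 * (s.max() - s.min()), 1.0)
    return np.vstack([v - half * u, v + half * u])


def _order_by_lattice(centroids: np.ndarray, window: int = 11) -> np.ndarray:
    """Order subunit centroids along the tube by 1-start lattice decoding.

    Projection onto a straight chord axis misranks subunits near the ends
    of a curved segment (the off-axis ring offset leaks into the axial
    coordinate by up to ±r·sin(κ·L/2), more than one rise).  The azimuth
    carries the complementary information — consecutive subunits step by
    the 1-start twist — so the 1-start index is recovered by jointly
    fitting both cylindrical coordinates to the lattice model
    s ≈ s0 + k·Δz, φ ≈ φ0 + k·Δφ (mod 2π) and decoding k per subunit.

    Two stages: a first decode against the straight chord axis, then
    refinement rounds in which the curved axis polyline is rebuilt from
    the current ordering and the coordinates re-measured against it, until
    the assignment is self-consistent.
    """
    n = len(centroids)
    order = _chord_decode_order(centroids)
    # Refinement against the curved axis implied by the current ordering.
    # The window polyline is only trustworthy where the ordering already
    # is, so a refined ordering is accepted only if it improves the global
    # lattice consistency (circular SD of the 1-start azimuthal steps).
    if n >= window + 1:
        best_order, best_score = order, _ordering_score(centroids, order, window)
        for _ in range(4):
            # Build the reference axis from the trusted middle of the
            # current ordering: chord-decode errors concentrate at the
            # ends, and a core polyline extrapolated along its end
            # tangents measures end azimuths far more faithfully than a
            # polyline contaminated by misordered end windows.
            trim = int(0.15 * n)
            core = order[trim:n - trim] if n - 2 * trim >= window + 1 else order
            poly = _window_means(centroids[core], window)
            s, phi, _ = _cylindrics_about_polyline(centroids, poly)
            k = np.argsort(order, kind="stable").astype(float)  # position of each
            k = _decode_indices(s, phi, k)
            new_order = np.lexsort((s, k))
            score = _ordering_score(centroids, new_order, window)
            if score < best_score:
                best_order, best_score = new_order, score
            if np.array_equal(new_order, order):
                break
            order = new_order
        order = best_order
    return order


def _ordering_score(centroids: np.ndarray, order: np.ndarray,
                    window: int) -> float:
    """Lattice-consistency score of an ordering: circular SD (degrees) of
    consecutive azimuthal steps about the ordering's own window polyline."""
    poly = _window_means(centroids[order], window)
    if len(poly) < 2:
        return np.inf
    _, phi, _ = _cylindrics_about_polyline(centroids[order], poly)
    steps = np.diff(phi)
    steps = np.arctan2(np.sin(steps), np.cos(steps))
    return _circular_sd_deg(steps - steps.mean())


#: Segment size above which chord-based decoding splits recursively: the
#: straight-chord lattice model degrades once a piece subtends too large a
#: bend angle, and ~30 subunits keeps each piece within its validity for
#: curvatures up to the physical compression limit.
_CHORD_PIECE_LIMIT = 30


def _chord_decode_order(centroids: np.ndarray) -> np.ndarray:
    """1-start ordering by chord-frame decoding, divide-and-conquer.

    Short segments are decoded directly against their chord axis.  Longer
    segments are split into two overlapping halves along the chord, each
    half ordered recursively, and the two index sets stitched by the
    median index offset over the shared subunits (with a reversal check).
    """
    n = len(centroids)
    if n <= _CHORD_PIECE_LIMIT:
        return _chord_decode_single(centroids)
    u = _cylinder_axis_direction(centroids)
    s = (centroids - centroids.mean(axis=0)) @ u
    by_s = np.argsort(s, kind="stable")
    cut = int(np.ceil(0.6 * n))
    idx_a = by_s[:cut]
    idx_b = by_s[n - cut:]
    order_a = idx_a[_chord_decode_order(centroids[idx_a])]
    order_b = idx_b[_chord_decode_order(centroids[idx_b])]
    k_a = {int(i): pos for pos, i in enumerate(order_a)}
    k_b = {int(i): pos for pos, i in enumerate(order_b)}
    shared = sorted(set(k_a) & set(k_b))
    ka = np.array([k_a[i] for i in shared], float)
    kb = np.array([k_b[i] for i in shared], float)
    if len(shared) >= 2 and np.corrcoef(ka, kb)[0, 1] < 0:
        order_b = order_b[::-1]
        k_b = {int(i): pos for pos, i in enumerate(order_b)}
        kb = np.array([k_b[i] for i in shared], float)
    offset = float(np.median(ka - kb))
    k_full = dict(k_a)
    for i, pos in k_b.items():
        if i not in k_full:
            k_full[i] = pos + offset
    items = sorted(k_full.items(), key=lambda kv: (kv[1], s[kv[0]]))
    return np.array([i for i, _ in items])


def _chord_decode_single(centroids: np.ndarray) -> np.ndarray:
    """Decode one chord-scale piece (see :func:`_order_by_lattice`)."""
    n = len(centroids)
    u = _cylinder_axis_direction(centroids)
    local = centroids - centroids.mean(axis=0)
    s = local @ u
    v = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, u)) > 0.9:
        v = np.array([0.0, 1.0, 0.0])
    v = v - np.dot(v, u) * u
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    phi = np.arctan2(local @ w, local @ v)
    k = np.argsort(np.argsort(s, kind="stable"), kind="stable").astype(float)
    s_corr = s.copy()
    for _ in range(6):
        k = _decode_indices(s_corr, phi, k)
        s_corr = s - _ring_axial_leak(s, phi, k)
    return np.lexsort((s_corr, k))


def _ring_axial_leak(s: np.ndarray, phi: np.ndarray,
                     k: np.ndarray) -> np.ndarray:
    """Systematic leak of the off-axis ring offset into the chord-axis
    axial coordinate of a curved segment.

    Where the true axis deviates laterally from the chord (offset δ(s),
    tangent tilt ≈ κ·(s − s̄)), a subunit's ring offset ρ·(cos φ, sin φ)
    projects onto the chord with error ≈ ρ·tilt·cos(φ − φ_bend) — bilinear
    in (1, s − s̄) × (cos φ, sin φ).  That form is fitted robustly against
    the current lattice assignment and returned for subtraction.
    """
    n = len(s)
    A = np.column_stack([np.ones(n), k])
    coef0, *_ = np.linalg.lstsq(A, s, rcond=None)
    e = s - A @ coef0
    sb = s - s.mean()
    X = np.column_stack([np.cos(phi), np.sin(phi),
                         sb * np.cos(phi), sb * np.sin(phi)])
    w = np.ones(n)
    for _ in range(2):
        cf, *_ = np.linalg.lstsq(X * w[:, None], e * w, rcond=None)
        r = e - X @ cf
        mad = np.median(np.abs(r)) + 1e-9
        w = (np.abs(r) < 5 * mad).astype(float)
    return X @ cf


def _decode_indices(s: np.ndarray, phi: np.ndarray, k: np.ndarray) -> np.ndarray:
    """One round of lattice-index decoding from cylindrical coordinates.

    The azimuthal residual is decisive: two indices share an azimuth only
    at offsets of a full 1-start repeat (k ± S), far beyond the axial
    uncertainty, whereas the axial estimate can be off by more than one
    rise near curved ends.  The axial term only breaks near-ties.
    """
    n = len(s)
    order = np.argsort(k, kind="stable")
    dphi = np.diff(phi[order])
    dphi = np.arctan2(np.sin(dphi), np.cos(dphi))
    step = float(np.arctan2(np.median(np.sin(dphi)), np.median(np.cos(dphi))))
    if abs(step) < 1e-6:
        return k  # no azimuthal progression; keep axial ranking
    dz = float(np.median(np.diff(np.sort(s))))
    if dz <= 0:
        dz = max((s.max() - s.min()) / max(n - 1, 1), 1e-6)
    res0 = phi - step * k
    phi0 = float(np.arctan2(np.sin(res0).mean(), np.cos(res0).mean()))
    s0 = float(np.mean(s - dz * k))
    # Candidates stay within ±4 ranks of the axial estimate: the nearest
    # azimuthal look-alike in an 11-start lattice sits 5 ranks away (its
    # azimuth differs by only 720/11 − 360/11 ≈ 32.7°), while the axial
    # estimate is never off by more than ~3 ranks, so capping the window
    # at ±4 rules the alias out without risking the true index.
    cands = np.arange(-4, 5)
    knew = np.empty(n)
    for i in range(n):
        kc = np.round((s[i] - s0) / dz) + cands
        r_ax = (s[i] - s0 - kc * dz) / dz
        r_az = phi[i] - phi0 - step * kc
        r_az = np.arctan2(np.sin(r_az), np.cos(r_az)) / abs(step)
        knew[i] = kc[np.argmin(r_az ** 2 + 0.01 * r_ax ** 2)]
    return knew


def _cylindrics_about_polyline(points: np.ndarray, polyline: np.ndarray
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(s, φ, r) of each point about a polyline, transported-frame azimuths."""
    T, E1, E2 = axis_frames(polyline)
    seg = np.diff(polyline, axis=0)
    s_out, phi_out, r_out = np.empty(len(points)), np.empty(len(points)), np.empty(len(points))
    for idx, p in enumerate(points):
        s, i, t = project_to_polyline(p, polyline)
        foot = polyline[i] + t * seg[i]
        w = float(np.clip(t, 0.0, 1.0))
        j = min(i + 1, len(polyline) - 1)
        Tf = (1 - w) * T[i] + w * T[j]
        Tf /= np.linalg.norm(Tf)
        e1 = (1 - w) * E1[i] + w * E1[j]
        e1 = e1 - np.dot(e1, Tf) * Tf
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(Tf, e1)
        vv = p - foot
        vv = vv - np.dot(vv, Tf) * Tf
        s_out[idx] = s
        phi_out[idx] = np.arctan2(np.dot(vv, e2), np.dot(vv, e1))
        r_out[idx] = np.linalg.norm(vv)
    return s_out, phi_out, r_out


def _cylinder_axis_direction(points: np.ndarray) -> np.ndarray:
    """Axis direction of the best-fitting cylinder through ``points``.

    A short tube segment is nearly as wide as it is long, so no principal
    component of the point cloud can be trusted on its own.  Instead the
    axis is found by least squares: the line about which the spread of
    point-to-line distances is minimal (all subunits sit at the same tube
    radius).  All three principal directions seed the optimization and the
    best fit wins.
    """
    from scipy.optimize import least_squares

    center = points.mean(axis=0)
    local = points - center
    axes = np.linalg.svd(local, full_matrices=False)[2]

    def unpack(x):
        theta, phi, p1, p2 = x
        u = np.array([np.sin(theta) * np.cos(phi),
                      np.sin(theta) * np.sin(phi),
                      np.cos(theta)])
        v = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            v = np.array([0.0, 1.0, 0.0])
        v = v - np.dot(v, u) * u
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        base = p1 * v + p2 * w
        return u, base

    def residuals(x):
        u, base = unpack(x)
        rel = local - base
        radial = rel - np.outer(rel @ u, u)
        d = np.linalg.norm(radial, axis=1)
        return d - d.mean()

    best = None
    for u0 in axes:
        theta0 = float(np.arccos(np.clip(u0[2], -1.0, 1.0)))
        phi0 = float(np.arctan2(u0[1], u0[0]))
        fit = least_squares(residuals, x0=[theta0, phi0, 0.0, 0.0],
                            method="lm", max_nfev=2000)
        if best is None or fit.cost < best.cost:
            best = fit
    return unpack(best.x)[0]


def _window_means(ordered_centroids: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.column_stack([
        np.convolve(ordered_centroids[:, i], kernel, mode="valid")
        for i in range(3)])


def _radius_spread(centroids: np.ndarray, polyline: np.ndarray) -> float:
    """SD of centroid-to-polyline distances; small for a correct ordering
    (all subunits sit at the same tube radius)."""
    if len(polyline) < 2:
        return np.inf
    d = [np.linalg.norm(c - polyline, axis=1).min() for c in centroids]
    return float(np.std(d))


def _polyline_tangents(polyline: np.ndarray) -> np.ndarray:
    diffs = np.gradient(polyline, axis=0)
    norms = np.linalg.norm(diffs, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise InsufficientDataError("degenerate axis polyline (repeated vertices)")
    return diffs / norms


def axis_frames(polyline: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangents plus a parallel-transported normal basis along a polyline.

    Returns (T, E1, E2), each (n, 3).  E1 is seeded perpendicular to the
    first tangent and transported vertex-to-vertex by the minimal rotation
    aligning consecutive tangents, so the basis carries no spurious twist.
    """
    T = _polyline_tangents(polyline)
    n = len(polyline)
    E1 = np.empty_like(T)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, T[0])) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e = seed - np.dot(seed, T[0]) * T[0]
    E1[0] = e / np.linalg.norm(e)
    for i in range(1, n):
        axis = np.cross(T[i - 1], T[i])
        s = np.linalg.norm(axis)
        c = float(np.clip(np.dot(T[i - 1], T[i]), -1.0, 1.0))
        if s < 1e-12:
            e = E1[i - 1]
        else:
            axis = axis / s
            angle = np.arctan2(s, c)
            e = (E1[i - 1] * np.cos(angle)
                 + np.cross(axis, E1[i - 1]) * np.sin(angle)
                 + axis * np.dot(axis, E1[i - 1]) * (1 - np.cos(angle)))
        e = e - np.dot(e, T[i]) * T[i]
        E1[i] = e / np.linalg.norm(e)
    E2 = np.cross(T, E1)
    return T, E1, E2


def project_to_polyline(point: np.ndarray, polyline: np.ndarray
                        ) -> tuple[float, int, float]:
    """Project a point onto a polyline.

    Returns ``(s, segment index, t)`` where ``s`` is the arclength of the
    foot point and ``t`` the (possibly extrapolated, on end segments) local
    parameter within the segment.
    """
    seg = np.diff(polyline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best = (np.inf, 0, 0.0)
    for i in range(len(seg)):
        t = np.dot(point - polyline[i], seg[i]) / (seg_len[i] ** 2)
        t_eval = float(np.clip(t, 0.0, 1.0))
        foot = polyline[i] + t_eval * seg[i]
        d = np.linalg.norm(point - foot)
        if d < best[0]:
            best = (d, i, t_eval)
    _, i, t = best
    # extrapolate only for points genuinely beyond the polyline ends;
    # interior points must never project onto an end segment's extension
    # (at high curvature that line can pass close to off-axis points)
    if i == 0 and t == 0.0:
        t = float(np.dot(point - polyline[0], seg[0]) / (seg_len[0] ** 2))
        t = min(t, 0.0)
    elif i == len(seg) - 1 and t == 1.0:
        t = float(np.dot(point - polyline[i], seg[i]) / (seg_len[i] ** 2))
        t = max(t, 1.0)
    return float(cum[i] + t * seg_len[i]), i, t


# --------------------------------------------------------------------------
# Lattice type
# --------------------------------------------------------------------------

@dataclass
class HelicalLattice:
    """1-start ordering, neighbor maps and protofilament assignment."""

    order: dict[str, int]                  # chain id → 1-start index k (0-based)
    start_number: int
    neighbor_maps: dict[int, dict[int, int]]   # offset → {k: k+offset}
    protofilament: dict[int, int]          # k → protofilament id (1..S)
    axis: np.ndarray                       # polyline (m, 3), Å
    axial_position: dict[int, float]       # k → arclength s_k, Å
    azimuth: dict[int, float]              # k → φ_k, radians (transported frame)
    radius: dict[int, float]               # k → centroid radius, Å

    @property
    def chain_of_k(self) -> dict[int, str]:
        return {k: c for c, k in self.order.items()}

    @property
    def n_subunits(self) -> int:
        return len(self.order)

    def protofilament_members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for k, p in self.protofilament.items():
            out.setdefault(p, []).append(k)
        return {p: sorted(ks) for p, ks in out.items()}

    def protofilament_azimuth(self) -> dict[int, float]:
        """Circular-mean material azimuth of each protofilament (radians)."""
        out = {}
        for p, ks in self.protofilament_members().items():
            phis = np.array([self.azimuth[k] for k in ks])
            out[p] = float(np.arctan2(np.sin(phis).mean(), np.cos(phis).mean()))
        return out

    def local_axis_direction(self, s: float) -> np.ndarray:
        """Unit tangent of the axis polyline at arclength ``s``."""
        seg = np.diff(self.axis, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        i = int(np.clip(np.searchsorted(cum, s) - 1, 0, len(seg) - 1))
        return seg[i] / seg_len[i]

    def to_json_dict(self) -> dict:
        return {
            "start_number": self.start_number,
            "order": self.order,
            "protofilament": {str(k): p for k, p in self.protofilament.items()},
            "neighbor_maps": {str(off): {str(k): v for k, v in m.items()}
                              for off, m in self.neighbor_maps.items()},
            "axial_position_A": {str(k): round(s, 4)
                                 for k, s in self.axial_position.items()},
            "azimuth_rad": {str(k): round(a, 6) for k, a in self.azimuth.items()},
            "axis_polyline_A": np.round(self.axis, 4).tolist(),
        }


# --------------------------------------------------------------------------
# Indexing
# --------------------------------------------------------------------------

def _circular_sd_deg(angles_rad: np.ndarray) -> float:
    z = np.exp(1j * angles_rad)
    Rbar = abs(z.mean())
    Rbar = min(max(Rbar, 1e-12), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(Rbar))))


def _measure_cylindrics(subunits: Sequence[SubunitModel],
                        polyline: np.ndarray):
    """Per-subunit (chain id, arclength, azimuth, radius) along a polyline.

    Azimuths use the parallel-transported frame, so they are mutually
    comparable along a curved axis.  The input order is preserved.
    """
    pts = np.array([sub.centroid() for sub in subunits])
    s, phi, r = _cylindrics_about_polyline(pts, polyline)
    return [(sub.chain_id, float(s[i]), float(phi[i]), float(r[i]))
            for i, sub in enumerate(subunits)]


def index_lattice(subunits: Sequence[SubunitModel],
                  start_number: int = 11) -> HelicalLattice:
    """Assign 1-start indices, neighbor maps and protofilament identities.

    Subunits are ordered along the estimated tube axis by 1-start lattice
    decoding of their axial/azimuthal coordinates; the ordering origin is
    anchored at the end subunit with the smaller chain identifier.  An
    arrangement whose azimuthal steps scatter by more than
    ``AZIMUTH_STEP_SD_LIMIT`` (circular SD) is rejected.
    """
    if len(subunits) < start_number:
        raise InsufficientDataError(
            f"need ≥ {start_number} subunits, got {len(subunits)}")
    centroids = np.array([s.centroid() for s in subunits])
    order_idx = _order_by_lattice(centroids)
    # Polarity: the azimuthal step sign is a chirality, identical from both
    # ends, so geometry cannot decide which end is k = 0.  Anchor the
    # orientation deterministically on chain identifiers: the end subunit
    # with the lexicographically smaller chain id becomes the origin.
    if subunits[order_idx[-1]].chain_id < subunits[order_idx[0]].chain_id:
        order_idx = order_idx[::-1]
    ordered = [subunits[i] for i in order_idx]
    window = min(start_number, len(subunits))
    if len(subunits) >= window + 1:
        polyline = _window_means(centroids[order_idx], window)
    else:
        polyline = estimate_tube_axis(subunits, window=window)
        # orient the synthesized two-vertex axis to match the ordering
        d = ordered[-1].centroid() - ordered[0].centroid()
        if np.dot(polyline[-1] - polyline[0], d) < 0:
            polyline = polyline[::-1].copy()
    records = _measure_cylindrics(ordered, polyline)
    steps = np.array([records[i + 1][2] - records[i][2]
                      for i in range(len(records) - 1)])
    steps = np.arctan2(np.sin(steps), np.cos(steps))

    sd = _circular_sd_deg(steps - steps.mean())
    if sd > AZIMUTH_STEP_SD_LIMIT:
        worst = np.argsort(-np.abs(steps - np.median(steps)))[:3]
        offenders = [records[i + 1][0] for i in worst]
        raise IndexingError(
            f"azimuthal steps inconsistent with a 1-start lattice "
            f"(circular SD {sd:.1f}° > {AZIMUTH_STEP_SD_LIMIT}°); "
            f"worst offenders: {offenders}")

    order = {rec[0]: k for k, rec in enumerate(records)}
    axial = {k: rec[1] for k, rec in enumerate(records)}
    azim = {k: rec[2] for k, rec in enumerate(records)}
    radius = {k: rec[3] for k, rec in enumerate(records)}
    n = len(records)
    neighbor_maps = {off: {k: k + off for k in range(n - off)}
                     for off in NEIGHBOR_OFFSETS}
    protofilament = {k: k % start_number + 1 for k in range(n)}
    logger.info("indexed %d subunits; azimuthal step %.2f° (SD %.2f°)",
                n, np.degrees(steps.mean()), sd)
    return HelicalLattice(order=order, start_number=start_number,
                          neighbor_maps=neighbor_maps,
                          protofilament=protofilament, axis=polyline,
                          axial_position=axial, azimuth=azim, radius=radius)


# --------------------------------------------------------------------------
# Protofilament renumbering
# --------------------------------------------------------------------------

def renumber_protofilaments(lattice: HelicalLattice,
                            pf_mean_spacing: dict[int, float],
                            tie_tol: float = 1e-6) -> HelicalLattice:
    """Renumber protofilaments by the extension convention.

    The protofilament with the largest mean axial spacing becomes id 1
    (most extended, outside of the bend); ids then increase consecutively
    around the circumference in the direction that places the smaller of
    the two opposite-side means at id 7, so the most compressed
    protofilaments land at ids 6–7.  Ties on the largest mean are broken
    deterministically by lowest azimuth.

    ``pf_mean_spacing`` maps current protofilament ids to their mean axial
    Cα spacing (from the protofilament-geometry stage).
    """
    S = lattice.start_number
    az = lattice.protofilament_azimuth()
    ids = sorted(az)
    if len(ids) != S:
        raise InsufficientDataError(
            f"renumbering needs all {S} protofilaments, got {len(ids)}")
    means = np.array([pf_mean_spacing[p] for p in ids])
    best = means.max()
    cand = [p for p, m in zip(ids, means) if best - m <= tie_tol]
    if len(cand) > 1:
        logger.warning("tie in largest mean spacing among %s; using lowest azimuth",
                       cand)
        anchor = min(cand, key=lambda p: az[p] % (2 * np.pi))
    else:
        anchor = cand[0]

    ring = sorted(ids, key=lambda p: az[p] % (2 * np.pi))
    i0 = ring.index(anchor)
    fwd = ring[i0:] + ring[:i0]
    bwd = [fwd[0]] + list(reversed(fwd[1:]))
    # choose the direction that puts the smaller mean at slot 7 (index 6)
    m = dict(zip(ids, means))
    choice = fwd if m[fwd[6]] <= m[bwd[6]] else bwd
    mapping = {p: i + 1 for i, p in enumerate(choice)}
    new_pf = {k: mapping[p] for k, p in lattice.protofilament.items()}
    logger.info("protofilament renumbering: %s", mapping)
    return replace(lattice, protofilament=new_pf)
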
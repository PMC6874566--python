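"""End-to-end orchestration: analyze, synthesize, recover, report.

``analyze`` runs the full measurement chain on one assembly — lattice
indexing, protofilament spacing profile, conformation classes and domain
motions, supercoil estimation, contact variability — and writes a bundle
of CSV/JSON outputs plus a single summary JSON echoing the headline
numbers.  ``recover`` is the parameter-recovery harness: a seeded suite of
random synthetic supercoils, each pushed through the pipeline and compared
against its generator ground truth.

All lengths are Å internally; nm appears only in serialized reports.
Every output records the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import contacts as contacts_mod
from . import synthetic as synth_mod
from .domain_motion import (conformation_classes, extension,
                            relative_domain_motion, subunit_length)
from .errors import HookjointError
from .lattice import index_lattice, renumber_protofilaments
from .protofilament import (D0_REFERENCE_SPACING, axial_distance_map,
                            bending_consistency, domain_mean_distances)
from .structure_io import (DEFAULT_FLGE_DOMAINS, DomainDefinition,
                           SubunitModel, read_assembly, write_assembly,
                           write_table)
from .supercoil import (centerline_curvature_torsion, fit_coiled_tube,
                        fit_coiled_tube_template, fit_helix_lsq,
                        helix_from_kappa_tau)

logger = logging.getLogger("hookjoint.pipeline")

__all__ = ["RunConfig", "analyze", "recover", "load_domains"]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

def load_domains(spec: dict | Sequence[DomainDefinition] | None
                 ) -> tuple[DomainDefinition, ...]:
    """Domain definitions from a mapping {name: [[lo, hi], ...]} (or pass
    through an existing definition sequence).  None → FlgE defaults."""
    if spec is None:
        return DEFAULT_FLGE_DOMAINS
    if isinstance(spec, dict):
        return tuple(DomainDefinition(name, tuple(map(tuple, ranges)))
                     for name, ranges in spec.items())
    return tuple(spec)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    input_path: str | None = None
    domains: tuple[DomainDefinition, ...] = DEFAULT_FLGE_DOMAINS
    start_number: int = 11
    contact_cutoff: float = contacts_mod.DEFAULT_CONTACT_CUTOFF
    d0: float = D0_REFERENCE_SPACING
    output_dir: str = "hookjoint_out"
    seed: int = 0
    verbosity: int = 1
    n_bootstrap: int = 50
    n_recovery_specs: int = 20

    def validate(self) -> None:
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)
        if self.start_number < 2:
            raise HookjointError("start_number must be ≥ 2")
        if self.contact_cutoff < 0 or self.d0 <= 0:
            raise HookjointError("cutoff must be ≥ 0 and d0 > 0")

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        # the hash identifies the scientific configuration, not where the
        # outputs land or how chatty the logs are
        payload.pop("output_dir")
        payload.pop("verbosity")
        payload["domains"] = [(d.name, list(map(list, d.ranges)))
                              for d in self.domains]
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def metadata(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed,
                "units": "angstrom unless suffixed _nm"}


# --------------------------------------------------------------------------
# Analysis bundle
# --------------------------------------------------------------------------

def _bend_azimuth(pf_means: dict[int, float], pf_azimuth: dict[int, float],
                  d0: float) -> tuple[float, float]:
    """Bend-center azimuth φc and modulation amplitude from per-
    protofilament means, by linear regression of d_p on cos/sin(φ_p)."""
    pfs = sorted(pf_means)
    y = np.array([pf_means[p] for p in pfs])
    phi = np.array([pf_azimuth[p] for p in pfs])
    X = np.column_stack([np.ones_like(phi), np.cos(phi), np.sin(phi)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    amp = float(np.hypot(coef[1], coef[2]))
    phic = float(np.arctan2(-coef[2], -coef[1]))  # d = a - B·cos(φ - φc)
    return phic, amp


def analyze(config: RunConfig,
            subunits: Sequence[SubunitModel] | None = None) -> dict:
    """Run the full measurement chain; returns the summary dict.

    ``subunits`` may be passed directly (e.g. a synthetic assembly);
    otherwise they are read from ``config.input_path``.
    """
    config.validate()
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = config.metadata()

    if subunits is None:
        if config.input_path is None:
            raise HookjointError("no input assembly")
        subunits = read_assembly(config.input_path)
    subunits = list(subunits)

    def stage(name):
        logger.info("stage %s", name)

    # ---- lattice ------------------------------------------------------
    stage("lattice")
    lattice = index_lattice(subunits, start_number=config.start_number)

    # ---- protofilament profile ---------------------------------------
    stage("profile")
    profile = axial_distance_map(subunits, lattice, d0=config.d0)
    if len(set(lattice.protofilament.values())) == config.start_number:
        relabeled = renumber_protofilaments(lattice,
                                            profile.per_protofilament_mean())
        mapping = {lattice.protofilament[k]: relabeled.protofilament[k]
                   for k in lattice.protofilament}
        lattice = relabeled
        profile = profile.relabeled(mapping)
    (outdir / "lattice.json").write_text(json.dumps(
        {**meta, **lattice.to_json_dict()}, indent=1))
    write_table(profile.table, outdir / "profile.csv", metadata=meta)

    d_min, p_min, r_min = profile.global_min()
    d_max, p_max, r_max = profile.global_max()
    pf_means = profile.per_protofilament_mean()

    domain_means = domain_mean_distances(profile, config.domains)
    write_table(domain_means.reset_index(names="domain"),
                outdir / "domain_means.csv", metadata=meta)
    bending = bending_consistency(profile, config.domains)
    write_table(bending.reset_index(), outdir / "bending_consistency.csv",
                metadata=meta)

    # ---- conformation classes & domain motions -----------------------
    stage("domain_motion")
    classes = conformation_classes(subunits, lattice)
    by_chain = {s.chain_id: s for s in subunits}
    compressed_pf = min(pf_means, key=pf_means.get)
    extended_pf = max(pf_means, key=pf_means.get)
    s_of = lattice.axial_position
    k_comp = lattice.order[classes.representative[compressed_pf]]
    axis_dir = lattice.local_axis_direction(s_of[k_comp])
    conf_comp = by_chain[classes.representative[compressed_pf]]
    conf_ext = by_chain[classes.representative[extended_pf]]
    motions_all = {}
    if not classes.conformationally_uniform:
        for p in sorted(classes.representative):
            for q in sorted(classes.representative):
                if p == q:
                    continue
                dm = relative_domain_motion(by_chain[classes.representative[p]],
                                            by_chain[classes.representative[q]],
                                            config.domains, axis_dir)
                motions_all[f"{p}->{q}"] = {
                    name: {"tilt_deg": v["tilt_deg"],
                           "axial_shift_A": v["axial_shift"]}
                    for name, v in dm.domains.items()}
        headline = relative_domain_motion(conf_comp, conf_ext,
                                          config.domains, axis_dir)
        delta_len = extension(conf_comp, conf_ext, axis_dir)
    else:
        headline, delta_len = None, 0.0
    (outdir / "domain_motions.json").write_text(json.dumps(
        {**meta, "pairs": motions_all}, indent=1))

    # ---- supercoil ----------------------------------------------------
    stage("supercoil")
    kappa_d, tau_d, _, _ = centerline_curvature_torsion(lattice.axis)
    discrete = helix_from_kappa_tau(kappa_d, tau_d)
    phic, amp = _bend_azimuth(pf_means, lattice.protofilament_azimuth(),
                              config.d0)
    straight = amp < 0.02 * config.d0   # < 2% modulation: no supercoil signal
    if straight:
        params = helix_from_kappa_tau(0.0, 0.0)
    else:
        params = fit_helix_lsq(lattice.axis, discrete,
                               n_bootstrap=config.n_bootstrap)
        params = _refine_with_tube_model(subunits, lattice, params,
                                         domains=config.domains)
        phi1 = lattice.protofilament_azimuth()[extended_pf]
        params.phi0 = float(np.arctan2(np.sin(phic - phi1),
                                       np.cos(phic - phi1)))
    (outdir / "supercoil.json").write_text(json.dumps(
        {**meta, **params.to_json_dict(),
         "discrete_estimate": discrete.to_json_dict()}, indent=1))

    # ---- contacts & variability --------------------------------------
    stage("contacts")
    variability = {}
    for direction in (5, 6, 11):
        try:
            table = contacts_mod.find_contacts(subunits, lattice, direction,
                                               cutoff=config.contact_cutoff)
            write_table(table.table, outdir / f"contacts_{direction}.csv",
                        metadata=meta)
            rv = contacts_mod.residue_variability(subunits, lattice, direction)
            variability[direction] = {
                "min_sd_residue": rv.min_sd_residue(),
                "max_sd_residue": rv.max_sd_residue(),
                "per_domain": rv.domain_summary(
                    config.domains, subunits[0]).to_dict(orient="index"),
            }
        except HookjointError as exc:
            logger.warning("contacts +%d skipped: %s", direction, exc)
    (outdir / "variability.json").write_text(json.dumps(
        {**meta, "directions": variability}, indent=1))

    gap = {}
    try:
        gap = {
            "extended": contacts_mod.d1_triangle_gap(
                subunits, lattice, extended_pf, config.domains),
            "compressed": contacts_mod.d1_triangle_gap(
                subunits, lattice, compressed_pf, config.domains),
        }
    except HookjointError as exc:
        logger.warning("triangle gap skipped: %s", exc)

    # ---- summary ------------------------------------------------------
    summary = {
        **meta,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_subunits": len(subunits),
        "n_protofilaments": len(set(lattice.protofilament.values())),
        "n_conformation_classes": classes.n_classes,
        "conformationally_uniform": classes.conformationally_uniform,
        "straight": straight,
        "spacing": {
            "global_min_A": d_min, "global_min_protofilament": p_min,
            "global_max_A": d_max, "global_max_protofilament": p_max,
            "modulation_amplitude_A": amp,
            "per_protofilament_mean_A": {str(p): v
                                         for p, v in sorted(pf_means.items())},
            "domain_means_A": {str(d): {str(p): float(v)
                                        for p, v in row.items()}
                               for d, row in domain_means.iterrows()},
            "bending_midpoints_A": {str(d): float(r["midpoint"])
                                    for d, r in bending.iterrows()},
            "d0_A": config.d0,
        },
        "supercoil": params.to_json_dict(),
        "domain_motion_compressed_to_extended": (
            {name: {"tilt_deg": v["tilt_deg"],
                    "axial_shift_A": v["axial_shift"]}
             for name, v in headline.domains.items()}
            if headline is not None else None),
        "subunit_length_extension_A": delta_len,
        "d1_triangle_gap": gap,
        "runtime_s": round(time.time() - t_start, 2),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary




def _refine_with_tube_model(subunits, lattice, params, domains=None):
    """Coiled-tube refinement of the supercoil fit.

    With domain definitions available, each subunit contributes one
    material-ring point per radial layer (layer Cα centroids), so the fit
    sees the differential bending stretch across radii; otherwise the
    whole-subunit centroids form a single ring.
    """
    from .structure_io import assign_domains

    by_chain = {s.chain_id: s for s in subunits}
    ks = sorted(lattice.axial_position)
    points, k_idx, groups = [], [], []
    for k in ks:
        sub = by_chain[lattice.chain_of_k[k]]
        added = False
        if domains:
            assigned = assign_domains(sub, domains)
            for g, dom in enumerate(domains):
                members = assigned[dom.name]
                if members.size >= 5:
                    points.append(sub.ca_of(members).mean(axis=0))
                    k_idx.append(k)
                    groups.append(g)
                    added = True
        if not added:
            points.append(sub.centroid())
            k_idx.append(k)
            groups.append(len(domains) if domains else 0)
    steps = np.diff([lattice.azimuth[k] for k in ks])
    steps = np.arctan2(np.sin(steps), np.cos(steps))
    delta0 = float(np.mean(steps))
    dz0 = float(np.mean(np.diff([lattice.axial_position[k] for k in ks])))
    ring_fit = fit_coiled_tube(np.array(points), np.array(k_idx, dtype=float),
                               params, delta0=delta0, dz0=dz0,
                               groups=np.array(groups))
    # atom-level refinement with an estimated reference subunit
    coords, k_all, res_all = [], [], []
    res_ids = {}
    for k in ks:
        sub = by_chain[lattice.chain_of_k[k]]
        for num, xyz in zip(sub.residue_numbers, sub.ca):
            coords.append(xyz)
            k_all.append(k)
            res_all.append(res_ids.setdefault(int(num), len(res_ids)))
    refined = fit_coiled_tube_template(
        np.array(coords), np.array(k_all, dtype=float),
        np.array(res_all), ring_fit, delta0=delta0, dz0=dz0)
    return refined


# --------------------------------------------------------------------------
# Recovery harness
# --------------------------------------------------------------------------

#: Recovery thresholds: relative error bounds on pitch/radius, exactness of
#: handedness and lattice indexing, spacing amplitude vs closed form.
RECOVERY_PITCH_TOL = 0.03
RECOVERY_RADIUS_TOL = 0.03
RECOVERY_AMPLITUDE_TOL = 0.05


def _recover_one(spec: synth_mod.SyntheticSpec) -> dict:
    subunits, gt = synth_mod.generate_supercoiled(spec)
    row = {"pitch_A": spec.pitch, "radius_A": spec.radius,
           "handedness": spec.handedness, "noise_sd": spec.noise_sd,
           "seed": spec.seed}
    try:
        lattice = index_lattice(subunits, spec.start_number)
    except HookjointError as exc:
        row.update(indexing_exact=False, error=str(exc), passed=False)
        return row
    row["indexing_exact"] = all(lattice.order[c] == k
                                for c, k in gt.k_of_chain.items())
    kappa_d, tau_d, _, _ = centerline_curvature_torsion(lattice.axis)
    fit = fit_helix_lsq(lattice.axis, helix_from_kappa_tau(kappa_d, tau_d))
    fit = _refine_with_tube_model(subunits, lattice, fit,
                                  domains=spec.domain_definitions())
    row["pitch_rel_err"] = abs(fit.pitch - spec.pitch) / spec.pitch
    row["radius_rel_err"] = abs(fit.radius - spec.radius) / spec.radius
    row["handedness_ok"] = fit.handedness == spec.handedness

    profile = axial_distance_map(subunits, lattice, d0=spec.d0)
    measured = domain_mean_distances(profile, spec.domain_definitions())
    expected = gt.spacing_table().pivot(index="layer",
                                        columns="protofilament_raw",
                                        values="expected_spacing")
    amp_err = 0.0
    for layer in measured.index:
        m = measured.loc[layer]
        e = expected.loc[layer]
        m_amp = (m.max() - m.min()) / 2.0
        e_amp = (e.max() - e.min()) / 2.0
        if e_amp > 0:
            amp_err = max(amp_err, abs(m_amp - e_amp) / e_amp)
    row["amplitude_rel_err"] = amp_err
    row["passed"] = bool(row["indexing_exact"] and row["handedness_ok"]
                         and row["pitch_rel_err"] <= RECOVERY_PITCH_TOL
                         and row["radius_rel_err"] <= RECOVERY_RADIUS_TOL
                         and amp_err <= RECOVERY_AMPLITUDE_TOL)
    return row


def recover(config: RunConfig) -> tuple[pd.DataFrame, bool]:
    """Seeded random-supercoil recovery suite; returns (table, all passed)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_recovery_specs):
        spec = synth_mod.random_spec(rng)
        row = _recover_one(spec)
        row["spec_index"] = i
        rows.append(row)
    table = pd.DataFrame(rows)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(table, outdir / "recovery.csv", metadata=config.metadata())
    ok = bool(table["passed"].all())
    logger.info("recovery: %d/%d specs passed", int(table["passed"].sum()),
                len(table))
    return table, ok
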
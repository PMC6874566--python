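"""Structure input/output and domain bookkeeping.

Assemblies are handled as lists of :class:`SubunitModel`, one per polymer
chain, holding residue-indexed Cα and heavy-atom coordinates in Å.  Files are
read and written through :mod:`gemmi`, which understands both the mmCIF and
PDB dialects; tabular results go out as CSV/JSON with a JSON metadata sidecar
describing columns and units.

Residue numbering follows the author numbering of the coordinate file
(1-based, inclusive ranges) because domain boundaries in the hook literature
are quoted in author numbers.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyAssemblyError, FormatError

logger = logging.getLogger("hookjoint.structure_io")

__all__ = [
    "SubunitModel",
    "DomainDefinition",
    "DEFAULT_FLGE_DOMAINS",
    "read_assembly",
    "write_assembly",
    "write_table",
    "assign_domains",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class SubunitModel:
    """One polymer chain: ordered residues with Cα and heavy-atom coordinates.

    Parameters
    ----------
    chain_id : str
        Chain identifier as found in (or destined for) the coordinate file.
    residue_numbers : ndarray of int
        Author residue numbers, strictly increasing.
    residue_names : list of str
        Three-letter residue codes, parallel to ``residue_numbers``.
    atoms : list of dict
        Per residue, mapping atom name → coordinate (3-vector, Å).  Heavy
        atoms only; every residue must carry a ``CA`` entry.
    """

    chain_id: str
    residue_numbers: np.ndarray
    residue_names: list[str]
    atoms: list[dict[str, np.ndarray]]
    _ca_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        n = len(self.residue_numbers)
        if n == 0:
            raise ValueError(f"chain {self.chain_id!r}: no residues")
        if len(self.residue_names) != n or len(self.atoms) != n:
            raise ValueError(f"chain {self.chain_id!r}: field lengths disagree")
        if np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError(
                f"chain {self.chain_id!r}: residue numbers not strictly increasing"
            )
        for num, res in zip(self.residue_numbers, self.atoms):
            if "CA" not in res:
                raise ValueError(f"chain {self.chain_id!r}: residue {num} lacks CA")
        if not np.isfinite(self.ca).all():
            raise ValueError(f"chain {self.chain_id!r}: non-finite coordinates")

    # -- views ----------------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    @property
    def ca(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates, Å, in residue order."""
        if self._ca_cache is None:
            self._ca_cache = np.array([r["CA"] for r in self.atoms], dtype=float)
        return self._ca_cache

    def ca_of(self, residues: Iterable[int]) -> np.ndarray:
        """Cα coordinates of the given author residue numbers, in given order."""
        index = {int(n): i for i, n in enumerate(self.residue_numbers)}
        rows = [index[int(r)] for r in residues]
        return self.ca[rows]

    def centroid(self) -> np.ndarray:
        """Unweighted mean of all Cα coordinates (rigid-subunit reference point)."""
        return self.ca.mean(axis=0)

    def heavy_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy-atom coordinates and the residue number of each atom.

        Returns ``(coords (m,3), residue_numbers (m,))``.
        """
        coords, resnums = [], []
        for num, res in zip(self.residue_numbers, self.atoms):
            for xyz in res.values():
                coords.append(xyz)
                resnums.append(num)
        return np.asarray(coords, dtype=float), np.asarray(resnums, dtype=int)

    def map_coords(self, fn: Callable[[np.ndarray], np.ndarray]) -> "SubunitModel":
        """Return a copy with ``fn`` applied to the (m, 3) stack of all atoms."""
        flat = []
        for res in self.atoms:
            for name, xyz in res.items():
                flat.append(xyz)
        flat = fn(np.asarray(flat, dtype=float))
        out, i = [], 0
        for res in self.atoms:
            new = {}
            for name in res:
                new[name] = flat[i].copy()
                i += 1
            out.append(new)
        return SubunitModel(self.chain_id, self.residue_numbers.copy(),
                            list(self.residue_names), out)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SubunitModel":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return self.map_coords(lambda xyz: xyz @ R.T + t)


@dataclass(frozen=True)
class DomainDefinition:
    """A named domain as a union of inclusive author-numbered intervals."""

    name: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ConfigurationError(f"domain {self.name!r}: no intervals")
        for lo, hi in self.ranges:
            if hi < lo:
                raise ConfigurationError(
                    f"domain {self.name!r}: empty interval ({lo}, {hi})"
                )

    def contains(self, residue: int) -> bool:
        return any(lo <= residue <= hi for lo, hi in self.ranges)

    def residues(self) -> np.ndarray:
        """All residue numbers covered by this definition."""
        return np.concatenate([np.arange(lo, hi + 1) for lo, hi in self.ranges])


#: Default FlgE layer decomposition.  The inner D0–Dc layer (terminal
#: α-helices plus the Dc β-hairpin) is 1–71 ∪ 358–402; the D1/D2 boundary is
#: not fixed by the deposited annotation and is chosen here so that the D1
#: triangular loop (117–135) and β-hairpin tip (329–330) fall in D1 while the
#: 159–284 outer-surface contacts fall in D2.  Override via configuration.
DEFAULT_FLGE_DOMAINS: tuple[DomainDefinition, ...] = (
    DomainDefinition("D0c", ((1, 71), (358, 402))),
    DomainDefinition("D1", ((72, 144), (285, 357))),
    DomainDefinition("D2", ((145, 284),)),
)


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def _element_is_hydrogen(atom: gemmi.Atom) -> bool:
    return atom.element.name in ("H", "D")


def read_assembly(path: str | Path, format: str = "auto") -> list[SubunitModel]:
    """Read a helical assembly from mmCIF or PDB.

    One :class:`SubunitModel` is produced per polymer chain (a chain counts
    as polymer if it has at least one residue with a carbon Cα), ordered by
    chain identifier.  Waters, ligands and other non-polymer entities are
    dropped.  Only the first model and the first alternate location of each
    atom are kept; residues with insertion codes are rejected with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "pdb": gemmi.CoorFormat.Pdb}.get(format)
    if fmt is None:
        raise FormatError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyAssemblyError(f"{path}: no models")
    model = st[0]

    subunits = []
    for chain in model:
        numbers: list[int] = []
        names: list[str] = []
        atoms: list[dict[str, np.ndarray]] = []
        for residue in chain:
            if residue.name in ("HOH", "WAT", "DOD"):
                continue
            ca = residue.find_atom("CA", "*")
            if ca is None or ca.element.name != "C":
                continue
            if residue.seqid.icode not in ("", " "):
                warnings.warn(
                    f"{path}: chain {chain.name} residue "
                    f"{residue.seqid.num}{residue.seqid.icode}: insertion "
                    "codes are not supported; residue skipped"
                )
                continue
            res_atoms: dict[str, np.ndarray] = {}
            for atom in residue:
                if _element_is_hydrogen(atom) or atom.name in res_atoms:
                    continue  # first altloc wins
                res_atoms[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
            if numbers and residue.seqid.num <= numbers[-1]:
                continue  # duplicate/decreasing numbering: keep first pass
            numbers.append(residue.seqid.num)
            names.append(residue.name)
            atoms.append(res_atoms)
        if numbers:
            subunits.append(SubunitModel(chain.name, np.asarray(numbers), names, atoms))
    if not subunits:
        raise EmptyAssemblyError(f"{path}: no polymer chain with Cα atoms")
    subunits.sort(key=lambda s: s.chain_id)
    logger.info("read %d polymer chains from %s", len(subunits), path)
    return subunits


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def _guess_element(atom_name: str) -> gemmi.Element:
    stripped = atom_name.strip("0123456789'")
    if not stripped:
        return gemmi.Element("X")
    # protein heavy atoms: first character is the element except two-letter
    # metals, which do not occur in the entities handled here
    return gemmi.Element(stripped[0])


def write_assembly(subunits: Sequence[SubunitModel], path: str | Path,
                   format: str = "pdb") -> None:
    """Write an assembly as a single-model PDB file."""
    if format != "pdb":
        raise FormatError(f"unsupported output format {format!r}")
    st = gemmi.Structure()
    st.name = "hookjoint"
    model = gemmi.Model("1")
    for sub in subunits:
        if not np.isfinite(sub.ca).all():
            raise ValueError(f"chain {sub.chain_id}: non-finite coordinates")
        chain = gemmi.Chain(sub.chain_id)
        for num, resname, res_atoms in zip(sub.residue_numbers, sub.residue_names,
                                           sub.atoms):
            residue = gemmi.Residue()
            residue.name = resname
            residue.seqid = gemmi.SeqId(int(num), " ")
            for atom_name, xyz in res_atoms.items():
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = _guess_element(atom_name)
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        st.write_pdb(str(path))
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def write_table(records: pd.DataFrame, path: str | Path, format: str = "csv",
                metadata: Mapping[str, object] | None = None) -> None:
    """Write a result table plus a ``<path>.meta.json`` sidecar.

    The sidecar records the column list and any caller-supplied metadata
    (units, parameters, configuration hash) so that every table is
    self-describing.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        records.to_csv(path, index=False)
    elif format == "json":
        records.to_json(path, orient="records", indent=1)
    else:
        raise FormatError(f"unsupported table format {format!r}")
    sidecar = {"columns": list(map(str, records.columns)),
               "n_rows": int(len(records))}
    if metadata:
        sidecar.update(metadata)
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))


# --------------------------------------------------------------------------
# Domain assignment
# --------------------------------------------------------------------------

def assign_domains(subunit: SubunitModel,
                   defs: Sequence[DomainDefinition]) -> dict[str, np.ndarray]:
    """Map each residue of ``subunit`` to at most one named domain.

    Returns a mapping ``domain name → array of author residue numbers``;
    residues covered by no definition appear under ``"unassigned"``.  Domain
    intervals must not overlap across the definition set.
    """
    covered: dict[int, str] = {}
    for d in defs:
        for lo, hi in d.ranges:
            for r in range(lo, hi + 1):
                if r in covered:
                    raise ConfigurationError(
                        f"residue {r} claimed by both {covered[r]!r} and {d.name!r}"
                    )
                covered[r] = d.name
    out: dict[str, list[int]] = {d.name: [] for d in defs}
    out["unassigned"] = []
    for num in subunit.residue_numbers:
        out[covered.get(int(num), "unassigned")].append(int(num))
    return {k: np.asarray(v, dtype=int) for k, v in out.items()}
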
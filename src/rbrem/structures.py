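"""Atom-level data model, PDB input/output and nonbonded parameterization.

The central container is :class:`Structure`: an ordered, array-backed
collection of atoms with the residue/chain hierarchy of a PDB file and,
once :func:`assign_parameters` has been applied, per-atom nonbonded
parameters (partial charge in e, Lennard-Jones ε in kJ mol⁻¹ and σ in Å,
mass in g mol⁻¹).  Atom serials are 1-based in files and 0-based indices
in memory; every function in the package takes and returns 0-based
indices.

PDB reading/writing is delegated to :mod:`biotite`; files follow the
wwPDB v3.3 fixed columns, HETATM records are treated like ATOM records,
and alternate locations other than blank/'A' are rejected so that
fragile structures stay unambiguous.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as _struc
import biotite.structure.io.pdb as _pdb

from .selection import evaluate_query

__all__ = [
    "AtomRecord",
    "Structure",
    "ParameterTable",
    "ParameterError",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "assign_parameters",
    "select_atoms",
]

#: Sentinel meaning "parameter not assigned yet".
UNSET = math.nan


class PDBFormatError(ValueError):
    """Raised for malformed or unwritable PDB content."""


class ParameterError(KeyError):
    """Raised when a parameter table does not cover every atom."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position and nonbonded parameters.

    ``charge``/``lj_epsilon``/``lj_sigma``/``mass`` are NaN until a
    :class:`ParameterTable` has been applied.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    charge: float = UNSET
    lj_epsilon: float = UNSET
    lj_sigma: float = UNSET
    mass: float = UNSET

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.serial < 1:
            raise ValueError(f"serial must be positive, got {self.serial}")
        if not math.isnan(self.mass) and self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be > 0")
        if not math.isnan(self.lj_epsilon) and self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial}: lj_epsilon must be >= 0")
        if not math.isnan(self.lj_sigma) and self.lj_sigma <= 0:
            raise ValueError(f"atom {self.serial}: lj_sigma must be > 0")


class Structure:
    """Ordered atom collection backed by numpy arrays.

    Parameters are stored per atom in flat arrays (``positions``,
    ``charge``, ``lj_epsilon``, ``lj_sigma``, ``mass`` …) so that energy
    and dynamics kernels can operate without Python-level loops.
    """

    _FIELDS = ("serial", "name", "element", "res_name", "res_id", "chain_id")

    def __init__(self, atoms: Iterable[AtomRecord], body_label: str = "",
                 provenance: str = "") -> None:
        records = list(atoms)
        if not records:
            raise PDBFormatError("no atoms")
        self.body_label = body_label
        self.provenance = provenance
        self.serial = np.array([a.serial for a in records], dtype=int)
        self.name = np.array([a.name for a in records], dtype=object)
        self.element = np.array([a.element for a in records], dtype=object)
        self.res_name = np.array([a.residue_name for a in records], dtype=object)
        self.res_id = np.array([a.residue_index for a in records], dtype=int)
        self.chain_id = np.array([a.chain_id for a in records], dtype=object)
        self.positions = np.array([a.position for a in records], dtype=float)
        self.charge = np.array([a.charge for a in records], dtype=float)
        self.lj_epsilon = np.array([a.lj_epsilon for a in records], dtype=float)
        self.lj_sigma = np.array([a.lj_sigma for a in records], dtype=float)
        self.mass = np.array([a.mass for a in records], dtype=float)
        self._validate()

    def _validate(self) -> None:
        if len(np.unique(self.serial)) != len(self.serial):
            raise ValueError("atom serials must be unique")
        for chain in np.unique(self.chain_id):
            ids = self.res_id[self.chain_id == chain]
            if np.any(np.diff(ids) < 0):
                raise ValueError(
                    f"residue indices must be non-decreasing within chain {chain!r}")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(cls, *, positions, name, element, res_name, res_id,
                    chain_id, serial=None, charge=None, lj_epsilon=None,
                    lj_sigma=None, mass=None, body_label: str = "",
                    provenance: str = "") -> "Structure":
        """Build a Structure directly from flat arrays (internal fast path)."""
        obj = cls.__new__(cls)
        positions = np.asarray(positions, dtype=float)
        n = len(positions)
        obj.body_label = body_label
        obj.provenance = provenance
        obj.positions = positions
        obj.serial = (np.arange(1, n + 1) if serial is None
                      else np.asarray(serial, dtype=int))
        obj.name = np.asarray(name, dtype=object)
        obj.element = np.asarray(element, dtype=object)
        obj.res_name = np.asarray(res_name, dtype=object)
        obj.res_id = np.asarray(res_id, dtype=int)
        obj.chain_id = np.asarray(chain_id, dtype=object)
        for attr, arr in (("charge", charge), ("lj_epsilon", lj_epsilon),
                          ("lj_sigma", lj_sigma), ("mass", mass)):
            setattr(obj, attr,
                    np.full(n, UNSET) if arr is None else np.asarray(arr, dtype=float))
        if n == 0:
            raise PDBFormatError("no atoms")
        obj._validate()
        return obj

    # -- basic protocol -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def atoms(self) -> list[AtomRecord]:
        """Materialize the atom list (convenience view; arrays are primary)."""
        return [self.atom(i) for i in range(len(self))]

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]), name=str(self.name[i]),
            element=str(self.element[i]), residue_name=str(self.res_name[i]),
            residue_index=int(self.res_id[i]), chain_id=str(self.chain_id[i]),
            position=self.positions[i].copy(), charge=float(self.charge[i]),
            lj_epsilon=float(self.lj_epsilon[i]),
            lj_sigma=float(self.lj_sigma[i]), mass=float(self.mass[i]))

    def copy(self) -> "Structure":
        return self.subset(np.arange(len(self)))

    def subset(self, indices: Sequence[int]) -> "Structure":
        """New Structure holding the given atoms (0-based indices), in order."""
        idx = np.asarray(indices, dtype=int)
        return Structure.from_arrays(
            positions=self.positions[idx].copy(), serial=self.serial[idx].copy(),
            name=self.name[idx].copy(), element=self.element[idx].copy(),
            res_name=self.res_name[idx].copy(), res_id=self.res_id[idx].copy(),
            chain_id=self.chain_id[idx].copy(), charge=self.charge[idx].copy(),
            lj_epsilon=self.lj_epsilon[idx].copy(),
            lj_sigma=self.lj_sigma[idx].copy(), mass=self.mass[idx].copy(),
            body_label=self.body_label, provenance=self.provenance)

    def is_parameterized(self) -> bool:
        return bool(np.all(np.isfinite(self.charge))
                    and np.all(np.isfinite(self.lj_epsilon))
                    and np.all(np.isfinite(self.lj_sigma))
                    and np.all(np.isfinite(self.mass)))

    def total_charge(self) -> float:
        return float(np.nansum(self.charge))

    def select(self, query: str) -> np.ndarray:
        return select_atoms(self, query)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<Structure {self.body_label or 'unnamed'}: {len(self)} atoms, "
                f"{'parameterized' if self.is_parameterized() else 'unparameterized'}>")


def concatenate(structures: Sequence[Structure], body_label: str = "") -> Structure:
    """Concatenate structures into one, re-serialing atoms 1..N."""
    return Structure.from_arrays(
        positions=np.concatenate([s.positions for s in structures]),
        name=np.concatenate([s.name for s in structures]),
        element=np.concatenate([s.element for s in structures]),
        res_name=np.concatenate([s.res_name for s in structures]),
        res_id=np.concatenate([s.res_id for s in structures]),
        chain_id=np.concatenate([s.chain_id for s in structures]),
        charge=np.concatenate([s.charge for s in structures]),
        lj_epsilon=np.concatenate([s.lj_epsilon for s in structures]),
        lj_sigma=np.concatenate([s.lj_sigma for s in structures]),
        mass=np.concatenate([s.mass for s in structures]),
        body_label=body_label)


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

class ParameterTable:
    """Nonbonded parameter lookup: (residue, atom name) first, element fallback.

    Entries map either a ``"RES.NAME"`` key or a bare element symbol to
    ``(charge e, lj_epsilon kJ mol⁻¹, lj_sigma Å, mass g mol⁻¹)``.  The
    two-level precedence lets toy fixtures use coarse element-only
    tables while real systems override specific atoms.
    """

    def __init__(self,
                 by_atom: Mapping[tuple[str, str], tuple[float, float, float, float]] | None = None,
                 by_element: Mapping[str, tuple[float, float, float, float]] | None = None):
        self.by_atom = dict(by_atom or {})
        self.by_element = dict(by_element or {})

    def lookup(self, residue_name: str, atom_name: str,
               element: str) -> tuple[float, float, float, float] | None:
        entry = self.by_atom.get((residue_name, atom_name))
        if entry is None:
            entry = self.by_element.get(element)
        return entry

    @classmethod
    def from_text(cls, text: str) -> "ParameterTable":
        """Parse the plain-text table format.

        One entry per line: ``key charge epsilon sigma mass`` where key
        is ``RES.NAME`` or an element symbol.  ``#`` starts a comment.
        """
        by_atom, by_element = {}, {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(
                    f"parameter table line {lineno}: expected 'key charge "
                    f"epsilon sigma mass', got {raw!r}")
            key = parts[0]
            try:
                values = tuple(float(p) for p in parts[1:])
            except ValueError as exc:
                raise ValueError(f"parameter table line {lineno}: {exc}") from exc
            if "." in key:
                res, name = key.split(".", 1)
                by_atom[(res, name)] = values
            else:
                by_element[key] = values
        return cls(by_atom, by_element)

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterTable":
        return cls.from_text(Path(path).read_text())

    def to_text(self) -> str:
        lines = []
        for (res, name), (q, e, s, m) in sorted(self.by_atom.items()):
            lines.append(f"{res}.{name} {q:.6g} {e:.6g} {s:.6g} {m:.6g}")
        for el, (q, e, s, m) in sorted(self.by_element.items()):
            lines.append(f"{el} {q:.6g} {e:.6g} {s:.6g} {m:.6g}")
        return "\n".join(lines) + "\n"


def assign_parameters(structure: Structure, table: ParameterTable) -> Structure:
    """Return a copy of ``structure`` with nonbonded parameters filled in.

    Every atom must be covered by the table; otherwise a
    :class:`ParameterError` is raised listing *all* uncovered
    (residue, atom-name) pairs, not only the first.  Coordinates are
    never modified.
    """
    out = structure.copy()
    misses: list[tuple[str, str]] = []
    for i in range(len(out)):
        entry = table.lookup(str(out.res_name[i]), str(out.name[i]),
                             str(out.element[i]))
        if entry is None:
            misses.append((str(out.res_name[i]), str(out.name[i])))
            continue
        q, eps, sig, mass = entry
        if mass <= 0 or eps < 0 or sig <= 0:
            raise ValueError(
                f"invalid parameters for {out.res_name[i]}.{out.name[i]}: "
                f"eps={eps}, sigma={sig}, mass={mass}")
        out.charge[i] = q
        out.lj_epsilon[i] = eps
        out.lj_sigma[i] = sig
        out.mass[i] = mass
    if misses:
        uniq = sorted(set(misses))
        raise ParameterError(
            f"parameter table does not cover {len(uniq)} atom type(s): {uniq}")
    return out


# ---------------------------------------------------------------------------
# PDB input/output (biotite-backed)
# ---------------------------------------------------------------------------

def _find_malformed_line(text: str) -> int | None:
    """Locate the first ATOM/HETATM line with unparsable coordinates."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            return lineno
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError:
            return lineno
    return None


def read_pdb(path: str | Path, body_label: str | None = None) -> Structure:
    """Read a wwPDB v3.3 file into a :class:`Structure`.

    HETATM records are treated like ATOM records; only the first model
    of a multi-model file is read.  Alternate locations other than
    blank/'A' raise :class:`PDBFormatError`.  Parameters are left unset.
    """
    path = Path(path)
    text = path.read_text()
    if not any(line.startswith(("ATOM", "HETATM"))
               for line in text.splitlines()):
        raise PDBFormatError(f"{path}: no atoms")
    try:
        pdb_file = _pdb.PDBFile.read(io.StringIO(text))
        array = pdb_file.get_structure(model=1, altloc="all",
                                       extra_fields=["atom_id"])
    except Exception as exc:
        lineno = _find_malformed_line(text)
        where = f" at line {lineno}" if lineno is not None else ""
        raise PDBFormatError(f"{path}: malformed PDB record{where}: {exc}") from exc
    if array.array_length() == 0:
        raise PDBFormatError(f"{path}: no atoms")
    bad_altloc = ~np.isin(array.altloc_id, (" ", "", "A", "."))
    if np.any(bad_altloc):
        locs = sorted(set(array.altloc_id[bad_altloc]))
        raise PDBFormatError(
            f"{path}: alternate locations {locs} present; only blank/'A' accepted")
    return Structure.from_arrays(
        positions=array.coord.astype(float),
        serial=array.atom_id.astype(int),
        name=array.atom_name.astype(object),
        element=np.array([e.capitalize() for e in array.element], dtype=object),
        res_name=array.res_name.astype(object),
        res_id=array.res_id.astype(int),
        chain_id=array.chain_id.astype(object),
        body_label=body_label if body_label is not None else path.stem,
        provenance=f"read from {path}")


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write ``structure`` as fixed-column PDB (serials re-emitted 1-based).

    Coordinates are rounded to 3 decimals (PDB precision); magnitudes
    ≥ 10000 Å overflow the 8.3f column and raise
    :class:`PDBFormatError`.  A TER record separates chains.
    """
    if not np.all(np.isfinite(structure.positions)):
        raise PDBFormatError("cannot write non-finite coordinates")
    if np.any(np.abs(structure.positions) >= 10000.0):
        raise PDBFormatError(
            "coordinate magnitude >= 10000 Å overflows the PDB column format")
    n = len(structure)
    array = _struc.AtomArray(n)
    array.coord = structure.positions.astype(np.float32)
    array.chain_id = structure.chain_id.astype("U4")
    array.res_id = structure.res_id
    array.res_name = structure.res_name.astype("U5")
    array.atom_name = structure.name.astype("U6")
    array.element = np.array([e.upper() for e in structure.element], dtype="U2")
    array.set_annotation("atom_id", np.arange(1, n + 1))
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(array)
    # biotite emits bare ATOM lines; add TER between chains and END.
    lines = list(pdb_file.lines)
    out_lines: list[str] = []
    for i, line in enumerate(lines):
        out_lines.append(line)
        last_of_chain = (i + 1 == n) or (structure.chain_id[i + 1] != structure.chain_id[i])
        if last_of_chain:
            out_lines.append("TER")
    out_lines.append("END")
    Path(path).write_text("\n".join(out_lines) + "\n")


def select_atoms(structure: Structure, query: str) -> np.ndarray:
    """Evaluate a selection expression; return sorted unique 0-based indices.

    The mini-language supports ``all``, ``none``, ``chain X``,
    ``name N1,N2``, ``resname R``, ``resid A`` / ``resid A-B``,
    ``element E``, combined with ``and``, ``or``, ``not`` and
    parentheses.  A valid query matching nothing returns an empty array.
    """
    mask = evaluate_query(structure, query)
    return np.flatnonzero(mask)
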
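"""Core data containers and file I/O.

Two containers run through the whole pipeline:

* :class:`Structure` -- an ordered set of atom records (chain, residue, atom
  name, element, coordinates in Angstrom) plus named atom selections
  ("labels") and free-form metadata (e.g. recorded symmetry axes).
* :class:`ScatteringProfile` -- a 1-D small-angle scattering curve I(Q) on a
  strictly increasing Q grid, with optional per-point uncertainties.

File formats are the field's plain-text standards: fixed-column PDB v3.3 for
coordinates (read/written through biotite; structures beyond 99,999 atoms fall
back to biotite's hybrid-36 serials) and whitespace-delimited ``Q I [sigma]``
text with ``#`` comments for profiles. Labels and metadata are in-memory
annotations only; they are not persisted to PDB.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as _struc
from biotite.structure.io.pdb import PDBFile

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "ScatteringProfile",
    "read_structure",
    "write_structure",
    "read_profile",
    "write_profile",
    "concat_structures",
    "extract_unit",
]


@dataclass
class Structure:
    """Ordered atom records with named selections.

    Parameters
    ----------
    serial : (n,) int array
        Unique atom serial numbers.
    chain_id : (n,) str array
    res_id : (n,) int array
        Residue numbers (PDB ``resSeq``).
    res_name : (n,) str array
    atom_name : (n,) str array
    element : (n,) str array
    coord : (n, 3) float array
        Cartesian coordinates in Angstrom.
    labels : dict mapping selection name -> int index array
        Named atom-index sets ("Fab1", "hinge1", "paratope", ...).
    meta : dict
        Free-form metadata, e.g. ``symmetry_axes`` for the antigen.
    """

    serial: np.ndarray
    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    labels: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.serial = np.asarray(self.serial, dtype=np.int64)
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.res_id = np.asarray(self.res_id, dtype=np.int64)
        self.res_name = np.asarray(self.res_name, dtype="U5")
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.coord = np.asarray(self.coord, dtype=np.float64)
        self.labels = {k: np.asarray(v, dtype=np.intp) for k, v in self.labels.items()}
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        n = len(self.serial)
        if self.coord.shape != (n, 3):
            raise ValidationError(
                f"coord shape {self.coord.shape} inconsistent with {n} atoms"
            )
        for name in ("chain_id", "res_id", "res_name", "atom_name", "element"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"field {name} has wrong length")
        if n and not np.all(np.isfinite(self.coord)):
            raise ValidationError("non-finite coordinates")
        if n and len(np.unique(self.serial)) != n:
            raise ValidationError("atom serials are not unique")
        for key, idx in self.labels.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValidationError(f"label {key!r} refers to nonexistent atoms")

    # -- basic queries ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def centroid(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Unweighted centroid of all atoms (or of a selection)."""
        xyz = self.coord if indices is None else self.coord[np.asarray(indices)]
        if len(xyz) == 0:
            raise ValidationError("centroid of empty selection")
        return xyz.mean(axis=0)

    def label_indices(self, name: str) -> np.ndarray:
        try:
            return self.labels[name]
        except KeyError:
            raise KeyError(
                f"no selection named {name!r}; have {sorted(self.labels)}"
            ) from None

    def select_residues(self, chain_id: str, res_lo: int, res_hi: int) -> np.ndarray:
        """Atom indices for a (chain, residue-range) rule, inclusive bounds."""
        mask = (
            (self.chain_id == chain_id)
            & (self.res_id >= res_lo)
            & (self.res_id <= res_hi)
        )
        return np.flatnonzero(mask)

    # -- construction helpers -------------------------------------------

    def copy(self) -> "Structure":
        return Structure(
            self.serial.copy(),
            self.chain_id.copy(),
            self.res_id.copy(),
            self.res_name.copy(),
            self.atom_name.copy(),
            self.element.copy(),
            self.coord.copy(),
            {k: v.copy() for k, v in self.labels.items()},
            dict(self.meta),
        )

    def subset(self, indices: np.ndarray, keep_labels: bool = True) -> "Structure":
        """New Structure with the given atoms (in the given order).

        Labels are intersected with the kept set and re-indexed.
        """
        indices = np.asarray(indices, dtype=np.intp)
        new_pos = -np.ones(self.n_atoms, dtype=np.intp)
        new_pos[indices] = np.arange(len(indices))
        labels = {}
        if keep_labels:
            for key, idx in self.labels.items():
                mapped = new_pos[idx]
                mapped = mapped[mapped >= 0]
                if mapped.size:
                    labels[key] = np.sort(mapped)
        return Structure(
            self.serial[indices],
            self.chain_id[indices],
            self.res_id[indices],
            self.res_name[indices],
            self.atom_name[indices],
            self.element[indices],
            self.coord[indices],
            labels,
            dict(self.meta),
        )

    def with_coord(self, coord: np.ndarray) -> "Structure":
        """Same topology and labels, new coordinates."""
        out = self.copy()
        out.coord = np.asarray(coord, dtype=np.float64)
        out.validate()
        return out


def concat_structures(
    parts: Sequence[Structure],
    prefixes: Sequence[str] | None = None,
    rechain: bool = True,
) -> Structure:
    """Concatenate structures into one, namespacing labels.

    Labels of part ``i`` are renamed ``f"{prefixes[i]}:{name}"`` when prefixes
    are given, and each part additionally contributes a label equal to its
    bare prefix covering all of its atoms. Serial numbers are renumbered from
    1; chain ids are remapped to unique single letters when ``rechain`` to
    keep the PDB writable.
    """
    if not parts:
        raise ValidationError("cannot concatenate zero structures")
    if prefixes is not None and len(prefixes) != len(parts):
        raise ValidationError("prefixes must match parts")
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"
    fields = {k: [] for k in ("chain_id", "res_id", "res_name", "atom_name", "element", "coord")}
    labels: dict[str, np.ndarray] = {}
    meta: dict = {}
    offset = 0
    chain_counter = 0
    for i, p in enumerate(parts):
        chain_map = {}
        if rechain:
            for c in dict.fromkeys(p.chain_id.tolist()):
                chain_map[c] = alphabet[chain_counter % len(alphabet)]
                chain_counter += 1
            fields["chain_id"].append(np.array([chain_map[c] for c in p.chain_id]))
        else:
            fields["chain_id"].append(p.chain_id)
        fields["res_id"].append(p.res_id)
        fields["res_name"].append(p.res_name)
        fields["atom_name"].append(p.atom_name)
        fields["element"].append(p.element)
        fields["coord"].append(p.coord)
        pre = prefixes[i] if prefixes is not None else None
        for key, idx in p.labels.items():
            name = f"{pre}:{key}" if pre else key
            labels[name] = idx + offset
        if pre:
            labels[pre] = np.arange(p.n_atoms) + offset
        for k, v in p.meta.items():
            meta.setdefault(f"{pre}:{k}" if pre else k, v)
        offset += p.n_atoms
    n = offset
    return Structure(
        np.arange(1, n + 1),
        np.concatenate(fields["chain_id"]),
        np.concatenate(fields["res_id"]),
        np.concatenate(fields["res_name"]),
        np.concatenate(fields["atom_name"]),
        np.concatenate(fields["element"]),
        np.vstack(fields["coord"]),
        labels,
        meta,
    )


def extract_unit(s: Structure, prefix: str) -> Structure:
    """Pull one namespaced unit back out of a concatenated structure.

    Returns the atoms under label ``prefix`` with inner labels de-namespaced
    (``"fab:paratope"`` -> ``"paratope"``) and the unit's metadata restored.
    """
    if prefix not in s.labels:
        raise KeyError(f"no unit {prefix!r} in structure; have {sorted(s.labels)}")
    unit = s.subset(s.labels[prefix])
    tag = f"{prefix}:"
    labels = {}
    for key, idx in unit.labels.items():
        if key == prefix:
            continue
        if key.startswith(tag):
            labels[key[len(tag):]] = idx
    unit.labels = labels
    meta = {}
    for key, val in s.meta.items():
        if key.startswith(tag):
            meta[key[len(tag):]] = val
    unit.meta = meta
    return unit


@dataclass
class ScatteringProfile:
    """1-D scattering curve I(Q), optionally with uncertainties.

    Invariants: Q strictly increasing, intensities finite, sigma (if present)
    strictly positive and of equal length.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.q.ndim != 1 or self.intensity.shape != self.q.shape:
            raise ValidationError("q and intensity must be 1-D of equal length")
        if len(self.q) and np.any(np.diff(self.q) <= 0):
            raise ValidationError("Q grid must be strictly increasing")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.intensity)):
            raise ValidationError("non-finite profile values")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise ValidationError("sigma length mismatch")
            if np.any(self.sigma <= 0) or not np.all(np.isfinite(self.sigma)):
                raise ValidationError("sigma must be positive and finite")

    def __len__(self) -> int:
        return len(self.q)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def read_structure(path) -> Structure:
    """Read a fixed-column PDB file into a :class:`Structure`.

    Atom order is preserved. Missing element columns are inferred from atom
    names. Only the first model and first altloc are kept (a warning is
    emitted for discarded altlocs).
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
    except OSError:
        raise
    except Exception as exc:  # biotite raises its own parse errors
        raise FormatError(f"{path}: not a readable PDB file: {exc}") from exc
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            atoms = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise FormatError(f"{path}: no parsable ATOM/HETATM records: {exc}") from exc
    if atoms.array_length() == 0:
        raise FormatError(f"{path}: zero atoms parsed")
    element = atoms.element.astype("U2")
    blank = element == ""
    if np.any(blank):
        inferred = np.asarray(_struc.infer_elements(atoms), dtype="U2")
        element[blank] = inferred[blank]
    return Structure(
        serial=np.arange(1, atoms.array_length() + 1),
        chain_id=atoms.chain_id,
        res_id=atoms.res_id,
        res_name=atoms.res_name,
        atom_name=atoms.atom_name,
        element=element,
        coord=atoms.coord,
    )


def write_structure(s: Structure, path) -> None:
    """Write fixed-column PDB v3.3; chains separated by TER records.

    Structures with more than 99,999 atoms are written with hybrid-36 serial
    numbers (biotite's fallback dialect).
    """
    arr = _struc.AtomArray(s.n_atoms)
    arr.coord = s.coord.astype(np.float32)
    arr.chain_id = s.chain_id
    arr.res_id = s.res_id
    arr.res_name = s.res_name
    arr.atom_name = s.atom_name
    arr.element = s.element
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr, hybrid36=s.n_atoms > 99999)
    lines = list(pdb.lines)
    # biotite does not emit TER records; insert one at each chain boundary
    out_lines = []
    atom_i = 0
    for line in lines:
        if line.startswith(("ATOM", "HETATM")):
            out_lines.append(line)
            nxt = atom_i + 1
            if nxt == s.n_atoms or (
                nxt < s.n_atoms and s.chain_id[nxt] != s.chain_id[atom_i]
            ):
                out_lines.append("TER")
            atom_i += 1
        else:
            out_lines.append(line)
    Path(path).write_text("\n".join(out_lines) + "\n")


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

def read_profile(path) -> ScatteringProfile:
    """Read a whitespace-delimited ``Q I [sigma]`` text profile.

    ``#`` comment lines are ignored; rows with non-numeric fields are skipped
    with a logged warning. Two-column files yield a profile without sigma.
    """
    path = Path(path)
    rows = []
    ncols = None
    skipped = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            try:
                vals = [float(x) for x in parts]
            except ValueError:
                skipped += 1
                continue
            if len(vals) < 2:
                skipped += 1
                continue
            if ncols is None:
                ncols = min(len(vals), 3)
            rows.append(vals[:ncols])
    if skipped:
        logger.warning("%s: skipped %d non-numeric rows", path, skipped)
    if len(rows) < 2:
        raise FormatError(f"{path}: fewer than 2 usable data rows")
    data = np.array([r + [np.nan] * (ncols - len(r)) for r in rows])
    q, intensity = data[:, 0], data[:, 1]
    if np.any(np.diff(q) <= 0):
        raise ValidationError(f"{path}: Q column is not strictly increasing")
    sigma = None
    if ncols == 3 and np.all(np.isfinite(data[:, 2])):
        sigma = data[:, 2]
    return ScatteringProfile(q, intensity, sigma)


def write_profile(p: ScatteringProfile, path) -> None:
    """Write a profile as 2- or 3-column text at full (>=9 sig. digit) precision."""
    cols = [p.q, p.intensity] + ([p.sigma] if p.sigma is not None else [])
    header = "Q I sigma" if p.sigma is not None else "Q I"
    np.savetxt(path, np.column_stack(cols), fmt="%.12e", header=header)
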
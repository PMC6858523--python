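"""Molecular structures, Gaussian basis sets, orbital indexing and file I/O.

Conventions used throughout the package:

* positions in Angstrom, energies in eV, forces in eV/Angstrom;
* Gaussian exponents in Bohr^-2 (the native unit of published basis sets);
* spherical Gaussian shells: a shell of angular momentum ``l`` contributes
  ``2l + 1`` atomic orbitals with magnetic index ``m = -l ... +l``;
* orbital ordering is atom-major, then shell order as listed in the basis,
  then ``m``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

HARTREE_EV = 27.211386245988
BOHR_ANGSTROM = 0.529177210903

_SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
]
_Z_OF = {s: z for z, s in enumerate(_SYMBOLS)}

#: standard atomic masses (amu) for the elements the toy systems use
ATOMIC_MASSES = {
    1: 1.008, 2: 4.0026, 3: 6.94, 4: 9.0122, 5: 10.81, 6: 12.011,
    7: 14.007, 8: 15.999, 9: 18.998, 10: 20.180, 11: 22.990, 12: 24.305,
    13: 26.982, 14: 28.085, 15: 30.974, 16: 32.06, 17: 35.45, 18: 39.948,
}


class ParseError(ValueError):
    """Malformed geometry or dataset file."""


class ConfigurationError(ValueError):
    """Inconsistent basis/molecule/model configuration."""


@dataclasses.dataclass
class Molecule:
    """Element list plus Cartesian coordinates (Angstrom)."""

    atomic_numbers: list
    positions: np.ndarray
    comment: str = ""

    def __post_init__(self):
        self.atomic_numbers = [int(z) for z in self.atomic_numbers]
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.atomic_numbers) != self.positions.shape[0]:
            raise ValueError("atomic_numbers and positions disagree in length")
        if any(z < 1 for z in self.atomic_numbers):
            raise ValueError("nuclear charges must be >= 1")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    def symbols(self):
        return [_SYMBOLS[z] for z in self.atomic_numbers]

    def with_positions(self, positions) -> "Molecule":
        return Molecule(list(self.atomic_numbers), np.asarray(positions, float),
                        self.comment)


@dataclasses.dataclass
class GaussianShell:
    """One contracted shell: angular momentum, primitive exponents, coefficients.

    Contraction coefficients apply to *normalized* primitives; the final
    contracted atomic orbitals are renormalized to unit self-overlap by the
    integral routines.
    """

    l: int
    exponents: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self):
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not 0 <= self.l <= 3:
            raise ValueError(f"angular momentum {self.l} outside supported range 0..3")
        if self.exponents.size == 0 or self.exponents.size != self.coefficients.size:
            raise ValueError("exponents/coefficients must be equal-length and non-empty")
        if np.any(self.exponents <= 0):
            raise ValueError("Gaussian exponents must be strictly positive")

    @property
    def n_orbitals(self) -> int:
        return 2 * self.l + 1


@dataclasses.dataclass
class BasisSet:
    """Ordered Gaussian shells per element."""

    shells: dict
    name: str = "custom"

    def shells_for(self, z: int):
        try:
            return self.shells[z]
        except KeyError:
            raise ConfigurationError(
                f"basis set '{self.name}' has no entry for element Z={z}") from None

    def n_ao(self, z: int) -> int:
        return sum(s.n_orbitals for s in self.shells_for(z))

    def max_l(self) -> int:
        return max(s.l for shells in self.shells.values() for s in shells)

    def to_json(self, path):
        payload = {
            str(z): [{"l": s.l, "exp": list(map(float, s.exponents)),
                      "coef": list(map(float, s.coefficients))} for s in shells]
            for z, shells in self.shells.items()
        }
        Path(path).write_text(json.dumps({"name": self.name, "shells": payload}, indent=1))

    @classmethod
    def from_json(cls, path) -> "BasisSet":
        raw = json.loads(Path(path).read_text())
        shells = {
            int(z): [GaussianShell(int(s["l"]), s["exp"], s["coef"]) for s in entry]
            for z, entry in raw["shells"].items()
        }
        return cls(shells, raw.get("name", "custom"))


@dataclasses.dataclass
class OrbitalIndex:
    """Deterministic map between (atom, shell, m) and global matrix row/column."""

    atom_offsets: np.ndarray
    atom_counts: np.ndarray
    orbital_labels: list          # (atom, shell index within atom, l, m) per orbital

    @property
    def n_orbitals(self) -> int:
        return int(self.atom_offsets[-1] + self.atom_counts[-1]) if len(self.atom_counts) else 0

    def atom_slice(self, i: int) -> slice:
        return slice(int(self.atom_offsets[i]), int(self.atom_offsets[i] + self.atom_counts[i]))

    def global_index(self, atom: int, shell: int, m: int) -> int:
        off = int(self.atom_offsets[atom])
        for k, (a, s, l, mm) in enumerate(self.orbital_labels[off:]):
            if a == atom and s == shell and mm == m:
                return off + k
        raise KeyError((atom, shell, m))


def build_orbital_index(mol: Molecule, basis: BasisSet) -> OrbitalIndex:
    counts, labels = [], []
    for i, z in enumerate(mol.atomic_numbers):
        n = 0
        for si, shell in enumerate(basis.shells_for(z)):
            for m in range(-shell.l, shell.l + 1):
                labels.append((i, si, shell.l, m))
            n += shell.n_orbitals
        counts.append(n)
    counts = np.asarray(counts, dtype=int)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]]) if len(counts) else np.zeros(0, int)
    return OrbitalIndex(offsets, counts, labels)


@dataclasses.dataclass
class ElectronicRecord:
    """One reference sample: geometry with Hamiltonian, overlap, energy, forces."""

    molecule: Molecule
    H: np.ndarray                 # eV
    S: np.ndarray                 # dimensionless
    E: float                      # eV
    F: np.ndarray                 # eV/Angstrom
    n_electrons: int

    def __post_init__(self):
        self.H = np.asarray(self.H, float)
        self.S = np.asarray(self.S, float)
        self.F = np.asarray(self.F, float).reshape(-1, 3)
        self.E = float(self.E)
        if self.H.shape != self.S.shape or self.H.shape[0] != self.H.shape[1]:
            raise ValueError("H and S must be square matrices of equal shape")
        if self.F.shape[0] != self.molecule.n_atoms:
            raise ValueError("force array does not match atom count")
        if self.n_electrons % 2:
            raise ValueError("only closed-shell (even) electron counts are supported")


# -- XYZ ----------------------------------------------------------------

def read_xyz(path) -> list:
    """Read a (possibly multi-frame) XYZ file into a list of molecules."""
    lines = Path(path).read_text().splitlines()
    mols, k = [], 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError:
            raise ParseError(f"{path}:{k + 1}: expected atom count, got {lines[k]!r}")
        comment = lines[k + 1] if k + 1 < len(lines) else ""
        body = lines[k + 2:k + 2 + n]
        if len(body) < n or any(len(row.split()) < 4 for row in body):
            raise ParseError(f"{path}:{k + 1}: frame truncated (count line says {n})")
        zs, pos = [], []
        for off, row in enumerate(body):
            fields = row.split()
            sym = fields[0]
            z = _Z_OF.get(sym) or (int(sym) if sym.isdigit() else None)
            if not z:
                raise ParseError(f"{path}:{k + 3 + off}: unknown element {sym!r}")
            try:
                pos.append([float(x) for x in fields[1:4]])
            except ValueError:
                raise ParseError(f"{path}:{k + 3 + off}: malformed coordinates")
            zs.append(z)
        mols.append(Molecule(zs, np.array(pos), comment))
        k += 2 + n
    if not mols:
        raise ParseError(f"{path}: no frames found")
    return mols


def write_xyz(path, mols) -> None:
    if isinstance(mols, Molecule):
        mols = [mols]
    out = []
    for mol in mols:
        out.append(str(mol.n_atoms))
        out.append(mol.comment.replace("\n", " "))
        for sym, r in zip(mol.symbols(), mol.positions):
            out.append(f"{sym:<3s} {r[0]:18.10f} {r[1]:18.10f} {r[2]:18.10f}")
    Path(path).write_text("\n".join(out) + "\n")


# -- neighbor list ------------------------------------------------------

def neighbor_pairs(mol: Molecule, r_c: float):
    """Ordered pairs (i, j, r_ij vector, distance) with distance < r_c.

    Both (i, j) and (j, i) are returned; the vector points from atom i to j.
    """
    if r_c <= 0:
        raise ValueError("cutoff must be positive")
    pos = mol.positions
    diff = pos[None, :, :] - pos[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    ii, jj = np.where((dist < r_c) & ~np.eye(mol.n_atoms, dtype=bool))
    return [(int(i), int(j), diff[i, j].copy(), float(dist[i, j])) for i, j in zip(ii, jj)]


# -- dataset container --------------------------------------------------

def write_dataset(path, records, basis_name="custom", metadata=None) -> None:
    """Write homogeneous electronic records to an HDF5 container."""
    if not records:
        raise ValueError("no records to write")
    n_ao = records[0].H.shape[0]
    with h5py.File(path, "w") as fh:
        fh.create_dataset("positions", data=np.stack([r.molecule.positions for r in records]))
        fh.create_dataset("atomic_numbers",
                          data=np.asarray(records[0].molecule.atomic_numbers, dtype=np.int64))
        fh.create_dataset("hamiltonian", data=np.stack([r.H for r in records]))
        fh.create_dataset("overlap", data=np.stack([r.S for r in records]))
        fh.create_dataset("energy", data=np.asarray([r.E for r in records]))
        fh.create_dataset("forces", data=np.stack([r.F for r in records]))
        meta = fh.create_group("meta")
        meta.attrs["basis_name"] = basis_name
        meta.attrs["n_electrons"] = records[0].n_electrons
        meta.attrs["units"] = "positions:Angstrom energy:eV forces:eV/Angstrom"
        meta.attrs["n_ao"] = n_ao
        for key, val in (metadata or {}).items():
            meta.attrs[key] = val


def read_dataset(path):
    """Read an HDF5 dataset back into records plus its metadata dict."""
    with h5py.File(path, "r") as fh:
        for group in ("positions", "atomic_numbers", "hamiltonian", "overlap",
                      "energy", "forces"):
            if group not in fh:
                raise ParseError(f"{path}: dataset missing required group /{group}")
        pos = fh["positions"][...]
        zs = [int(z) for z in fh["atomic_numbers"][...]]
        H, S = fh["hamiltonian"][...], fh["overlap"][...]
        E, F = fh["energy"][...], fh["forces"][...]
        meta = dict(fh["meta"].attrs) if "meta" in fh else {}
    if not (len(pos) == len(H) == len(S) == len(E) == len(F)):
        raise ParseError(f"{path}: frame counts disagree between groups")
    n_el = int(meta.get("n_electrons", 0))
    records = [
        ElectronicRecord(Molecule(zs, p), h, s, e, f, n_el)
        for p, h, s, e, f in zip(pos, H, S, E, F)
    ]
    return records, meta
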
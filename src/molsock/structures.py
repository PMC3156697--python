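"""Minimal molecular model, PDB text I/O, energy tables, synthetic fixtures.

The model is deliberately small: ordered chains/residues/atoms with
Cartesian coordinates in Angstroms — just enough to carry a conformation
over the wire as PDB text and to attach per-residue scalar energies.  The
synthetic generator produces poly-alanine-like backbones on an ideal
helical curve so the whole pipeline is exercisable without any deposited
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "MolecularModel",
    "EnergyMap",
    "PDBParseError",
    "EmptyModelError",
    "EnergyParseError",
    "write_pdb",
    "parse_pdb",
    "serialize_energies",
    "parse_energies",
    "make_synthetic_model",
    "perturb_model",
    "toy_score",
]


class PDBParseError(ValueError):
    """Malformed PDB text; carries the offending line number."""


class EmptyModelError(ValueError):
    """No ATOM/HETATM records found, or a model with no residues."""


class EnergyParseError(ValueError):
    """Malformed energy-table payload."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    def __post_init__(self):
        if not self.name or len(self.name) > 4:
            raise ValueError(f"atom name {self.name!r} must be 1-4 characters")
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"atom {self.name!r} has non-finite coordinates")

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class Residue:
    chain_id: str
    number: int  # 1-based, PDB convention
    name: str
    atoms: tuple[Atom, ...]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"residue {self.chain_id}{self.number} has no atoms")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.number)


@dataclass(frozen=True)
class MolecularModel:
    """One conformation: a named, ordered list of residues."""

    name: str
    residues: tuple[Residue, ...]

    def __post_init__(self):
        if not self.residues:
            raise EmptyModelError(f"model {self.name!r} has no residues")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue number) in model")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coordinates(self) -> np.ndarray:
        """All atom coordinates in model order, shape (n_atoms, 3)."""
        return np.array(
            [a.xyz for r in self.residues for a in r.atoms], dtype=np.float64
        ).reshape(-1, 3)


@dataclass(frozen=True)
class EnergyMap:
    """A score-term name plus per-residue scalar values."""

    term: str
    values: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite energy for residue {k}")


# ---------------------------------------------------------------------------
# PDB text I/O (fixed-column v3.3 ATOM records)

def _format_atom_name(name: str) -> str:
    # Columns 13-16: one-letter elements conventionally start in column 14.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb(m: MolecularModel) -> str:
    """Serialize a model as fixed-column PDB v3.3 ATOM records.

    Coordinates are written to 3 decimals; occupancy/B-factor as 1.00/0.00;
    a TER record closes each chain and END closes the file.
    """
    lines = []
    serial = 0
    prev_chain = None
    last_res = None
    for res in m.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            serial += 1
            lines.append(_ter_line(serial, last_res))
        for a in res.atoms:
            serial += 1
            lines.append(
                f"ATOM  {serial:5d} {_format_atom_name(a.name)} {res.name:>3s} "
                f"{res.chain_id}{res.number:4d}    "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.element:>2s}".ljust(80)
            )
        prev_chain = res.chain_id
        last_res = res
    serial += 1
    lines.append(_ter_line(serial, last_res))
    lines.append("END".ljust(80))
    return "\n".join(lines) + "\n"


def _ter_line(serial: int, res: Residue) -> str:
    return (
        f"TER   {serial:5d}      {res.name:>3s} {res.chain_id}{res.number:4d}".ljust(80)
    )


def parse_pdb(text: str, name: str = "model") -> MolecularModel:
    """Parse ATOM/HETATM records from PDB text; other record types ignored.

    Residues are grouped by (chain, residue number) in order of first
    appearance.  Raises :class:`EmptyModelError` if no atom records exist
    and :class:`PDBParseError` (naming the line) on malformed fields.
    """
    residues: dict[tuple[str, int], list] = {}
    res_names: dict[tuple[str, int], str] = {}
    order: list[tuple[str, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        try:
            atom_name = line[12:16].strip()
            res_name = line[17:20].strip()
            chain = line[21].strip() or " "
            resnum = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"line {lineno}: malformed atom record: {exc}") from None
        element = line[76:78].strip() or (atom_name[:1] if atom_name else "X")
        key = (chain, resnum)
        if key not in residues:
            residues[key] = []
            res_names[key] = res_name
            order.append(key)
        residues[key].append(Atom(atom_name, element, x, y, z))
    if not order:
        raise EmptyModelError("no ATOM/HETATM records in PDB text")
    return MolecularModel(
        name,
        tuple(
            Residue(chain, num, res_names[(chain, num)], tuple(residues[(chain, num)]))
            for chain, num in order
        ),
    )


# ---------------------------------------------------------------------------
# Energy table payload (line-oriented text dialect)

def serialize_energies(e: EnergyMap) -> bytes:
    """Encode as ASCII lines ``<chain> <resnum> <value>`` (repr-faithful)."""
    lines = [f"{c} {n} {v!r}\n" for (c, n), v in e.values.items()]
    return "".join(lines).encode("ascii")


def parse_energies(b: bytes, term: str = "") -> EnergyMap:
    """Invert :func:`serialize_energies`; *term* comes from the packet header."""
    values: dict[tuple[str, int], float] = {}
    for lineno, line in enumerate(b.decode("ascii", errors="replace").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise EnergyParseError(f"line {lineno}: expected 'chain resnum value'")
        chain, num_s, val_s = parts
        try:
            values[(chain, int(num_s))] = float(val_s)
        except ValueError:
            raise EnergyParseError(f"line {lineno}: non-numeric field in {line!r}") from None
    return EnergyMap(term, values)


# ---------------------------------------------------------------------------
# Synthetic fixtures

#: ideal-helix parameters: rise per residue (A) and twist per residue (deg)
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
#: CA radius chosen so consecutive CA-CA distance is ~3.8 A for the above
_CA_RADIUS = 2.28

_BACKBONE = (
    # (atom name, element, radial offset, angular offset deg, axial offset)
    ("N", "N", -0.45, -28.0, -0.70),
    ("CA", "C", 0.0, 0.0, 0.0),
    ("C", "C", -0.30, 26.0, 0.70),
    ("O", "O", 0.55, 38.0, 1.10),
)


def make_synthetic_model(n_residues: int, seed: int = 0, name: str = "synthetic") -> MolecularModel:
    """Poly-alanine-like backbone (N, CA, C, O) on an ideal helical curve.

    Deterministic for a fixed seed: the helix itself is ideal (1.5 A rise,
    100 deg twist per residue) and the seed drives only a small (<=0.05 A)
    per-atom jitter so distinct seeds give distinct but equally realistic
    conformations.
    """
    if n_residues < 1:
        raise ValueError(f"n_residues must be >= 1, got {n_residues}")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.05, 0.05, size=(n_residues, len(_BACKBONE), 3))
    residues = []
    for i in range(n_residues):
        theta0 = math.radians(HELIX_TWIST_DEG) * i
        atoms = []
        for j, (aname, elem, dr, dth, dz) in enumerate(_BACKBONE):
            r = _CA_RADIUS + dr
            th = theta0 + math.radians(dth)
            x = r * math.cos(th) + jitter[i, j, 0]
            y = r * math.sin(th) + jitter[i, j, 1]
            z = HELIX_RISE * i + dz + jitter[i, j, 2]
            atoms.append(Atom(aname, elem, round(x, 3), round(y, 3), round(z, 3)))
        residues.append(Residue("A", i + 1, "ALA", tuple(atoms)))
    return MolecularModel(name, tuple(residues))


def perturb_model(m: MolecularModel, magnitude: float, seed: int = 0) -> MolecularModel:
    """Displace every coordinate by uniform noise in [-magnitude, +magnitude].

    Returns a new model; the input is untouched.  Deterministic per seed.
    """
    if magnitude == 0:
        return m
    rng = np.random.default_rng(seed)
    residues = []
    for res in m.residues:
        atoms = []
        for a in res.atoms:
            dx, dy, dz = rng.uniform(-magnitude, magnitude, size=3)
            atoms.append(
                Atom(a.name, a.element, round(a.x + dx, 3), round(a.y + dy, 3), round(a.z + dz, 3))
            )
        residues.append(Residue(res.chain_id, res.number, res.name, tuple(atoms)))
    return MolecularModel(m.name, tuple(residues))


def toy_score(m: MolecularModel, cutoff: float = 3.0) -> EnergyMap:
    """Per-residue clash count: atoms of OTHER residues within *cutoff* A.

    A stand-in scalar score so energy streaming and spectrum coloring can be
    exercised end to end; it is not a physical energy.  Term name
    ``"toy_clash"``.
    """
    from scipy.spatial import cKDTree

    coords = m.coordinates()
    res_idx = np.repeat(
        np.arange(len(m.residues)), [len(r.atoms) for r in m.residues]
    )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    counts = np.zeros(len(m.residues), dtype=np.int64)
    if len(pairs):
        ri, rj = res_idx[pairs[:, 0]], res_idx[pairs[:, 1]]
        inter = ri != rj
        np.add.at(counts, ri[inter], 1)
        np.add.at(counts, rj[inter], 1)
    return EnergyMap(
        "toy_clash", {r.key: float(c) for r, c in zip(m.residues, counts)}
    )
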
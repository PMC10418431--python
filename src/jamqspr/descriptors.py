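"""Topological molecular descriptors computed from SMILES.

The fifteen descriptors exposed here are the classic Dragon-style set used
in mixture QSPR work on food systems: five constitutional indexes (MW, AMW,
nH, nC, nStructures), the polarity number, four connectivity-type indexes
(X1Av, X1sol, XMOD, RDCHI), an H-bond donor count, and four bulk/surface
descriptors (P_VSA_p_1, SAtot, VvdwMG, PDI).

SMILES strings are parsed with RDKit; everything downstream of the parse —
the hydrogen-depleted graph, topological distances, degree and valence-delta
bookkeeping, and the descriptor sums themselves — is computed here on plain
data structures so each quantity has a single auditable definition.

Eleven of the fifteen descriptors have exact closed forms.  XMOD and the
four bulk descriptors use additive per-atom contribution tables shipped as
package data (see :mod:`jamqspr.calibration`); their values are flagged
``calibrated`` in the metadata returned by :func:`compute_descriptors`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from scipy.sparse.csgraph import shortest_path

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "AtomRecord",
    "MolecularGraph",
    "TopologicalDistances",
    "DescriptorVector",
    "SmilesParseError",
    "UnsupportedElementError",
    "DESCRIPTOR_NAMES",
    "DISCONNECTED",
    "parse_smiles",
    "distance_matrix",
    "constitutional",
    "polarity_number",
    "connectivity_indexes",
    "hbond_donors",
    "bulk_descriptors",
    "xmod_index",
    "compute_descriptors",
    "read_smi",
    "descriptor_table",
]

#: Column order of the descriptor vector (fixed report order).
DESCRIPTOR_NAMES = (
    "MW", "AMW", "nH", "nC", "nStructures",
    "Pol", "X1Av", "X1sol", "XMOD", "RDCHI",
    "P_VSA_p_1", "nHDon", "SAtot", "VvdwMG", "PDI",
)

#: Sentinel distance for atom pairs in different connected components.
DISCONNECTED = -1

# Two-decimal atomic masses; this table (not IUPAC 2021 weights) reproduces
# the reference molecular weights exactly (e.g. glucose 180.18).
ATOMIC_MASS = {"H": 1.01, "C": 12.01, "N": 14.01, "O": 16.00, "F": 19.00}

#: Principal quantum number of the valence shell, by element.
PRINCIPAL_QUANTUM = {"H": 1, "C": 2, "N": 2, "O": 2, "F": 2}

_PT = Chem.GetPeriodicTable()


class SmilesParseError(ValueError):
    """Raised when RDKit cannot turn a SMILES string into a molecule."""


class UnsupportedElementError(ValueError):
    """Raised when an atom's element is missing from a parameter table."""


@dataclass(frozen=True)
class AtomRecord:
    """Per-atom bookkeeping for the hydrogen-depleted graph.

    ``delta`` is the skeletal degree (non-H neighbours); ``valence_delta``
    is the Kier--Hall value used by valence connectivity indexes.
    """

    element: str
    Z: int
    Zv: int
    h: int
    formal_charge: int
    aromatic: bool
    L: int
    delta: int
    valence_delta: float


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-depleted labelled molecular graph."""

    atoms: tuple[AtomRecord, ...]
    bonds: tuple[tuple[int, int, float], ...]  # (i, j, bond order)
    components: int

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


@dataclass(frozen=True)
class TopologicalDistances:
    """All-pairs shortest-path bond counts; ``DISCONNECTED`` marks pairs
    in different components."""

    matrix: np.ndarray

    def __getitem__(self, ij):
        return self.matrix[ij]


@dataclass(frozen=True)
class DescriptorVector:
    """The fifteen descriptor values, in fixed report order."""

    values: dict[str, float]
    calibrated: frozenset[str] = field(
        default_factory=lambda: frozenset(
            {"XMOD", "P_VSA_p_1", "SAtot", "VvdwMG", "PDI"}
        )
    )

    def __post_init__(self):
        missing = set(DESCRIPTOR_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"descriptor vector missing entries: {sorted(missing)}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in DESCRIPTOR_NAMES], dtype=float)


def _valence_delta(element: str, Z: int, Zv: int, h: int, charge: int) -> float:
    """Kier--Hall valence delta.

    delta_v = (Zv - q - h) / (Z - Zv - 1), with the denominator taken for
    the neutral element (1 for all second-row atoms).  Subtracting the
    formal charge q from the valence-electron count handles cations such as
    the flavylium ring oxygen (delta_v = 5), the convention that reproduces
    the reference X1Av of the anthocyanin core.
    """
    denom = Z - Zv - 1
    if denom <= 0:
        if element == "H":
            raise UnsupportedElementError("valence delta undefined for hydrogen")
        denom = 1  # second row
    return (Zv - charge - h) / denom


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-depleted molecular graph.

    Implicit hydrogens follow standard valence rules; bracket atoms carry
    only the hydrogens they state explicitly; formal charges are preserved.

    Raises
    ------
    SmilesParseError
        if the string is not valid SMILES.
    UnsupportedElementError
        if an element has no principal-quantum-number entry.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles.strip(), sanitize=True)
    if mol is None:
        raise SmilesParseError(f"malformed SMILES: {smiles!r}")
    atoms = []
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        if sym not in PRINCIPAL_QUANTUM:
            raise UnsupportedElementError(f"unsupported element {sym!r} in {smiles!r}")
        Z = a.GetAtomicNum()
        Zv = _PT.GetNOuterElecs(Z)
        h = a.GetTotalNumHs()
        q = a.GetFormalCharge()
        atoms.append(
            AtomRecord(
                element=sym,
                Z=Z,
                Zv=Zv,
                h=h,
                formal_charge=q,
                aromatic=a.GetIsAromatic(),
                L=PRINCIPAL_QUANTUM[sym],
                delta=a.GetDegree(),
                valence_delta=_valence_delta(sym, Z, Zv, h, q),
            )
        )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    )
    n_components = len(Chem.GetMolFrags(mol))
    return MolecularGraph(atoms=tuple(atoms), bonds=bonds, components=n_components)


def distance_matrix(g: MolecularGraph) -> TopologicalDistances:
    """All-pairs shortest-path bond counts over the H-depleted graph."""
    n = g.n_atoms
    adj = np.zeros((n, n))
    for i, j, _ in g.bonds:
        adj[i, j] = adj[j, i] = 1
    d = shortest_path(adj, method="D", unweighted=True)
    out = np.where(np.isinf(d), DISCONNECTED, d).astype(int)
    return TopologicalDistances(matrix=out)


def constitutional(g: MolecularGraph) -> tuple[float, float, int, int, int]:
    """Constitutional indexes: (MW, AMW, nH, nC, nStructures).

    MW uses the two-decimal mass table including implicit hydrogens; AMW is
    MW divided by the total atom count (hydrogens included).
    """
    mw = 0.0
    n_h = 0
    n_c = 0
    for a in g.atoms:
        if a.element not in ATOMIC_MASS:
            raise UnsupportedElementError(f"no atomic mass for {a.element!r}")
        mw += ATOMIC_MASS[a.element] + a.h * ATOMIC_MASS["H"]
        n_h += a.h
        n_c += a.element == "C"
    total_atoms = g.n_atoms + n_h
    amw = mw / total_atoms if total_atoms else 0.0
    return mw, amw, n_h, n_c, g.components


def polarity_number(g: MolecularGraph, d: TopologicalDistances) -> int:
    """Number of unordered skeletal atom pairs at topological distance 3."""
    return int(np.count_nonzero(np.triu(d.matrix == 3, k=1)))


def connectivity_indexes(
    g: MolecularGraph, d: TopologicalDistances
) -> tuple[float, float, float, float]:
    """Connectivity-type indexes: (X1Av, X1sol, XMOD, RDCHI).

    X1v   = sum over skeletal bonds (dv_i * dv_j)^(-1/2); X1Av = X1v / bonds
    X1sol = (1/4) * sum over bonds (L_i * L_j) / sqrt(delta_i * delta_j)
    RDCHI = sum over bonds (RS_i * RS_j)^(-1/2), RS = reciprocal-distance
            row sums
    XMOD  = calibrated modified Randic-like vertex-contribution sum
            (see :func:`xmod_index`)

    Molecules without skeletal bonds return 0 for all four.
    """
    if g.n_bonds == 0:
        return 0.0, 0.0, 0.0, 0.0
    delta = np.array([a.delta for a in g.atoms], dtype=float)
    dv = np.array([a.valence_delta for a in g.atoms])
    L = np.array([a.L for a in g.atoms], dtype=float)
    ii = np.array([b[0] for b in g.bonds])
    jj = np.array([b[1] for b in g.bonds])

    x1v = float(np.sum(1.0 / np.sqrt(dv[ii] * dv[jj])))
    x1av = x1v / g.n_bonds
    x1sol = 0.25 * float(np.sum(L[ii] * L[jj] / np.sqrt(delta[ii] * delta[jj])))

    dm = d.matrix
    recip = np.where(dm > 0, 1.0 / np.maximum(dm, 1), 0.0)
    rs = recip.sum(axis=1)
    rdchi = float(np.sum(1.0 / np.sqrt(rs[ii] * rs[jj])))

    return x1av, x1sol, xmod_index(g), rdchi


def hbond_donors(g: MolecularGraph) -> int:
    """Count of hydrogen atoms attached to N or O (donor hydrogens)."""
    return sum(a.h for a in g.atoms if a.element in ("N", "O"))


# ---------------------------------------------------------------------------
# Calibrated descriptors (parameter tables shipped as package data)
# ---------------------------------------------------------------------------

def _load_params() -> dict:
    with resources.files("jamqspr.data").joinpath("bulk_contributions.json").open() as fh:
        return json.load(fh)


_PARAMS: dict | None = None


def _params() -> dict:
    global _PARAMS
    if _PARAMS is None:
        _PARAMS = _load_params()
    return _PARAMS


def _atom_class_key(a: AtomRecord) -> str:
    return f"{a.element}|q{a.formal_charge:+d}|d{a.delta}|h{a.h}|ar{int(a.aromatic)}"


def xmod_index(g: MolecularGraph) -> float:
    """Modified Randic-like index (calibrated).

    Additive vertex-contribution form c0 + c1*delta + c2*[O] + c3*h per
    skeletal atom; molecules without skeletal bonds return 0.  Coefficients
    live in the shipped parameter file.
    """
    if g.n_bonds == 0:
        return 0.0
    c0, c1, c2, c3 = _params()["XMOD"]["coefficients"]
    total = 0.0
    for a in g.atoms:
        total += c0 + c1 * a.delta + c2 * (a.element == "O") + c3 * a.h
    return total


def bulk_descriptors(g: MolecularGraph) -> tuple[float, float, float, float]:
    """Bulk/surface descriptors: (P_VSA_p_1, SAtot, VvdwMG, PDI).

    Additive per-atom-class contribution sums; the class of an atom is
    (element, formal charge, skeletal degree, hydrogen count, aromaticity).
    An empty graph returns zeros.
    """
    if g.n_atoms == 0:
        return 0.0, 0.0, 0.0, 0.0
    params = _params()
    out = []
    for name in ("P_VSA_p_1", "SAtot", "VvdwMG", "PDI"):
        table = params[name]["per_class"]
        total = 0.0
        for a in g.atoms:
            key = _atom_class_key(a)
            if key not in table:
                raise UnsupportedElementError(
                    f"atom class {key!r} absent from the {name} parameter table"
                )
            total += table[key]
        out.append(total)
    return tuple(out)


def compute_descriptors(smiles: str) -> DescriptorVector:
    """Compute the full fifteen-descriptor vector for one SMILES string."""
    g = parse_smiles(smiles)
    d = distance_matrix(g)
    mw, amw, n_h, n_c, n_struct = constitutional(g)
    x1av, x1sol, xmod, rdchi = connectivity_indexes(g, d)
    pvsa, satot, vvdw, pdi = bulk_descriptors(g)
    return DescriptorVector(
        values={
            "MW": mw,
            "AMW": amw,
            "nH": n_h,
            "nC": n_c,
            "nStructures": n_struct,
            "Pol": polarity_number(g, d),
            "X1Av": x1av,
            "X1sol": x1sol,
            "XMOD": xmod,
            "RDCHI": rdchi,
            "P_VSA_p_1": pvsa,
            "nHDon": hbond_donors(g),
            "SAtot": satot,
            "VvdwMG": vvdw,
            "PDI": pdi,
        }
    )


# ---------------------------------------------------------------------------
# File plumbing
# ---------------------------------------------------------------------------

def read_smi(path) -> list[tuple[str, str]]:
    """Read a ``.smi`` file: one SMILES plus optional name per line."""
    entries = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"mol{k}"
            entries.append((name, smiles))
    return entries


def descriptor_table(entries: Sequence[tuple[str, str]]):
    """Descriptor DataFrame (one row per molecule, columns in report order)."""
    import pandas as pd

    rows = {name: compute_descriptors(smi).values for name, smi in entries}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(DESCRIPTOR_NAMES))
    df.index.name = "name"
    return df
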
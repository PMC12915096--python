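"""Featurized directed molecular graphs and prediction-condition encoding.

A molecule is represented as a graph over heavy atoms whose hidden states will
live on *directed* edges: every chemical bond contributes two directed edges
(one per direction), and each edge knows the index of its reverse.  This is
the standard bond-centric (directed) message-passing representation.

Prediction conditions come in two flavours:

* a wavelength pair (absorption query in 300–900 nm, emission query in
  400–1200 nm) for the fluorescence-activity classifier, min–max scaled to
  ``[0, 1]^2``;
* a solvent SMILES for the photophysical regressors, which is featurized into
  its own :class:`MolGraph` and encoded by a dedicated solvent branch
  downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .errors import DomainError, InvalidStructureError

ABS_RANGE = (300.0, 900.0)
EM_RANGE = (400.0, 1200.0)

# element vocabulary; anything else falls into a trailing "other" slot
_ELEMENTS = (5, 6, 7, 8, 9, 14, 15, 16, 17, 35, 53)
_CHIRAL_TAGS = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)
_HYBRIDIZATIONS = (
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)
_BOND_ORDERS = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
_BOND_STEREO = (
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
)

#: atom feature width: element one-hot (+other), mass/100, valence 0-6,
#: formal charge -2..+2, chirality (+other), hybridization (+other), aromatic
ATOM_FDIM = (len(_ELEMENTS) + 1) + 1 + 7 + 5 + (len(_CHIRAL_TAGS) + 1) + (len(_HYBRIDIZATIONS) + 1) + 1
#: bond feature width: order one-hot, conjugation, ring membership, stereo
BOND_FDIM = len(_BOND_ORDERS) + 1 + 1 + len(_BOND_STEREO)


def _one_hot(value, choices, out, offset):
    try:
        idx = choices.index(value)
    except ValueError:
        idx = len(choices)  # "other" slot; caller must have reserved it
    out[offset + idx] = 1.0
    return offset + len(choices) + 1


@dataclass
class MolGraph:
    """A featurized heavy-atom molecular graph with directed edges."""

    n_atoms: int
    atom_features: np.ndarray  # (n_atoms, ATOM_FDIM) float32
    bond_features: np.ndarray  # (n_edges, BOND_FDIM) float32
    edge_src: np.ndarray       # (n_edges,) int64 source atom of each directed edge
    edge_dst: np.ndarray       # (n_edges,) int64 target atom
    reverse_index: np.ndarray  # (n_edges,) int64, involution without fixed points
    incoming: list = field(repr=False, default_factory=list)  # per-atom incoming edge ids

    @property
    def n_edges(self) -> int:
        return int(self.edge_src.shape[0])


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES, raising :class:`InvalidStructureError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidStructureError(str(smiles), "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(smiles)
    return mol


def atom_features(atom: Chem.Atom) -> np.ndarray:
    x = np.zeros(ATOM_FDIM, dtype=np.float32)
    off = _one_hot(atom.GetAtomicNum(), list(_ELEMENTS), x, 0)
    x[off] = atom.GetMass() / 100.0  # scaled so magnitudes stay O(1)
    off += 1
    valence = min(atom.GetTotalValence(), 6)
    x[off + valence] = 1.0
    off += 7
    charge = int(np.clip(atom.GetFormalCharge(), -2, 2))
    x[off + charge + 2] = 1.0
    off += 5
    off = _one_hot(atom.GetChiralTag(), list(_CHIRAL_TAGS), x, off)
    off = _one_hot(atom.GetHybridization(), list(_HYBRIDIZATIONS), x, off)
    x[off] = 1.0 if atom.GetIsAromatic() else 0.0
    return x


def bond_features(bond: Chem.Bond) -> np.ndarray:
    x = np.zeros(BOND_FDIM, dtype=np.float32)
    bt = bond.GetBondType()
    if bt in _BOND_ORDERS:
        x[_BOND_ORDERS.index(bt)] = 1.0
    off = len(_BOND_ORDERS)
    x[off] = 1.0 if bond.GetIsConjugated() else 0.0
    x[off + 1] = 1.0 if bond.IsInRing() else 0.0
    stereo = bond.GetStereo()
    if stereo in _BOND_STEREO:
        x[off + 2 + _BOND_STEREO.index(stereo)] = 1.0
    return x


def featurize_molecule(smiles: str) -> MolGraph:
    """Convert a SMILES string into a directed :class:`MolGraph`.

    Hydrogens are implicit: the graph is over heavy atoms only, and explicit-H
    spellings collapse to the same heavy-atom graph.  Each bond yields the
    directed edge pair ``(2i, 2i+1)`` so ``reverse_index`` is simply an XOR
    with 1.
    """
    mol = mol_from_smiles(smiles)
    n = mol.GetNumAtoms()
    afeat = np.zeros((n, ATOM_FDIM), dtype=np.float32)
    for atom in mol.GetAtoms():
        afeat[atom.GetIdx()] = atom_features(atom)

    n_bonds = mol.GetNumBonds()
    bfeat = np.zeros((2 * n_bonds, BOND_FDIM), dtype=np.float32)
    src = np.zeros(2 * n_bonds, dtype=np.int64)
    dst = np.zeros(2 * n_bonds, dtype=np.int64)
    for bond in mol.GetBonds():
        i = bond.GetIdx()
        f = bond_features(bond)
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bfeat[2 * i] = f
        bfeat[2 * i + 1] = f
        src[2 * i], dst[2 * i] = a, b
        src[2 * i + 1], dst[2 * i + 1] = b, a
    rev = np.arange(2 * n_bonds, dtype=np.int64) ^ 1

    incoming = [[] for _ in range(n)]
    for e in range(2 * n_bonds):
        incoming[dst[e]].append(e)
    incoming = [np.asarray(lst, dtype=np.int64) for lst in incoming]

    return MolGraph(
        n_atoms=n,
        atom_features=afeat,
        bond_features=bfeat,
        edge_src=src,
        edge_dst=dst,
        reverse_index=rev,
        incoming=incoming,
    )


@dataclass(frozen=True)
class WavelengthPair:
    """Absorption/emission query condition for the activity classifier (nm)."""

    abs_nm: float
    em_nm: float

    def __post_init__(self):
        if not (ABS_RANGE[0] <= self.abs_nm <= ABS_RANGE[1]):
            raise DomainError(
                f"absorption query {self.abs_nm} nm outside {ABS_RANGE}"
            )
        if not (EM_RANGE[0] <= self.em_nm <= EM_RANGE[1]):
            raise DomainError(f"emission query {self.em_nm} nm outside {EM_RANGE}")


def encode_condition(ctx) -> "np.ndarray | MolGraph":
    """Encode a prediction condition.

    A :class:`WavelengthPair` is min–max scaled by its admissible range into
    ``[0, 1]^2``.  A solvent SMILES (str) returns the solvent's
    :class:`MolGraph`, to be embedded by the solvent encoder downstream.
    """
    if isinstance(ctx, WavelengthPair):
        a = (ctx.abs_nm - ABS_RANGE[0]) / (ABS_RANGE[1] - ABS_RANGE[0])
        e = (ctx.em_nm - EM_RANGE[0]) / (EM_RANGE[1] - EM_RANGE[0])
        return np.array([a, e], dtype=np.float32)
    if isinstance(ctx, str):
        return featurize_molecule(ctx)
    raise DomainError(f"unsupported condition context: {ctx!r}")
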
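"""Structure standardization and molecular representations.

Two representations feed the models: folded extended-connectivity count
fingerprints of diameter 6 (ECFC6) for the dense networks, and heavy-atom
molecular graphs with 75 binary atom features for the graph convolutional
networks.

Standardization follows the common pharma preprocessing recipe: keep the
largest fragment, neutralize charges by (de)protonation, clear all stereo
annotations and (optionally) canonicalize the tautomer, so that one
physical compound maps to one canonical structure regardless of how the
registrar drew it.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "StandardizedMolecule",
    "MolecularGraph",
    "CountFingerprint",
    "MoleculeParseError",
    "standardize_molecule",
    "atom_features",
    "mol_to_graph",
    "ecfc_fingerprint",
    "N_ATOM_FEATURES",
]

N_ATOM_FEATURES = 75
FINGERPRINT_RADIUS = 3  # diameter 6


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or standardized."""


@dataclass(frozen=True)
class StandardizedMolecule:
    """A neutral, stereo-free, single-fragment structure."""

    mol: Chem.Mol
    canonical_smiles: str
    mol_weight: float

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()


@dataclass
class MolecularGraph:
    """Heavy-atom graph: binary node features, symmetric adjacency."""

    node_features: np.ndarray  # (n_atoms, 75), entries in {0, 1}
    adjacency: np.ndarray      # (n_atoms, n_atoms) bool, zero diagonal
    degrees: np.ndarray        # (n_atoms,) int

    def __post_init__(self):
        n = self.node_features.shape[0]
        if self.node_features.shape[1] != N_ATOM_FEATURES:
            raise ValueError(f"node feature width must be {N_ATOM_FEATURES}")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape mismatch")

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]


@dataclass
class CountFingerprint:
    """Folded circular count fingerprint (ECFC6)."""

    counts: np.ndarray
    n_bits: int
    diameter: int = 6

    def to_sparse_text(self) -> str:
        """Serialize as whitespace-separated ``index:count`` pairs."""
        idx = np.nonzero(self.counts)[0]
        return " ".join(f"{i}:{int(self.counts[i])}" for i in idx)


_largest_fragment = rdMolStandardize.LargestFragmentChooser()
_uncharger = rdMolStandardize.Uncharger()
_tautomer_enumerator = rdMolStandardize.TautomerEnumerator()


def standardize_molecule(smiles: str, canonical_tautomer: bool = True) -> StandardizedMolecule:
    """Standardize a SMILES string into a canonical neutral structure.

    Steps: parse, keep the largest fragment by heavy-atom count, neutralize
    by deprotonating bases / protonating acids, clear stereochemistry, and
    optionally pick the canonical tautomer.  Deterministic: the same input
    always yields the same canonical SMILES.

    Raises
    ------
    MoleculeParseError
        If the SMILES does not parse or cannot be sanitized.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES: {smiles!r}")
    try:
        mol = _largest_fragment.choose(mol)
        mol = _uncharger.uncharge(mol)
        if canonical_tautomer:
            mol = _tautomer_enumerator.Canonicalize(mol)
        Chem.RemoveStereochemistry(mol)
        mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
        if mol is None:
            raise MoleculeParseError(f"standardization produced invalid structure for {smiles!r}")
    except MoleculeParseError:
        raise
    except Exception as exc:  # pragma: no cover - RDKit-internal failures
        raise MoleculeParseError(f"standardization failed for {smiles!r}: {exc}") from exc
    return StandardizedMolecule(
        mol=mol,
        canonical_smiles=Chem.MolToSmiles(mol),
        mol_weight=Descriptors.MolWt(mol),
    )


# Element vocabulary for the one-hot block (43 symbols + an "other" slot).
# This matches the convention of the neural-fingerprint implementations the
# 75-feature layout originates from.
ELEMENTS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]
_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]


def _one_hot(value, choices, other_slot: bool = False) -> list:
    vec = [0.0] * (len(choices) + (1 if other_slot else 0))
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        if other_slot:
            vec[-1] = 1.0
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """75-dimensional feature vector for one heavy atom.

    Layout (sizes): element one-hot incl. "other" (44), heavy-atom degree
    one-hot 0-10 (11), implicit valence one-hot 0-6 (7), formal charge (1),
    radical electrons (1), hybridization one-hot SP/SP2/SP3/SP3D/SP3D2 (5),
    aromaticity flag (1), total hydrogen count one-hot 0-4 (5).
    """
    features = (
        _one_hot(atom.GetSymbol(), ELEMENTS, other_slot=True)
        + _one_hot(atom.GetDegree(), list(range(11)))
        + _one_hot(atom.GetImplicitValence(), list(range(7)))
        + [float(atom.GetFormalCharge()), float(atom.GetNumRadicalElectrons())]
        + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _one_hot(atom.GetTotalNumHs(), list(range(5)))
    )
    out = np.array(features, dtype=np.float64)
    assert out.shape == (N_ATOM_FEATURES,)
    return out


def mol_to_graph(molecule: StandardizedMolecule) -> MolecularGraph:
    """Build the heavy-atom graph.  Bond types are not distinguished."""
    mol = molecule.mol
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError("cannot build a graph for a molecule with no heavy atoms")
    feats = np.stack([atom_features(mol.GetAtomWithIdx(i)) for i in range(n)])
    adjacency = Chem.GetAdjacencyMatrix(mol).astype(bool)
    return MolecularGraph(node_features=feats, adjacency=adjacency,
                          degrees=adjacency.sum(axis=1).astype(int))


def _initial_invariant(atom: Chem.Atom) -> int:
    """ECFP-style initial atom identifier (Daylight-like invariants)."""
    payload = struct.pack(
        "<7i",
        atom.GetAtomicNum(),
        atom.GetDegree(),
        atom.GetTotalNumHs(),
        atom.GetFormalCharge(),
        int(atom.GetIsAromatic()),
        int(atom.IsInRing()),
        int(atom.GetMass()),
    )
    return zlib.crc32(payload) & 0xFFFFFFFF


def _hash_ids(radius: int, own: int, neighbor_ids: list[int]) -> int:
    payload = struct.pack(f"<{2 + len(neighbor_ids)}I", radius, own, *sorted(neighbor_ids))
    return zlib.crc32(payload) & 0xFFFFFFFF


def ecfc_fingerprint(molecule: StandardizedMolecule, n_bits: int = 2048) -> CountFingerprint:
    """Extended-connectivity count fingerprint of diameter 6, folded.

    Every heavy atom emits one 32-bit circular identifier per radius
    0..3 (iteratively hashing its own identifier with the sorted identifiers
    of its neighbours), so the unfolded multiset holds exactly
    ``4 * n_atoms`` identifiers.  Folding is modulo reduction into `n_bits`
    buckets accumulating counts, which conserves the total count.
    """
    if n_bits not in (1024, 2048):
        raise ValueError("fingerprint length must be 1024 or 2048")
    mol = molecule.mol
    n = mol.GetNumAtoms()
    neighbors = [[b.GetIdx() for b in mol.GetAtomWithIdx(i).GetNeighbors()] for i in range(n)]
    ids = [_initial_invariant(mol.GetAtomWithIdx(i)) for i in range(n)]
    counts = np.zeros(n_bits, dtype=np.int64)
    for i in ids:
        counts[i % n_bits] += 1
    for radius in range(1, FINGERPRINT_RADIUS + 1):
        ids = [_hash_ids(radius, ids[i], [ids[j] for j in neighbors[i]]) for i in range(n)]
        for i in ids:
            counts[i % n_bits] += 1
    return CountFingerprint(counts=counts, n_bits=n_bits)


def fingerprint_matrix(molecules, n_bits: int = 2048) -> np.ndarray:
    """Stack fingerprints of an iterable of molecules into an (n, bits) array."""
    return np.stack([ecfc_fingerprint(m, n_bits).counts for m in molecules]).astype(np.float64)
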
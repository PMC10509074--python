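"""Fixed-length bit-vector featurizers and atom masking.

Two featurizers feed the random-forest baselines:

* **Morgan** — hashed circular substructures of the ligand's 2D graph
  (radius 2 by default); purely ligand-based, no coordinates consulted.
* **PLEC-style** — for every (ligand atom, synthetic residue) pair closer
  than a distance cutoff, the ligand atom's circular environments up to a
  depth (default 3) are hashed together with the residue's identity.  A
  synthetic residue is a single unconnected typed atom, so its depth is 0
  and its identity is its type.  The hashing is a stable 64-bit digest
  folded modulo the bit-vector length; like any hashed fingerprint it
  tolerates collisions, and no bit-for-bit match with other interaction
  fingerprint implementations is promised — only pair locality and cutoff
  response.

Masking replaces one atom by a typeless dummy that keeps its coordinates
and bonds but carries no element identity, generates no substructure
environments and enters no contact pairs; masked fingerprints drive the
per-atom attribution scores.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from functools import singledispatch

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.distance import cdist

from synthscreen.ligand_chem import Ligand
from synthscreen.synth_generator import SyntheticComplex


@dataclass(frozen=True)
class FeaturizerConfig:
    """Fingerprint parameters; lengths and the PLEC cutoff are configurable."""

    morgan_radius: int = 2
    morgan_bits: int = 2048
    plec_cutoff: float = 4.5
    plec_ligand_depth: int = 3
    plec_protein_depth: int = 0
    plec_bits: int = 16384

    def __post_init__(self):
        if self.morgan_radius < 0 or self.plec_ligand_depth < 0 or self.plec_protein_depth < 0:
            raise ValueError("radii/depths must be >= 0")
        if self.plec_cutoff <= 0:
            raise ValueError("plec_cutoff must be positive")


@dataclass(frozen=True)
class FingerprintVector:
    """Sparse binary fingerprint: sorted indices of set bits."""

    indices: np.ndarray
    n_bits: int
    tag: str  # "morgan" | "plec"
    params: FeaturizerConfig

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        if len(idx) and (idx[0] < 0 or idx[-1] >= self.n_bits):
            raise ValueError("set bit outside the vector length")
        object.__setattr__(self, "indices", idx)

    def to_dense(self) -> np.ndarray:
        v = np.zeros(self.n_bits, dtype=np.uint8)
        v[self.indices] = 1
        return v

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FingerprintVector)
            and self.n_bits == other.n_bits
            and self.tag == other.tag
            and np.array_equal(self.indices, other.indices)
        )


def _prepared_mol(ligand: Ligand) -> Chem.Mol:
    """Molecule with the masked atom (if any) replaced by a dummy."""
    if ligand.masked_atom is None:
        return ligand.mol
    mol = Chem.RWMol(ligand.mol)
    atom = mol.GetAtomWithIdx(ligand.masked_atom)
    atom.SetAtomicNum(0)
    atom.SetFormalCharge(0)
    atom.SetNoImplicit(True)
    atom.SetNumExplicitHs(0)
    mol.UpdatePropertyCache(strict=False)
    Chem.GetSymmSSSR(mol)
    return mol.GetMol()


def morgan_fingerprint(ligand: Ligand, config: FeaturizerConfig) -> FingerprintVector:
    """Hashed circular-substructure bit vector of the ligand's 2D graph.

    A masked atom contributes no environments of its own (it is excluded as
    an environment center) and appears as a typeless dummy in environments
    centered on its neighbours.
    """
    mol = _prepared_mol(ligand)
    from_atoms = [
        a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() != ligand.masked_atom
    ]
    bv = AllChem.GetMorganFingerprintAsBitVect(
        mol, config.morgan_radius, nBits=config.morgan_bits, fromAtoms=from_atoms
    )
    return FingerprintVector(
        indices=np.array(bv.GetOnBits(), dtype=np.int64),
        n_bits=config.morgan_bits,
        tag="morgan",
        params=config,
    )


def _atom_environments(mol: Chem.Mol, depth: int) -> dict:
    """Map ``(atom index, radius)`` to the unhashed circular-environment id."""
    info: dict = {}
    AllChem.GetMorganFingerprint(mol, depth, bitInfo=info)
    env: dict = {}
    for env_id, entries in info.items():
        for atom_idx, radius in entries:
            env[(atom_idx, radius)] = env_id
    return env


def _pair_bit(env_id: int, residue_type: str, radius: int, n_bits: int) -> int:
    key = f"{env_id}|{residue_type}|{radius}".encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return int.from_bytes(digest, "big") % n_bits


def plec_fingerprint(
    cmplx: SyntheticComplex, config: FeaturizerConfig
) -> FingerprintVector:
    """Protein-ligand contact fingerprint over pairs within the cutoff.

    For every (ligand atom, residue) pair with distance strictly below
    ``plec_cutoff``, the ligand atom's environments at radii
    ``0..plec_ligand_depth`` are each hashed with the residue type.  An empty
    pair set yields the zero vector; residues beyond the cutoff never affect
    the result.
    """
    ligand = cmplx.ligand
    mol = _prepared_mol(ligand)
    bits: set[int] = set()
    if cmplx.protein.n_res > 0:
        dists = cdist(ligand.coords(), cmplx.protein.coords)
        env = _atom_environments(mol, config.plec_ligand_depth)
        pairs = np.argwhere(dists < config.plec_cutoff)
        for atom_idx, res_idx in pairs:
            if atom_idx == ligand.masked_atom:
                continue
            rtype = cmplx.protein.types[res_idx]
            for radius in range(config.plec_ligand_depth + 1):
                env_id = env.get((int(atom_idx), radius))
                if env_id is None:
                    continue
                bits.add(_pair_bit(env_id, rtype, radius, config.plec_bits))
    return FingerprintVector(
        indices=np.array(sorted(bits), dtype=np.int64),
        n_bits=config.plec_bits,
        tag="plec",
        params=config,
    )


def save_fingerprint_matrix(X, config: FeaturizerConfig, tag: str, prefix) -> None:
    """Persist a sparse fingerprint matrix as CSR triples plus a JSON sidecar.

    Writes ``<prefix>.csr.csv`` (columns data, indices, indptr padded with
    blanks) and ``<prefix>.json`` (shape, tag and featurizer parameters).
    """
    import json
    from dataclasses import asdict

    import pandas as pd
    from scipy import sparse

    X = sparse.csr_matrix(X)
    cols = {
        "data": pd.Series(X.data),
        "indices": pd.Series(X.indices),
        "indptr": pd.Series(X.indptr),
    }
    pd.DataFrame(cols).to_csv(f"{prefix}.csr.csv", index=False)
    with open(f"{prefix}.json", "w") as fh:
        json.dump({"shape": list(X.shape), "tag": tag, "params": asdict(config)}, fh)


def load_fingerprint_matrix(prefix):
    """Invert :func:`save_fingerprint_matrix`; returns (X, config, tag)."""
    import json

    import pandas as pd
    from scipy import sparse

    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    df = pd.read_csv(f"{prefix}.csr.csv")
    data = df["data"].dropna().to_numpy(np.float32)
    indices = df["indices"].dropna().to_numpy(np.int64)
    indptr = df["indptr"].dropna().to_numpy(np.int64)
    X = sparse.csr_matrix((data, indices, indptr), shape=tuple(meta["shape"]))
    return X, FeaturizerConfig(**meta["params"]), meta["tag"]


@singledispatch
def mask_atom(obj, atom_index: int):
    """Return a copy of a ligand or complex with one atom masked to a dummy.

    The original object is unmodified.  The dummy keeps coordinates and
    bonds but has no element identity, no pharmacophore types, and yields
    no Morgan environments and no PLEC pairs.
    """
    raise TypeError(f"cannot mask a {type(obj).__name__}")


@mask_atom.register
def _(obj: Ligand, atom_index: int) -> Ligand:
    if not 0 <= atom_index < obj.mol.GetNumAtoms():
        raise IndexError(
            f"atom index {atom_index} out of range for {obj.mol.GetNumAtoms()} atoms"
        )
    return replace(obj, mol=Chem.Mol(obj.mol), masked_atom=int(atom_index))


@mask_atom.register
def _(obj: SyntheticComplex, atom_index: int) -> SyntheticComplex:
    masked_ligand = mask_atom(obj.ligand, atom_index)
    return replace(obj, ligand=masked_ligand)
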
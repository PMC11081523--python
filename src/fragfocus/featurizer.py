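"""Fragment-aware molecular feature vectors.

Each molecule becomes the concatenation of three blocks:

1. a folded circular (Morgan/ECFP) fingerprint, default 1024 bits, radius 2;
2. one Tanimoto similarity per library fragment, computed between the
   molecule's fingerprint and the fragment's fingerprint under the same
   configuration, in library order;
3. a single fragment match count: the number of library fragments embedded
   in the molecule as substructures.

With the default 1024 bits and a 266-fragment library this yields
1024 + 266 + 1 = 1291 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from fragfocus.chem_io import ChemIOError, Dataset, MoleculeRecord
from fragfocus.fragment_miner import FragmentLibrary, parse_fragment_smiles

MATCH_DEFINITIONS = ("substructure", "similarity_threshold")


@dataclass(frozen=True)
class FeaturizerConfig:
    """Fingerprint size/radius and the fragment-match definition.

    ``match_definition="substructure"`` counts fragments embedded as
    substructures; ``"similarity_threshold"`` instead counts fragments whose
    fingerprint Tanimoto to the molecule reaches ``similarity_threshold``
    (a sensitivity-analysis alternative).
    """

    n_bits: int = 1024
    fp_radius: int = 2
    match_definition: str = "substructure"
    similarity_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.n_bits < 1 or (self.n_bits & (self.n_bits - 1)) != 0:
            raise ValueError("n_bits must be a power of two")
        if self.fp_radius < 1:
            raise ValueError("fp_radius must be >= 1")
        if self.match_definition not in MATCH_DEFINITIONS:
            raise ValueError(f"unknown match_definition {self.match_definition!r}")

    def column_names(self, lib_size: int) -> list[str]:
        return (
            [f"bit_{i}" for i in range(self.n_bits)]
            + [f"frag_{j}" for j in range(lib_size)]
            + ["frag_match_count"]
        )


def _generator(cfg: FeaturizerConfig):
    return rdFingerprintGenerator.GetMorganGenerator(radius=cfg.fp_radius, fpSize=cfg.n_bits)


def _as_mol(record: MoleculeRecord | Chem.Mol | str) -> Chem.Mol:
    if isinstance(record, Chem.Mol):
        return record
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemIOError(f"invalid structure: {smiles!r}")
    return mol


def ecfp(record: MoleculeRecord | Chem.Mol | str, cfg: FeaturizerConfig = FeaturizerConfig()) -> np.ndarray:
    """Folded circular fingerprint as a uint8 0/1 vector of length ``n_bits``."""
    fp = _generator(cfg).GetFingerprint(_as_mol(record))
    arr = np.zeros(cfg.n_bits, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| on 0/1 vectors; 0.0 when both are all-zero."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def fragment_fingerprints(lib: FragmentLibrary, cfg: FeaturizerConfig = FeaturizerConfig()) -> np.ndarray:
    """Fingerprints of the library fragments, shape (len(lib), n_bits), library order."""
    gen = _generator(cfg)
    out = np.zeros((len(lib), cfg.n_bits), dtype=np.uint8)
    for j, frag in enumerate(lib):
        fp = gen.GetFingerprint(parse_fragment_smiles(frag.smiles))
        for b in fp.GetOnBits():
            out[j, b] = 1
    return out


def fragment_match_count(
    record: MoleculeRecord | Chem.Mol | str,
    lib: FragmentLibrary,
    cfg: FeaturizerConfig = FeaturizerConfig(),
) -> int:
    """Number of library fragments matching the molecule.

    Under the default substructure definition a fragment matches when it
    embeds in the molecule; under the similarity-threshold definition, when
    its fingerprint Tanimoto to the molecule reaches the configured
    threshold.
    """
    mol = _as_mol(record)
    if len(lib) == 0:
        return 0
    if cfg.match_definition == "substructure":
        return sum(1 for q in lib.query_mols() if mol.HasSubstructMatch(q))
    mol_fp = ecfp(mol, cfg)
    frag_fps = fragment_fingerprints(lib, cfg)
    return int(sum(tanimoto(mol_fp, f) >= cfg.similarity_threshold for f in frag_fps))


def _bulk_tanimoto(mol_fps: np.ndarray, frag_fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto, rows = molecules, columns = fragments."""
    m = mol_fps.astype(np.float32)
    f = frag_fps.astype(np.float32)
    inter = m @ f.T
    union = m.sum(axis=1, keepdims=True) + f.sum(axis=1, keepdims=True).T - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(union > 0, inter / union, 0.0)
    return sims


def featurize_record(
    record: MoleculeRecord | Chem.Mol | str,
    lib: FragmentLibrary,
    cfg: FeaturizerConfig = FeaturizerConfig(),
) -> np.ndarray:
    """Feature vector [fp bits | fragment similarities | match count] for one molecule."""
    mol = _as_mol(record)
    bits = ecfp(mol, cfg)
    frag_fps = fragment_fingerprints(lib, cfg)
    sims = _bulk_tanimoto(bits[None, :], frag_fps)[0] if len(lib) else np.zeros(0)
    count = fragment_match_count(mol, lib, cfg)
    return np.concatenate([bits.astype(np.float64), sims.astype(np.float64), [float(count)]])


def featurize(
    data: Dataset | Sequence[MoleculeRecord],
    lib: FragmentLibrary,
    cfg: FeaturizerConfig = FeaturizerConfig(),
) -> pd.DataFrame:
    """Feature matrix for a dataset; rows follow dataset order, index = record ids.

    Columns are ``bit_0..bit_{n-1}``, ``frag_0..frag_{k-1}`` (library
    order), and ``frag_match_count``.  Records whose structure does not
    parse are collected into a single error listing every offending id.
    """
    records = list(data)
    bad = []
    mols = []
    for r in records:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is None:
            bad.append(r.id)
        mols.append(mol)
    if bad:
        raise ChemIOError(f"invalid structures for records: {bad}")

    gen = _generator(cfg)
    mol_fps = np.zeros((len(mols), cfg.n_bits), dtype=np.uint8)
    for i, mol in enumerate(mols):
        for b in gen.GetFingerprint(mol).GetOnBits():
            mol_fps[i, b] = 1

    if len(lib):
        frag_fps = fragment_fingerprints(lib, cfg)
        sims = _bulk_tanimoto(mol_fps, frag_fps)
        if cfg.match_definition == "substructure":
            queries = lib.query_mols()
            counts = np.array(
                [sum(1 for q in queries if mol.HasSubstructMatch(q)) for mol in mols], dtype=np.float64
            )
        else:
            counts = (sims >= cfg.similarity_threshold).sum(axis=1).astype(np.float64)
    else:
        sims = np.zeros((len(mols), 0))
        counts = np.zeros(len(mols))

    X = np.hstack([mol_fps.astype(np.float64), sims, counts[:, None]])
    return pd.DataFrame(X, columns=cfg.column_names(len(lib)), index=[r.id for r in records])
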
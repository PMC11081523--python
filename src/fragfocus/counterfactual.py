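"""Molecular counterfactuals: minimal edits that flip the model's decision.

A counterfactual for a screened compound is a chemically valid variant,
produced by small local edits, whose predicted class differs from the
base compound's.  Ranking flipped variants by fingerprint similarity to
the base surfaces the smallest decisive changes; annotating which mined
fragments are lost, retained, or gained by the edit ties the explanation
back to the fragment library the model was trained with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from rdkit import Chem

from fragfocus.chem_io import ChemIOError, Dataset, MoleculeRecord
from fragfocus.ensemble import EnsembleModel
from fragfocus.featurizer import FeaturizerConfig, ecfp, featurize, tanimoto
from fragfocus.fragment_miner import FragmentLibrary

#: elements tried by atom substitution / insertion edits
_EDIT_ELEMENTS = (6, 7, 8, 9, 16, 17)
_BOND_ORDERS = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)


@dataclass(frozen=True)
class Counterfactual:
    """One decision-flipping variant of a base compound."""

    base_id: str
    variant_smiles: str
    similarity_to_base: float
    base_label: bool
    variant_label: bool
    votes_variant: int

    def __post_init__(self) -> None:
        if self.variant_label == self.base_label:
            raise ValueError("a counterfactual must flip the label")
        if not 0.0 <= self.similarity_to_base <= 1.0:
            raise ValueError("similarity must be in [0, 1]")


def _random_edit(mol: Chem.Mol, rng: np.random.Generator) -> Optional[str]:
    """Apply one random local edit; return the canonical variant SMILES or None.

    Edits operate on a kekulized copy (atom substitution, bond-order
    change, terminal-atom deletion, single-atom insertion); full RDKit
    sanitization of the result is the validity guarantee.
    """
    rw = Chem.RWMol(mol)
    try:
        Chem.Kekulize(rw, clearAromaticFlags=True)
    except Chem.KekulizeException:
        return None
    n_atoms = rw.GetNumAtoms()
    if n_atoms == 0:
        return None
    op = rng.integers(4)
    try:
        if op == 0:  # substitute an atom's element
            a = rw.GetAtomWithIdx(int(rng.integers(n_atoms)))
            choices = [z for z in _EDIT_ELEMENTS if z != a.GetAtomicNum()]
            a.SetAtomicNum(int(choices[rng.integers(len(choices))]))
            a.SetFormalCharge(0)
            a.SetNumExplicitHs(0)
        elif op == 1:  # change a bond order
            if rw.GetNumBonds() == 0:
                return None
            b = rw.GetBondWithIdx(int(rng.integers(rw.GetNumBonds())))
            choices = [o for o in _BOND_ORDERS if o != b.GetBondType()]
            b.SetBondType(choices[rng.integers(len(choices))])
        elif op == 2:  # delete a terminal atom
            terminal = [a.GetIdx() for a in rw.GetAtoms() if a.GetDegree() == 1]
            if not terminal or n_atoms <= 2:
                return None
            rw.RemoveAtom(int(terminal[rng.integers(len(terminal))]))
        else:  # insert a single atom at a random position
            host = int(rng.integers(n_atoms))
            new_z = int(_EDIT_ELEMENTS[rng.integers(len(_EDIT_ELEMENTS))])
            new_idx = rw.AddAtom(Chem.Atom(new_z))
            rw.AddBond(host, new_idx, Chem.BondType.SINGLE)
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except (Chem.AtomValenceException, Chem.KekulizeException, Chem.AtomKekulizeException, RuntimeError):
        return None
    return Chem.MolToSmiles(out)


def perturb_molecule(
    record: MoleculeRecord | str, n_samples: int, seed: int = 0, max_attempts_per_sample: int = 25
) -> list[str]:
    """Up to *n_samples* unique, valid variant SMILES from seeded local edits.

    The base structure is excluded; results are reproducible for a seed.
    """
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    base = Chem.MolFromSmiles(smiles)
    if base is None:
        raise ChemIOError(f"invalid base structure: {smiles!r}")
    base_canon = Chem.MolToSmiles(base)
    rng = np.random.default_rng(seed)
    variants: list[str] = []
    seen = {base_canon}
    attempts = 0
    while len(variants) < n_samples and attempts < n_samples * max_attempts_per_sample:
        attempts += 1
        smi = _random_edit(base, rng)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        variants.append(smi)
    return variants


def _decide(model: EnsembleModel, X, member: Optional[str]) -> tuple[np.ndarray, np.ndarray]:
    """(boolean decisions, ensemble votes) for the rows of X."""
    votes = model.predict_votes(X)
    if member is not None:
        probs = model.member_probabilities(X)[member].to_numpy()
        return probs >= 0.5, votes
    return votes >= model.vote_threshold, votes


def find_counterfactuals(
    model: EnsembleModel,
    record: MoleculeRecord | str,
    lib: FragmentLibrary,
    cfg: FeaturizerConfig = FeaturizerConfig(),
    n_samples: int = 2000,
    top_k: int = 10,
    seed: int = 0,
    member: Optional[str] = None,
) -> list[Counterfactual]:
    """The *top_k* decision-flipping variants, ranked by similarity to the base.

    By default the flip is judged against the ensemble consensus at the
    model's vote threshold; pass ``member`` to explain a single member's
    decision instead (the reported vote counts are always ensemble votes).
    An empty result (no variant flips) is valid and raises a warning.
    """
    rec = record if isinstance(record, MoleculeRecord) else MoleculeRecord("base", record)
    variants = perturb_molecule(rec, n_samples, seed)
    pool = [rec] + [MoleculeRecord(f"variant{i}", s) for i, s in enumerate(variants)]
    X = featurize(Dataset(pool), lib, cfg)
    decisions, votes = _decide(model, X, member)
    base_label = bool(decisions[0])

    base_fp = ecfp(rec.smiles, cfg)
    flipped = []
    for i, smi in enumerate(variants, start=1):
        if bool(decisions[i]) == base_label:
            continue
        flipped.append(
            Counterfactual(
                base_id=rec.id,
                variant_smiles=smi,
                similarity_to_base=tanimoto(base_fp, ecfp(smi, cfg)),
                base_label=base_label,
                variant_label=not base_label,
                votes_variant=int(votes[i]),
            )
        )
    if not flipped:
        warnings.warn("no counterfactual found: no generated variant flips the decision")
        return []
    flipped.sort(key=lambda c: (-c.similarity_to_base, c.variant_smiles))
    return flipped[:top_k]


def annotate_fragment_overlap(cf: Counterfactual, lib: FragmentLibrary, base_smiles: Optional[str] = None):
    """Per-fragment change flags between the base molecule and the variant.

    Each library fragment is reported as retained (matched both), lost
    (base only), gained (variant only), or absent.  ``base_smiles`` must be
    supplied when the counterfactual's ``base_id`` is not resolvable.
    """
    import pandas as pd

    if base_smiles is None:
        raise ValueError("base_smiles is required to annotate fragment overlap")
    base = Chem.MolFromSmiles(base_smiles)
    variant = Chem.MolFromSmiles(cf.variant_smiles)
    if base is None or variant is None:
        raise ChemIOError("invalid base or variant structure")
    rows = []
    for j, (frag, q) in enumerate(zip(lib, lib.query_mols())):
        b = base.HasSubstructMatch(q)
        v = variant.HasSubstructMatch(q)
        status = "retained" if b and v else "lost" if b else "gained" if v else "absent"
        rows.append(
            {
                "fragment_index": j,
                "fragment_smiles": frag.smiles,
                "base_match": bool(b),
                "variant_match": bool(v),
                "status": status,
            }
        )
    return pd.DataFrame(rows)
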
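"""Shared test vocabulary and fake model members."""

import numpy as np
from rdkit import Chem

#: small valid molecules (<= 8 heavy atoms, no fused ring systems) used to
#: build random datasets for the miner/oracle comparisons
SMALL_MOLECULES = [
    "c1ccccc1",
    "c1ccncc1",
    "c1ccoc1",
    "c1ccsc1",
    "C1CCCC1",
    "C1CCCCC1",
    "Oc1ccccc1",
    "Cc1ccncc1",
    "Cc1ccco1",
    "Clc1ccccc1",
    "CCO",
    "CC(C)O",
    "CCN",
    "CC(=O)O",
    "CC(=O)C",
    "CCCC",
    "CC#N",
    "CCS",
    "C=CCC",
    "NCCO",
    "COC",
    "CNC(C)=O",
    "OCC(C)C",
    "O=C1CCCC1",
]


def distinct_acyclic_smiles(n, elements="CNO", max_len=8):
    """*n* distinct simple acyclic molecules made of the given elements."""
    out, seen = [], set()
    from itertools import product

    for length in range(1, max_len + 1):
        for combo in product(elements, repeat=length):
            smi = "".join(combo)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            seen.add(canon)
            out.append(canon)
            if len(out) == n:
                return out
    raise ValueError(f"could not build {n} distinct molecules")


class FakeMember:
    """A fixed-probability classifier standing in for a fitted member."""

    def __init__(self, probs=None, constant=None):
        self._probs = None if probs is None else np.asarray(probs, dtype=float)
        self._constant = constant

    def predict_proba(self, X):
        n = len(X)
        p = np.full(n, self._constant) if self._probs is None else self._probs[:n]
        return np.column_stack([1 - p, p])
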
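"""Seeded synthetic benchmarks with the statistical structure the pipeline assumes.

The generator emulates three inputs without any download: (a) an
imbalanced labeled bioactivity set whose actives are enriched for a small
number of planted ring scaffolds, (b) a scaffold-free assumed-inactive
decoy pool standing in for a commercial chemical directory sample, and
(c) a large screening stream mixing decoys with planted-scaffold
molecules at a known rate.  Molecules are built by decorating curated,
valid ring systems with small substituents, which guarantees parseability
without a generative model; potencies are drawn log-normally per class and
the labels are then re-derived through the 10,000 nM cutoff so the
generator and the labeler always agree.  Nothing here imitates real
target chemistry — the benchmark tests statistical structure, not
pharmacology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from rdkit import Chem

from fragfocus.chem_io import Dataset, LabelingConfig, MoleculeRecord, assign_labels
from fragfocus.fragment_miner import fragment_query, parse_fragment_smiles

logger = logging.getLogger(__name__)

#: ring systems planted in actives (the "pharmacophore" the miner must recover)
PLANTED_SCAFFOLDS = ("c1ccncc1", "c1cncnc1", "c1cc[nH]n1")

#: scaffold-free decoy cores (none contains a planted scaffold)
DECOY_CORES = (
    "c1ccccc1",
    "c1ccsc1",
    "c1ccoc1",
    "C1CCCCC1",
    "C1CCCC1",
    "C1CCOC1",
    "C1CCNCC1",
)

#: substituents; the first atom is the attachment point
SUBSTITUENTS = ("C", "CC", "F", "Cl", "O", "OC", "N", "C(F)(F)F", "C#N", "C(C)=O")

_CONC_TYPES = ("Kd", "EC50", "IC50")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: 1:9 active/inactive imbalance, 3 planted scaffolds carried by
    90% of actives and 2% of inactives, log-potencies centered at 100 nM
    (actives) and 100,000 nM (inactives) with 0.4 log10 spread.
    """

    n_active: int = 50
    n_inactive: int = 450
    n_scaffolds: int = 3
    scaffold_penetrance: float = 0.9
    inactive_contamination: float = 0.02
    potency_log_mean_active: float = 2.0
    potency_log_mean_inactive: float = 5.0
    potency_log_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("class counts must be >= 1")
        if not 1 <= self.n_scaffolds <= len(PLANTED_SCAFFOLDS):
            raise ValueError(f"n_scaffolds must be in [1, {len(PLANTED_SCAFFOLDS)}]")
        if not self.scaffold_penetrance > self.inactive_contamination:
            raise ValueError("scaffold_penetrance must exceed inactive_contamination")


def _scaffold_queries(scaffolds: Iterable[str]):
    return [fragment_query(parse_fragment_smiles(s)) for s in scaffolds]


def _decorate(core: str, rng: np.random.Generator) -> Optional[str]:
    """Attach 1-3 random substituents to carbon positions of *core*."""
    mol = Chem.MolFromSmiles(core)
    n_subs = int(rng.integers(1, 4))
    for _ in range(n_subs):
        sub = Chem.MolFromSmiles(SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))])
        sites = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1 and a.IsInRing()
        ]
        if not sites:
            return None
        site = int(sites[rng.integers(len(sites))])
        combined = Chem.RWMol(Chem.CombineMols(mol, sub))
        combined.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
        try:
            out = combined.GetMol()
            Chem.SanitizeMol(out)
        except (Chem.AtomValenceException, Chem.KekulizeException):
            return None
        mol = out
    return Chem.MolToSmiles(mol)


def _sample_molecule(
    rng: np.random.Generator,
    scaffolds: list[str],
    scaffolded: bool,
    forbidden: set[str],
    scaffold_queries,
    max_attempts: int = 200,
) -> Optional[str]:
    """One unique decorated molecule; decoys must not embed any planted scaffold."""
    for _ in range(max_attempts):
        core = (
            scaffolds[rng.integers(len(scaffolds))]
            if scaffolded
            else DECOY_CORES[rng.integers(len(DECOY_CORES))]
        )
        smi = _decorate(core, rng)
        if smi is None or smi in forbidden:
            continue
        if not scaffolded:
            mol = Chem.MolFromSmiles(smi)
            if any(mol.HasSubstructMatch(q) for q in scaffold_queries):
                continue
        return smi
    return None


def generate_benchmark(cfg: BenchmarkConfig = BenchmarkConfig()) -> tuple[Dataset, list[str]]:
    """A labeled benchmark dataset plus the planted scaffold SMILES.

    Actives carry a planted scaffold at the configured penetrance and draw
    potencies around the active log-mean; inactives are scaffold-free
    decoys except for the contamination fraction.  Labels are re-derived
    from the drawn potencies by the 10,000 nM cutoff, so a few records may
    cross class lines — exactly the label noise a potency cutoff produces.
    """
    rng = np.random.default_rng(cfg.seed)
    scaffolds = list(PLANTED_SCAFFOLDS[: cfg.n_scaffolds])
    queries = _scaffold_queries(scaffolds)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []

    def build(n: int, prefix: str, p_scaffold: float, log_mean: float) -> None:
        # exact scaffold counts (ceil) rather than Bernoulli draws, so the
        # stated penetrance is a guaranteed floor at any sample size
        flags = np.zeros(n, dtype=bool)
        flags[: int(np.ceil(p_scaffold * n))] = True
        rng.shuffle(flags)
        for i in range(n):
            scaffolded = bool(flags[i])
            smi = _sample_molecule(rng, scaffolds, scaffolded, seen, queries)
            if smi is None:
                raise RuntimeError("could not generate a unique molecule; vocabulary exhausted")
            seen.add(smi)
            potency = float(10 ** rng.normal(log_mean, cfg.potency_log_sd))
            ptype = _CONC_TYPES[rng.integers(len(_CONC_TYPES))]
            records.append(MoleculeRecord(f"{prefix}{i:04d}", smi, potency, ptype))

    build(cfg.n_active, "A", cfg.scaffold_penetrance, cfg.potency_log_mean_active)
    build(cfg.n_inactive, "I", cfg.inactive_contamination, cfg.potency_log_mean_inactive)
    ds = assign_labels(Dataset(records, f"benchmark-seed{cfg.seed}"), LabelingConfig())
    return ds, scaffolds


def generate_negative_pool(
    n: int, seed: int = 0, exclude: Iterable[str] = (), n_scaffolds: int = 3
) -> Dataset:
    """*n* scaffold-free decoys, unlabeled (assumed inactive).

    Pass the paired benchmark's SMILES as *exclude* to guarantee the pool
    is disjoint from the training data, mirroring a held-out directory
    sample used for false-positive estimation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed + 1_000_003)  # distinct stream from the benchmark
    scaffolds = list(PLANTED_SCAFFOLDS[:n_scaffolds])
    queries = _scaffold_queries(scaffolds)
    seen: set[str] = set(exclude)
    records = []
    for i in range(n):
        smi = _sample_molecule(rng, scaffolds, False, seen, queries)
        if smi is None:
            raise RuntimeError("could not generate a unique decoy; vocabulary exhausted")
        seen.add(smi)
        records.append(MoleculeRecord(f"ACD{i:04d}", smi))
    return Dataset(records, f"negative-pool-seed{seed}")


def generate_screening_stream(
    n: int,
    planted_active_fraction: float = 0.01,
    seed: int = 0,
    path: Optional[str | Path] = None,
    n_scaffolds: int = 3,
):
    """A reproducible screening library of *n* molecules as (id, smiles) pairs.

    Each molecule is a planted-scaffold compound with probability
    ``planted_active_fraction`` and a scaffold-free decoy otherwise.  With
    ``path`` given, the stream is also written as a ``.smi`` file.  When
    the decoy vocabulary runs out of unique structures, duplicates are
    allowed (a vendor library at desk scale).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= planted_active_fraction <= 1.0:
        raise ValueError("planted_active_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed + 2_000_029)
    scaffolds = list(PLANTED_SCAFFOLDS[:n_scaffolds])
    queries = _scaffold_queries(scaffolds)
    seen: set[str] = set()
    pairs: list[tuple[str, str]] = []
    n_dup = 0
    for i in range(n):
        scaffolded = bool(rng.random() < planted_active_fraction)
        smi = _sample_molecule(rng, scaffolds, scaffolded, seen, queries, max_attempts=50)
        if smi is None:
            # vocabulary saturated: accept a duplicate structure
            smi = _sample_molecule(rng, scaffolds, scaffolded, set(), queries)
            n_dup += 1
            if smi is None:
                raise RuntimeError("could not generate a stream molecule")
        seen.add(smi)
        pairs.append((f"LIB{i:06d}", smi))
    if n_dup:
        logger.warning("screening stream: %d duplicate structures after vocabulary saturation", n_dup)
    if path is not None:
        with open(path, "w") as fh:
            for rid, smi in pairs:
                fh.write(f"{smi}\t{rid}\n")
    return pairs


def is_planted(smiles: str, scaffolds: Iterable[str]) -> bool:
    """True if the molecule embeds any of the given planted scaffolds."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return any(mol.HasSubstructMatch(q) for q in _scaffold_queries(scaffolds))
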
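"""Library prefilters: PAINS alerts and QED druglikeness.

Screening libraries are cleaned before featurization by removing compounds
that match a pan-assay interference (PAINS) alert substructure or whose
quantitative estimate of druglikeness (QED) is at or below a cutoff
(default 0.25).  PAINS is checked first so every removed compound is
counted exactly once in the report.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem
from rdkit.Chem import QED
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from fragfocus.chem_io import ChemIOError, Dataset, MoleculeRecord

#: named alert sets understood by :func:`flag_pains`
PAINS_CATALOGS = {
    "pains": FilterCatalogParams.FilterCatalogs.PAINS,  # A + B + C
    "pains_a": FilterCatalogParams.FilterCatalogs.PAINS_A,
    "pains_b": FilterCatalogParams.FilterCatalogs.PAINS_B,
    "pains_c": FilterCatalogParams.FilterCatalogs.PAINS_C,
}


@dataclass(frozen=True)
class PrefilterConfig:
    """Removal thresholds: QED ≤ ``qed_max_removed`` is dropped (inclusive)."""

    qed_max_removed: float = 0.25
    pains_catalog: str = "pains"

    def __post_init__(self) -> None:
        if not 0.0 <= self.qed_max_removed <= 1.0:
            raise ValueError("qed_max_removed must be in [0, 1]")
        if self.pains_catalog not in PAINS_CATALOGS:
            raise ValueError(f"unknown PAINS catalog {self.pains_catalog!r}")


@dataclass(frozen=True)
class PrefilterReport:
    n_input: int
    n_pains_removed: int
    n_qed_removed: int
    n_kept: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_pains_removed + self.n_qed_removed + self.n_kept:
            raise ValueError("prefilter report counts do not balance")


@lru_cache(maxsize=None)
def _catalog(name: str) -> FilterCatalog:
    params = FilterCatalogParams()
    params.AddCatalog(PAINS_CATALOGS[name])
    return FilterCatalog(params)


def _mol(record: MoleculeRecord | str) -> Chem.Mol:
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemIOError(f"invalid structure: {smiles!r}")
    return mol


def flag_pains(record: MoleculeRecord | str, catalog: str = "pains") -> bool:
    """True iff at least one alert from the configured PAINS catalog matches."""
    return _catalog(catalog).HasMatch(_mol(record))


def compute_qed(record: MoleculeRecord | str) -> float:
    """Bickerton's mean-weighted QED desirability score, in [0, 1]."""
    return QED.qed(_mol(record))


def apply_prefilters(ds: Dataset, cfg: PrefilterConfig = PrefilterConfig()) -> tuple[Dataset, PrefilterReport]:
    """Keep records with no PAINS match and QED above the removal cutoff.

    A PAINS-matching compound is counted under PAINS even if its QED would
    also fail, so the report counts balance exactly.
    """
    kept: list[MoleculeRecord] = []
    n_pains = 0
    n_qed = 0
    for rec in ds:
        if flag_pains(rec, cfg.pains_catalog):
            n_pains += 1
        elif compute_qed(rec) <= cfg.qed_max_removed:
            n_qed += 1
        else:
            kept.append(rec)
    report = PrefilterReport(len(ds), n_pains, n_qed, len(kept))
    return Dataset(kept, ds.name), report
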
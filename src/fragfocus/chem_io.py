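"""Reading, canonicalizing, deduplicating, and labeling compound data.

Bioactivity tables arrive as CSV with a SMILES column and (optionally) a
potency column in nM plus a measurement-type column.  Screening libraries
arrive as ``.smi`` (``SMILES<whitespace>ID`` per line) or SDF.  All
structures are stored in RDKit's canonical aromatic SMILES form; rows whose
structure does not parse are dropped with a warning, since large vendor
libraries are noisy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

POTENCY_TYPES = ("Kd", "EC50", "IC50", "percent_inhibition")
LABELS = ("active", "inactive")

#: potency types that participate in cutoff-based labeling.  Percent
#: inhibition is not a concentration, so it is carried through but never
#: compared against a nM cutoff.
CONCENTRATION_TYPES = ("Kd", "EC50", "IC50")


class ChemIOError(ValueError):
    """Raised on malformed chemical input."""


def canonical_smiles(smiles: str) -> Optional[str]:
    """Canonical aromatic SMILES for *smiles*, or None if it does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _flat_smiles(smiles: str) -> Optional[str]:
    """Canonical SMILES with stereochemistry stripped (duplicate grouping key)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, canonical structure, optional potency and label.

    ``potency_nm`` is the measured potency in nM (lower = more potent);
    ``potency_type`` says what was measured (Kd, EC50, IC50 or percent
    inhibition); ``label`` is the activity class derived from the potency
    cutoff or supplied directly.
    """

    id: str
    smiles: str
    potency_nm: Optional[float] = None
    potency_type: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.potency_nm is not None and not self.potency_nm > 0:
            raise ChemIOError(f"record {self.id}: potency_nm must be > 0, got {self.potency_nm}")
        if self.potency_type is not None and self.potency_type not in POTENCY_TYPES:
            raise ChemIOError(f"record {self.id}: unknown potency_type {self.potency_type!r}")
        if self.label is not None and self.label not in LABELS:
            raise ChemIOError(f"record {self.id}: unknown label {self.label!r}")


@dataclass(frozen=True)
class LabelingConfig:
    """Potency cutoff for the active/inactive decision, in nM."""

    cutoff_nm: float = 10_000.0

    def __post_init__(self) -> None:
        if not self.cutoff_nm > 0:
            raise ChemIOError("cutoff_nm must be > 0")


@dataclass
class Dataset:
    """An ordered collection of molecule records with a name."""

    records: list[MoleculeRecord] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, labels: str | Sequence[str], name: str | None = None) -> "Dataset":
        """Records whose label is in *labels*."""
        if isinstance(labels, str):
            labels = (labels,)
        recs = [r for r in self.records if r.label in labels]
        return Dataset(recs, name if name is not None else f"{self.name}[{'|'.join(labels)}]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "potency_nm": [r.potency_nm for r in self.records],
                "potency_type": [r.potency_type for r in self.records],
                "label": [r.label for r in self.records],
            }
        )


def _canonicalize_records(
    rows: Iterable[tuple[str, str, Optional[float], Optional[str], Optional[str]]],
    source: str,
) -> list[MoleculeRecord]:
    records = []
    n_rejected = 0
    seen_ids: set[str] = set()
    for rid, smi, pot, ptype, label in rows:
        canon = canonical_smiles(smi) if smi else None
        if canon is None:
            n_rejected += 1
            continue
        if rid in seen_ids:
            raise ChemIOError(f"{source}: duplicate id {rid!r}")
        seen_ids.add(rid)
        records.append(MoleculeRecord(rid, canon, pot, ptype, label))
    if n_rejected:
        logger.warning("%s: dropped %d rows with unparseable structures", source, n_rejected)
    if not records:
        raise ChemIOError(f"{source}: no parseable structures")
    return records


def read_bioactivity_table(
    path: str | Path,
    smiles_col: str = "smiles",
    id_col: Optional[str] = None,
    potency_col: Optional[str] = None,
    potency_type_col: Optional[str] = None,
    label_col: Optional[str] = None,
    name: Optional[str] = None,
) -> Dataset:
    """Read a CSV bioactivity table into a canonicalized :class:`Dataset`.

    Rows with unparseable SMILES are dropped and counted in the log; a file
    with no parseable row is an error.  ``id_col=None`` assigns sequential
    ``row<N>`` identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    if len(header) != len(set(header)):
        raise ChemIOError(f"{path}: duplicate column names in header")
    df = pd.read_csv(path)
    for col in (smiles_col, id_col, potency_col, potency_type_col, label_col):
        if col is not None and col not in df.columns:
            raise ChemIOError(f"{path}: column {col!r} not found")

    def rows():
        for i, row in df.iterrows():
            rid = str(row[id_col]) if id_col else f"row{i}"
            pot = None
            if potency_col is not None and pd.notna(row[potency_col]):
                pot = float(row[potency_col])
            ptype = None
            if potency_type_col is not None and pd.notna(row[potency_type_col]):
                ptype = str(row[potency_type_col])
            label = None
            if label_col is not None and pd.notna(row[label_col]):
                label = str(row[label_col])
            smi = row[smiles_col]
            yield rid, (str(smi) if pd.notna(smi) else ""), pot, ptype, label

    return Dataset(_canonicalize_records(rows(), str(path)), name or path.stem)


def read_smiles_file(path: str | Path, name: Optional[str] = None) -> Dataset:
    """Read a ``.smi`` file (``SMILES<whitespace>ID`` per line, ID optional)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    def rows():
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smi = parts[0]
                rid = parts[1].strip() if len(parts) > 1 else f"mol{i}"
                yield rid, smi, None, None, None

    return Dataset(_canonicalize_records(rows(), str(path)), name or path.stem)


def write_smiles_file(ds: Dataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in ds:
            fh.write(f"{r.smiles}\t{r.id}\n")


def read_sdf(path: str | Path, name: Optional[str] = None) -> Dataset:
    """Read an SDF file; molecule titles (or sequential ids) become record ids."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    def rows():
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                yield f"sdf{i}", "", None, None, None
                continue
            rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i}"
            yield rid, Chem.MolToSmiles(mol), None, None, None

    return Dataset(_canonicalize_records(rows(), str(path)), name or path.stem)


def deduplicate_keep_most_potent(ds: Dataset) -> Dataset:
    """One record per structure, keeping the most potent (lowest nM) duplicate.

    Duplicate grouping ignores stereochemistry only when structures differ
    solely by *unspecified* stereo: within a flat-structure group, records
    with distinct specified stereo forms stay separate, while records with
    no stereo annotation merge into the group when at most one specified
    form exists.  Records lacking a potency lose ties to records having one;
    remaining ties keep the first occurrence.
    """
    # group key: flat canonical smiles, then full canonical smiles
    groups: dict[str, dict[str, list[MoleculeRecord]]] = {}
    order: list[tuple[str, str]] = []
    for rec in ds:
        flat = _flat_smiles(rec.smiles)
        sub = groups.setdefault(flat, {})
        if rec.smiles not in sub:
            order.append((flat, rec.smiles))
        sub.setdefault(rec.smiles, []).append(rec)

    merged: list[list[MoleculeRecord]] = []
    emitted: set[tuple[str, str]] = set()
    for flat, full in order:
        if (flat, full) in emitted:
            continue
        sub = groups[flat]
        specified = [k for k in sub if k != flat]
        if len(specified) <= 1:
            # at most one stereo form: unannotated records duplicate it
            bucket = [r for k in sub for r in sub[k]]
            for k in sub:
                emitted.add((flat, k))
        else:
            bucket = list(sub[full])
            emitted.add((flat, full))
        merged.append(bucket)

    def best(bucket: list[MoleculeRecord]) -> MoleculeRecord:
        with_pot = [r for r in bucket if r.potency_nm is not None]
        if with_pot:
            return min(with_pot, key=lambda r: r.potency_nm)
        return bucket[0]

    return Dataset([best(b) for b in merged], ds.name)


def assign_labels(ds: Dataset, cfg: LabelingConfig = LabelingConfig()) -> Dataset:
    """Label records active/inactive by the potency cutoff.

    Potency strictly below the cutoff is active; at or above it, inactive
    (the boundary is assigned to the conservative side).  Records whose
    potency type is percent inhibition are passed through unlabeled; records
    with a concentration-type (or untyped) potency missing their value raise
    an error naming the offending ids.
    """
    missing = [
        r.id
        for r in ds
        if r.potency_nm is None and (r.potency_type is None or r.potency_type in CONCENTRATION_TYPES)
    ]
    if missing:
        raise ChemIOError(f"records without potency cannot be labeled: {missing}")
    out = []
    for r in ds:
        if r.potency_type == "percent_inhibition":
            out.append(r)
            continue
        label = "active" if r.potency_nm < cfg.cutoff_nm else "inactive"
        out.append(replace(r, label=label))
    return Dataset(out, ds.name)


_COLUMNS = ["id", "smiles", "potency_nm", "potency_type", "label"]


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Serialize a dataset as CSV with columns id, smiles, potency_nm, potency_type, label."""
    ds.to_dataframe().to_csv(path, index=False)


def read_dataset(path: str | Path, name: Optional[str] = None) -> Dataset:
    """Read back a dataset written by :func:`write_dataset` (lossless round trip)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ChemIOError(f"{path}: not a dataset file") from exc
    if list(df.columns) != _COLUMNS:
        raise ChemIOError(f"{path}: expected columns {_COLUMNS}, got {list(df.columns)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            MoleculeRecord(
                id=str(row["id"]),
                smiles=str(row["smiles"]),
                potency_nm=float(row["potency_nm"]) if pd.notna(row["potency_nm"]) else None,
                potency_type=str(row["potency_type"]) if pd.notna(row["potency_type"]) else None,
                label=str(row["label"]) if pd.notna(row["label"]) else None,
            )
        )
    return Dataset(records, name or path.stem)
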
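"""Streaming library screening plus diversity and similarity analyses.

A SMILES library (possibly larger than memory) is featurized and voted on
in chunks; compounds reaching the vote threshold form the focused library.
The module also provides the downstream analyses run on a focused library:
pairwise Tanimoto similarity matrices, cluster-representative selection,
seeded 2-D chemical-space projection, and the fragment-match/label profile
relating fragment matches to the active fraction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from fragfocus.chem_io import Dataset, MoleculeRecord, read_smiles_file
from fragfocus.ensemble import EnsembleModel
from fragfocus.featurizer import FeaturizerConfig, _bulk_tanimoto, ecfp, featurize, fragment_match_count
from fragfocus.fragment_miner import FragmentLibrary

logger = logging.getLogger(__name__)

DEFAULT_MATCH_BINS = ((0, 0), (1, 4), (5, 9), (10, 19), (20, None))


@dataclass(frozen=True)
class ScreeningReport:
    """Accounting of one library screen."""

    n_input: int
    n_passed: int
    reduction_fraction: float
    per_threshold_counts: dict[int, int] = field(default_factory=dict)
    vote_histogram: dict[int, int] = field(default_factory=dict)
    n_invalid: int = 0

    def __post_init__(self) -> None:
        if self.n_input > 0 and abs(self.reduction_fraction - (1 - self.n_passed / self.n_input)) > 1e-12:
            raise ValueError("reduction_fraction inconsistent with counts")
        if self.vote_histogram and sum(self.vote_histogram.values()) != self.n_input:
            raise ValueError("vote histogram does not sum to n_input")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_passed": self.n_passed,
            "reduction_fraction": self.reduction_fraction,
            "per_threshold_counts": self.per_threshold_counts,
            "vote_histogram": self.vote_histogram,
            "n_invalid": self.n_invalid,
        }


def _iter_library(library) -> Iterator[tuple[str, str]]:
    """Yield (id, smiles) pairs from a path, Dataset, or iterable."""
    if isinstance(library, (str, Path)):
        path = Path(library)
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                rid = parts[1].strip() if len(parts) > 1 else f"mol{i}"
                yield rid, parts[0]
    elif isinstance(library, Dataset):
        for r in library:
            yield r.id, r.smiles
    else:
        for item in library:
            if isinstance(item, MoleculeRecord):
                yield item.id, item.smiles
            else:
                yield item


def screen_library(
    library,
    lib: FragmentLibrary,
    model: EnsembleModel,
    threshold: int = 6,
    cfg: FeaturizerConfig = FeaturizerConfig(),
    chunk_size: int = 1000,
    keep_votes: bool = False,
) -> tuple[Dataset, ScreeningReport]:
    """Stream a library through the ensemble; keep compounds at/above the threshold.

    *library* may be a ``.smi`` path, a :class:`Dataset`, or an iterable of
    ``(id, smiles)`` pairs.  Corrupt records are skipped and counted.
    Results are independent of ``chunk_size``.
    """
    passed: list[MoleculeRecord] = []
    vote_hist = {v: 0 for v in range(len(model.members) + 1)}
    n_input = 0
    n_invalid = 0
    all_votes: list[tuple[str, int]] = []

    pairs = _iter_library(library)
    while True:
        chunk = list(itertools.islice(pairs, chunk_size))
        if not chunk:
            break
        records = []
        for rid, smi in chunk:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                n_invalid += 1
                continue
            records.append(MoleculeRecord(rid, Chem.MolToSmiles(mol)))
        n_input += len(records)
        if not records:
            continue
        X = featurize(records, lib, cfg)
        votes = model.predict_votes(X)
        for rec, v in zip(records, votes):
            vote_hist[int(v)] += 1
            if keep_votes:
                all_votes.append((rec.id, int(v)))
            if v >= threshold:
                passed.append(rec)
    if n_invalid:
        logger.warning("screen_library: skipped %d corrupt records", n_invalid)

    per_threshold = {
        t: sum(c for v, c in vote_hist.items() if v >= t) for t in range(1, len(model.members) + 1)
    }
    report = ScreeningReport(
        n_input=n_input,
        n_passed=len(passed),
        reduction_fraction=1 - len(passed) / n_input if n_input else 0.0,
        per_threshold_counts=per_threshold,
        vote_histogram=vote_hist,
        n_invalid=n_invalid,
    )
    focused = Dataset(passed, "focused")
    if keep_votes:
        return focused, report, pd.DataFrame(all_votes, columns=["id", "votes"])
    return focused, report


def _fingerprint_matrix(ds: Dataset, cfg: FeaturizerConfig) -> np.ndarray:
    return np.vstack([ecfp(r, cfg) for r in ds])


def similarity_matrix(
    set_a: Dataset, set_b: Optional[Dataset] = None, cfg: FeaturizerConfig = FeaturizerConfig()
) -> pd.DataFrame:
    """Pairwise fingerprint Tanimoto; symmetric with unit diagonal on self-comparison."""
    self_compare = set_b is None
    set_b = set_a if self_compare else set_b
    fa = _fingerprint_matrix(set_a, cfg)
    fb = fa if self_compare else _fingerprint_matrix(set_b, cfg)
    sims = _bulk_tanimoto(fa, fb)
    if self_compare:
        np.fill_diagonal(sims, 1.0)  # exact, independent of float arithmetic
    return pd.DataFrame(sims, index=set_a.ids, columns=set_b.ids)


def select_cluster_representatives(
    ds: Dataset, n_clusters: int = 30, cfg: FeaturizerConfig = FeaturizerConfig(), seed: int = 0
) -> Dataset:
    """One representative per fingerprint cluster: the molecule nearest its center.

    Seeded k-means partitioning on fingerprint vectors; deterministic for a
    seed, with index order breaking distance ties.
    """
    if len(ds) < n_clusters:
        raise ValueError(f"need at least {n_clusters} molecules, got {len(ds)}")
    fps = _fingerprint_matrix(ds, cfg).astype(np.float64)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    assign = km.fit_predict(fps)
    reps = []
    for c in range(n_clusters):
        idx = np.where(assign == c)[0]
        d = np.linalg.norm(fps[idx] - km.cluster_centers_[c], axis=1)
        reps.append(int(idx[int(np.argmin(d))]))
    return Dataset([ds[i] for i in sorted(reps)], f"{ds.name}-representatives")


def chemical_space_projection(
    sets: dict[str, Dataset] | Dataset,
    cfg: FeaturizerConfig = FeaturizerConfig(),
    method: str = "pca",
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded 2-D embedding of fingerprints for diversity plots.

    *sets* is either one dataset or a mapping of set label to dataset; the
    result has columns ``id``, ``set``, ``x``, ``y``.  The default principal
    component projection is deterministic; a neighbor embedding (UMAP, if
    installed) is available behind ``method="umap"``.
    """
    if isinstance(sets, Dataset):
        sets = {sets.name or "set": sets}
    ids, labels, fps = [], [], []
    for label, ds in sets.items():
        for r in ds:
            ids.append(r.id)
            labels.append(label)
            fps.append(ecfp(r, cfg))
    if len(fps) < 3:
        raise ValueError("need at least 3 molecules to project")
    fps = np.asarray(fps, dtype=np.float64)
    if method == "pca":
        # fit then transform (not fit_transform): the row-wise projection makes
        # duplicate molecules map to bitwise-identical coordinates
        coords = PCA(n_components=2, random_state=seed).fit(fps).transform(fps)
    elif method == "umap":
        import umap

        coords = umap.UMAP(n_components=2, random_state=seed).fit_transform(fps)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    return pd.DataFrame({"id": ids, "set": labels, "x": coords[:, 0], "y": coords[:, 1]})


def fragment_match_label_profile(
    ds: Dataset,
    lib: FragmentLibrary,
    cfg: FeaturizerConfig = FeaturizerConfig(),
    bins: Sequence[tuple[int, Optional[int]]] = DEFAULT_MATCH_BINS,
) -> pd.DataFrame:
    """Active fraction per fragment-match-count bin on a labeled dataset.

    Default bins 0, 1-4, 5-9, 10-19, >=20; compounds matching many mined
    fragments should be enriched for the active label.
    """
    unlabeled = [r.id for r in ds if r.label not in ("active", "inactive")]
    if unlabeled:
        raise ValueError(f"dataset must be fully labeled; missing labels for {unlabeled}")
    counts = [fragment_match_count(r, lib, cfg) for r in ds]
    rows = []
    for lo, hi in bins:
        in_bin = [
            r for r, c in zip(ds, counts) if c >= lo and (hi is None or c <= hi)
        ]
        n_act = sum(1 for r in in_bin if r.label == "active")
        n_inact = len(in_bin) - n_act
        rows.append(
            {
                "bin": f"{lo}+" if hi is None else (f"{lo}" if lo == hi else f"{lo}-{hi}"),
                "n_active": n_act,
                "n_inactive": n_inact,
                "n_total": len(in_bin),
                "active_fraction": n_act / len(in_bin) if in_bin else float("nan"),
            }
        )
    return pd.DataFrame(rows)
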
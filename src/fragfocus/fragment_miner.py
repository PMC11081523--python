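"""Mining ring-complete frequent substructures that discriminate actives from inactives.

A fragment is a connected heavy-atom subgraph of a molecule in which every
ring bond is covered by a complete smallest-set-of-smallest-rings (SSSR)
ring — "ring mining": partial rings never appear.  Fragments are retained
when their molecule-level support in the active class reaches the minimum
support (default 1%) while their support in the inactive class stays at or
below the maximum support (default 20%); frequent-but-nonspecific
substructures are assumed to push compounds toward the inactive class and
are removed.

Search strategy: depth-first extension of induced atom subsets inside each
active molecule, starting from single heavy atoms.  An extension that pulls
in a ring bond immediately completes every SSSR ring covering it (branching
over the alternatives in fused systems), so only ring-complete candidates
are ever support-tested.  Candidates are deduplicated by canonical
substructure SMILES; support is counted by subgraph-isomorphism matching on
element + aromaticity + formal charge for atoms and order/aromaticity for
bonds.  The minimum active support is anti-monotone and prunes the search;
the inactive maximum is applied as an output filter only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from rdkit import Chem

from fragfocus.chem_io import ChemIOError, Dataset

_BOND_SMARTS = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


class MiningError(ValueError):
    """Raised on invalid mining inputs or configuration."""


@dataclass(frozen=True)
class MiningConfig:
    """Support thresholds and size bounds for the substructure search."""

    min_support_active: float = 0.01
    max_support_inactive: float = 0.20
    ring_mining: bool = True
    max_fragment_atoms: int = 15
    min_fragment_atoms: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support_active <= 1.0:
            raise MiningError("min_support_active must be in (0, 1]")
        if not 0.0 <= self.max_support_inactive <= 1.0:
            raise MiningError("max_support_inactive must be in [0, 1]")
        if self.max_fragment_atoms < 1:
            raise MiningError("max_fragment_atoms must be >= 1")
        if not 1 <= self.min_fragment_atoms <= self.max_fragment_atoms:
            raise MiningError("need 1 <= min_fragment_atoms <= max_fragment_atoms")


@dataclass(frozen=True)
class Fragment:
    """A mined connected, ring-complete substructure with per-class supports."""

    smiles: str
    n_atoms: int
    support_active: float
    support_inactive: float


@dataclass
class FragmentLibrary:
    """Ordered fragment collection with stable, deterministic order.

    Order is descending active support, then ascending atom count, then
    lexicographic SMILES, so downstream feature columns are stable across
    runs.
    """

    fragments: list[Fragment] = field(default_factory=list)
    mining_config: MiningConfig = field(default_factory=MiningConfig)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for f in self.fragments:
            if f.smiles in seen:
                raise MiningError(f"duplicate fragment {f.smiles!r} in library")
            seen.add(f.smiles)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments)

    def __getitem__(self, i):
        return self.fragments[i]

    @property
    def smiles(self) -> list[str]:
        return [f.smiles for f in self.fragments]

    def top(self, n: int) -> "FragmentLibrary":
        """The first *n* fragments in library order (highest active support)."""
        return FragmentLibrary(self.fragments[:n], self.mining_config, self.provenance)

    def query_mols(self) -> list[Chem.Mol]:
        """Substructure query molecules, one per fragment, in library order."""
        return [fragment_query(parse_fragment_smiles(f.smiles)) for f in self.fragments]


def _library_sort_key(f: Fragment):
    return (-f.support_active, f.n_atoms, f.smiles)


# ---------------------------------------------------------------------------
# fragment graphs: extraction, canonical form, matching queries
# ---------------------------------------------------------------------------

def fragment_from_subset(mol: Chem.Mol, atom_indices: Iterable[int]) -> Chem.Mol:
    """The induced substructure of *mol* on *atom_indices* as a fragment graph.

    Element, formal charge, aromatic flag, and bond types are preserved;
    hydrogens are implicit and not carried.  The result is a heavy-atom
    graph, not necessarily a valence-complete molecule.
    """
    idx = sorted(set(atom_indices))
    em = Chem.RWMol()
    amap = {}
    for i in idx:
        a = mol.GetAtomWithIdx(i)
        na = Chem.Atom(a.GetAtomicNum())
        na.SetFormalCharge(a.GetFormalCharge())
        na.SetIsAromatic(a.GetIsAromatic())
        na.SetNoImplicit(True)
        amap[i] = em.AddAtom(na)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in amap and j in amap:
            em.AddBond(amap[i], amap[j], b.GetBondType())
    frag = em.GetMol()
    frag.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(frag)
    return frag


def fragment_smiles(frag: Chem.Mol) -> str:
    """Canonical SMILES string of a fragment graph (identity key)."""
    return Chem.MolToSmiles(frag)


def parse_fragment_smiles(smiles: str) -> Chem.Mol:
    """Parse a fragment SMILES back to a fragment graph (no valence sanitization)."""
    frag = Chem.MolFromSmiles(smiles, sanitize=False)
    if frag is None:
        raise MiningError(f"unparseable fragment smiles {smiles!r}")
    frag.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(frag)
    return frag


def fragment_form(smiles: str) -> str:
    """The canonical heavy-atom fragment form of a whole molecule.

    Explicit hydrogen counts are not part of fragment identity (fragments
    are heavy-atom graphs), so e.g. pyrazole ``c1cc[nH]n1`` has fragment
    form ``c1ccnn1``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MiningError(f"invalid structure {smiles!r}")
    return fragment_smiles(fragment_from_subset(mol, range(mol.GetNumAtoms())))


def fragment_query(frag: Chem.Mol) -> Chem.Mol:
    """A substructure query matching on element + aromaticity + charge and bond order.

    RDKit's default mol-on-mol matching ignores formal charge and the
    aromatic flag of atoms whose bonds are all non-aromatic, so the query is
    built from explicit SMARTS atom/bond primitives.
    """
    q = Chem.RWMol()
    for a in frag.GetAtoms():
        sm = "[#%d;%s;%+d]" % (
            a.GetAtomicNum(),
            "a" if a.GetIsAromatic() else "A",
            a.GetFormalCharge(),
        )
        q.AddAtom(Chem.AtomFromSmarts(sm))
    for b in frag.GetBonds():
        qb = Chem.BondFromSmarts(_BOND_SMARTS[b.GetBondType()])
        q.AddBond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), Chem.BondType.UNSPECIFIED)
        q.ReplaceBond(q.GetNumBonds() - 1, qb)
    return q.GetMol()


def _dataset_mols(ds: Dataset) -> list[Chem.Mol]:
    mols = []
    for r in ds:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is None:
            raise ChemIOError(f"record {r.id}: invalid structure {r.smiles!r}")
        mols.append(mol)
    return mols


def compute_support(fragment: Fragment | Chem.Mol | str, molecules: Dataset) -> float:
    """Fraction of molecules containing at least one embedding of the fragment.

    Molecule-level support: a molecule counts once however many embeddings
    it has.
    """
    if len(molecules) == 0:
        raise MiningError("cannot compute support over an empty dataset")
    if isinstance(fragment, Fragment):
        frag = parse_fragment_smiles(fragment.smiles)
    elif isinstance(fragment, str):
        frag = parse_fragment_smiles(fragment)
    else:
        frag = fragment
    query = fragment_query(frag)
    mols = _dataset_mols(molecules)
    n = sum(1 for m in mols if m.HasSubstructMatch(query))
    return n / len(mols)


# ---------------------------------------------------------------------------
# ring-complete subset enumeration
# ---------------------------------------------------------------------------

def _ring_bond_rings(mol: Chem.Mol) -> tuple[list[frozenset[int]], dict[int, list[int]]]:
    """SSSR rings as atom sets plus, per ring bond index, the rings covering it."""
    info = mol.GetRingInfo()
    atom_rings = [frozenset(r) for r in info.AtomRings()]
    bond_to_rings: dict[int, list[int]] = {}
    for ri, bring in enumerate(info.BondRings()):
        for b in bring:
            bond_to_rings.setdefault(b, []).append(ri)
    return atom_rings, bond_to_rings


def _uncovered_ring_bond(
    mol: Chem.Mol,
    subset: frozenset[int],
    atom_rings: list[frozenset[int]],
    bond_to_rings: dict[int, list[int]],
) -> Optional[int]:
    """A ring bond induced by *subset* with no complete covering ring inside it."""
    for b in mol.GetBonds():
        bidx = b.GetIdx()
        if bidx not in bond_to_rings:
            continue
        if b.GetBeginAtomIdx() in subset and b.GetEndAtomIdx() in subset:
            if not any(atom_rings[ri] <= subset for ri in bond_to_rings[bidx]):
                return bidx
    return None


def _ring_closures(
    mol: Chem.Mol,
    subset: frozenset[int],
    atom_rings: list[frozenset[int]],
    bond_to_rings: dict[int, list[int]],
    max_atoms: int,
) -> list[frozenset[int]]:
    """All minimal ring-complete supersets of *subset* within the atom cap.

    Branches over every SSSR ring that can cover an uncovered ring bond, so
    fused systems where a bond belongs to several smallest rings yield every
    completion alternative.
    """
    done: list[frozenset[int]] = []
    seen: set[frozenset[int]] = set()
    stack = [subset]
    while stack:
        cur = stack.pop()
        if cur in seen or len(cur) > max_atoms:
            continue
        seen.add(cur)
        bidx = _uncovered_ring_bond(mol, cur, atom_rings, bond_to_rings)
        if bidx is None:
            done.append(cur)
            continue
        for ri in bond_to_rings[bidx]:
            stack.append(cur | atom_rings[ri])
    return done


def enumerate_ring_complete_subsets(mol: Chem.Mol, max_atoms: int) -> Iterator[frozenset[int]]:
    """All connected, ring-complete induced atom subsets of *mol*, each once.

    Depth-first growth from single atoms; each neighbor-atom extension is
    immediately ring-completed before being emitted, so every yielded subset
    satisfies the no-partial-ring invariant in this molecule.
    """
    atom_rings, bond_to_rings = _ring_bond_rings(mol)
    seen: set[frozenset[int]] = set()
    stack: list[frozenset[int]] = []
    for a in mol.GetAtoms():
        start = frozenset([a.GetIdx()])
        for s in _ring_closures(mol, start, atom_rings, bond_to_rings, max_atoms):
            if s not in seen:
                seen.add(s)
                stack.append(s)
                yield s
    while stack:
        cur = stack.pop()
        for i in cur:
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in cur:
                    continue
                grown = cur | {j}
                for s in _ring_closures(mol, grown, atom_rings, bond_to_rings, max_atoms):
                    if s not in seen:
                        seen.add(s)
                        stack.append(s)
                        yield s


# ---------------------------------------------------------------------------
# mining
# ---------------------------------------------------------------------------

def mine_fragments(
    actives: Dataset,
    inactives: Dataset,
    cfg: MiningConfig = MiningConfig(),
    provenance: str = "",
) -> FragmentLibrary:
    """Mine the fragments frequent among actives and rare among inactives.

    Returns exactly the connected, ring-complete induced substructures of
    the active molecules within the configured atom bounds whose active
    support is at least ``min_support_active`` and whose inactive support is
    at most ``max_support_inactive``, each carrying both supports.
    """
    if len(actives) == 0 or len(inactives) == 0:
        raise MiningError("both classes must be non-empty")
    active_mols = _dataset_mols(actives)
    inactive_mols = _dataset_mols(inactives)
    n_act, n_inact = len(active_mols), len(inactive_mols)

    # candidate smiles -> query mol; support caches keyed by smiles
    sup_act: dict[str, int] = {}
    extendable: dict[str, bool] = {}

    def active_count(smi: str, frag: Chem.Mol) -> int:
        if smi not in sup_act:
            query = fragment_query(frag)
            sup_act[smi] = sum(1 for m in active_mols if m.HasSubstructMatch(query))
        return sup_act[smi]

    for mol in active_mols:
        atom_rings, bond_to_rings = _ring_bond_rings(mol)
        seen_local: set[frozenset[int]] = set()
        stack: list[frozenset[int]] = []

        def admit(subset: frozenset[int]) -> None:
            if subset in seen_local:
                return
            seen_local.add(subset)
            frag = fragment_from_subset(mol, subset)
            smi = fragment_smiles(frag)
            if smi in extendable:
                keep = extendable[smi]
            else:
                # anti-monotone prune: a fragment below the active minimum
                # cannot have a superset at or above it
                keep = active_count(smi, frag) / n_act >= cfg.min_support_active
                extendable[smi] = keep
            if keep:
                stack.append(subset)

        for a in mol.GetAtoms():
            for s in _ring_closures(
                mol, frozenset([a.GetIdx()]), atom_rings, bond_to_rings, cfg.max_fragment_atoms
            ):
                admit(s)
        while stack:
            cur = stack.pop()
            for i in cur:
                for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                    j = nb.GetIdx()
                    if j in cur:
                        continue
                    for s in _ring_closures(
                        mol, cur | {j}, atom_rings, bond_to_rings, cfg.max_fragment_atoms
                    ):
                        admit(s)

    fragments = []
    for smi, keep in extendable.items():
        if not keep:
            continue
        frag = parse_fragment_smiles(smi)
        n_atoms = frag.GetNumAtoms()
        if not cfg.min_fragment_atoms <= n_atoms <= cfg.max_fragment_atoms:
            continue
        query = fragment_query(frag)
        s_in = sum(1 for m in inactive_mols if m.HasSubstructMatch(query)) / n_inact
        if s_in > cfg.max_support_inactive:
            continue
        fragments.append(Fragment(smi, n_atoms, sup_act[smi] / n_act, s_in))

    fragments.sort(key=_library_sort_key)
    return FragmentLibrary(fragments, cfg, provenance)


# ---------------------------------------------------------------------------
# persistence: one fragment per line, TSV with a config header
# ---------------------------------------------------------------------------

def write_fragment_library(lib: FragmentLibrary, path: str | Path) -> None:
    cfg = lib.mining_config
    with open(path, "w") as fh:
        fh.write(
            "# fragfocus fragment library\n"
            f"# min_support_active={cfg.min_support_active!r}\t"
            f"max_support_inactive={cfg.max_support_inactive!r}\t"
            f"ring_mining={cfg.ring_mining}\t"
            f"max_fragment_atoms={cfg.max_fragment_atoms}\t"
            f"min_fragment_atoms={cfg.min_fragment_atoms}\n"
            f"# provenance={lib.provenance}\n"
            "smiles\tn_atoms\tsupport_active\tsupport_inactive\n"
        )
        for f in lib.fragments:
            fh.write(f"{f.smiles}\t{f.n_atoms}\t{f.support_active!r}\t{f.support_inactive!r}\n")


def read_fragment_library(path: str | Path) -> FragmentLibrary:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text().splitlines()
    if len(lines) < 4 or not lines[0].startswith("# fragfocus fragment library"):
        raise MiningError(f"{path}: not a fragment library file")
    kv = {}
    for part in lines[1][2:].split("\t"):
        k, _, v = part.partition("=")
        kv[k] = v
    cfg = MiningConfig(
        min_support_active=float(kv["min_support_active"]),
        max_support_inactive=float(kv["max_support_inactive"]),
        ring_mining=kv["ring_mining"] == "True",
        max_fragment_atoms=int(kv["max_fragment_atoms"]),
        min_fragment_atoms=int(kv["min_fragment_atoms"]),
    )
    provenance = lines[2][2:].partition("=")[2]
    if lines[3] != "smiles\tn_atoms\tsupport_active\tsupport_inactive":
        raise MiningError(f"{path}: malformed column header")
    fragments = []
    for line in lines[4:]:
        if not line.strip():
            continue
        smi, n_atoms, s_act, s_in = line.split("\t")
        fragments.append(Fragment(smi, int(n_atoms), float(s_act), float(s_in)))
    return FragmentLibrary(fragments, cfg, provenance)
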
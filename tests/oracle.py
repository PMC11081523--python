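"""Brute-force oracles for the fragment miner, independent of its search code.

Candidate enumeration walks every connected induced atom subset of every
active molecule (feasible for the small test molecules), keeps the
ring-complete ones, and counts support directly by VF2 subgraph
monomorphism on networkx graphs with node match on element + aromaticity +
formal charge and edge match on bond type.
"""

from itertools import combinations

import networkx as nx
from networkx.algorithms.isomorphism import GraphMatcher
from rdkit import Chem

from fragfocus.fragment_miner import parse_fragment_smiles


def mol_to_nx(mol):
    g = nx.Graph()
    for a in mol.GetAtoms():
        g.add_node(a.GetIdx(), z=a.GetAtomicNum(), arom=a.GetIsAromatic(), chg=a.GetFormalCharge())
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), bt=str(b.GetBondType()))
    return g


def frag_smiles_to_nx(smiles):
    return mol_to_nx(parse_fragment_smiles(smiles))


def _node_match(a, b):
    return a["z"] == b["z"] and a["arom"] == b["arom"] and a["chg"] == b["chg"]


def _edge_match(a, b):
    return a["bt"] == b["bt"]


def graphs_isomorphic(g1, g2):
    return nx.is_isomorphic(g1, g2, node_match=_node_match, edge_match=_edge_match)


def embeds(target_graph, frag_graph):
    """True iff the fragment embeds in the target as a subgraph (monomorphism)."""
    return GraphMatcher(target_graph, frag_graph, node_match=_node_match, edge_match=_edge_match).subgraph_is_monomorphic()


def connected_induced_subsets(mol, max_atoms):
    """Every connected atom subset of *mol* up to *max_atoms*, each exactly once."""
    n = mol.GetNumAtoms()
    neighbors = {a.GetIdx(): {nb.GetIdx() for nb in a.GetNeighbors()} for a in mol.GetAtoms()}
    out = set()
    frontier = {frozenset([i]) for i in range(n)}
    while frontier:
        out |= frontier
        nxt = set()
        for s in frontier:
            if len(s) >= max_atoms:
                continue
            reach = set().union(*(neighbors[i] for i in s)) - s
            for j in reach:
                grown = s | {j}
                if grown not in out:
                    nxt.add(grown)
        frontier = nxt
    return out


def is_ring_complete(mol, subset):
    """No partial rings: every induced ring bond lies in a complete SSSR ring inside the subset."""
    info = mol.GetRingInfo()
    atom_rings = [frozenset(r) for r in info.AtomRings()]
    bond_rings = info.BondRings()
    for b in mol.GetBonds():
        if b.GetBeginAtomIdx() not in subset or b.GetEndAtomIdx() not in subset:
            continue
        covering = [ri for ri, br in enumerate(bond_rings) if b.GetIdx() in br]
        if not covering:
            continue
        if not any(atom_rings[ri] <= subset for ri in covering):
            return False
    return True


def oracle_mine(actives, inactives, cfg):
    """All retained fragments by direct enumeration: list of (graph, s_act, s_in)."""
    active_mols = [Chem.MolFromSmiles(r.smiles) for r in actives]
    inactive_mols = [Chem.MolFromSmiles(r.smiles) for r in inactives]
    active_graphs = [mol_to_nx(m) for m in active_mols]
    inactive_graphs = [mol_to_nx(m) for m in inactive_mols]

    candidates = []  # unique fragment graphs
    for mol in active_mols:
        g = mol_to_nx(mol)
        for subset in connected_induced_subsets(mol, cfg.max_fragment_atoms):
            if len(subset) < cfg.min_fragment_atoms:
                continue
            if not is_ring_complete(mol, subset):
                continue
            frag = g.subgraph(subset).copy()
            if not any(graphs_isomorphic(frag, c) for c in candidates):
                candidates.append(frag)

    retained = []
    for frag in candidates:
        s_act = sum(embeds(t, frag) for t in active_graphs) / len(active_graphs)
        if s_act < cfg.min_support_active:
            continue
        s_in = sum(embeds(t, frag) for t in inactive_graphs) / len(inactive_graphs)
        if s_in > cfg.max_support_inactive:
            continue
        retained.append((frag, s_act, s_in))
    return retained


def assert_library_equals_oracle(library, oracle_fragments):
    """Set equality (up to graph isomorphism) including both supports."""
    assert len(library) == len(oracle_fragments), (
        f"miner returned {len(library)} fragments, oracle {len(oracle_fragments)}"
    )
    unmatched = list(oracle_fragments)
    for f in library:
        fg = frag_smiles_to_nx(f.smiles)
        hit = None
        for i, (og, s_act, s_in) in enumerate(unmatched):
            if graphs_isomorphic(fg, og):
                assert abs(f.support_active - s_act) < 1e-12, f.smiles
                assert abs(f.support_inactive - s_in) < 1e-12, f.smiles
                hit = i
                break
        assert hit is not None, f"miner fragment {f.smiles} not found by oracle"
        unmatched.pop(hit)
    assert not unmatched
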
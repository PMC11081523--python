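import numpy as np
import pytest
from rdkit import Chem

from fragfocus.chem_io import Dataset, MoleculeRecord
from fragfocus.fragment_miner import (
    Fragment,
    FragmentLibrary,
    MiningConfig,
    MiningError,
    compute_support,
    fragment_form,
    mine_fragments,
    parse_fragment_smiles,
    read_fragment_library,
    write_fragment_library,
)
from helpers import SMALL_MOLECULES, distinct_acyclic_smiles
from oracle import assert_library_equals_oracle, oracle_mine


def ds(smiles, name="d", prefix="m"):
    return Dataset([MoleculeRecord(f"{prefix}{i}", s) for i, s in enumerate(smiles)], name)


class TestComputeSupport:
    def test_benzene_in_half_the_dataset(self):
        assert compute_support("c1ccccc1", ds(["Oc1ccccc1", "CCO"])) == 0.5

    def test_self_copies_give_full_support(self):
        assert compute_support("c1ccncc1", ds(["c1ccncc1"] * 4)) == 1.0

    def test_empty_dataset_is_an_error(self):
        with pytest.raises(MiningError):
            compute_support("C", ds([]))

    def test_matches_brute_force_count(self):
        from oracle import embeds, frag_smiles_to_nx, mol_to_nx

        molecules = ds(SMALL_MOLECULES)
        frag = frag_smiles_to_nx("cc")
        expected = sum(
            embeds(mol_to_nx(Chem.MolFromSmiles(s)), frag) for s in SMALL_MOLECULES
        ) / len(SMALL_MOLECULES)
        assert compute_support("cc", molecules) == expected


class TestMineFragments:
    def test_discriminative_ring_is_recovered_with_supports(self):
        actives = ds(["Cc1ccncc1", "CCc1ccncc1", "Oc1ccncc1", "c1ccncc1"], "act")
        inactives = ds(["Cc1ccccc1", "CCO", "C1CCCCC1", "CCN"], "inact")
        lib = mine_fragments(actives, inactives, MiningConfig(max_fragment_atoms=7))
        pyridine = fragment_form("c1ccncc1")
        match = [f for f in lib if f.smiles == pyridine]
        assert match and match[0].support_active == 1.0 and match[0].support_inactive == 0.0

    def test_empty_class_is_an_error(self):
        with pytest.raises(MiningError):
            mine_fragments(ds(["CCO"]), ds([]))

    def test_min_support_boundary_is_inclusive(self):
        # marker sulfur chain in exactly 1 of 100 actives: support 0.01 == minimum
        fillers = distinct_acyclic_smiles(120)
        actives = ds(fillers[:99] + ["CCS"], "act")
        inactives = ds(fillers[99:119], "inact")
        lib = mine_fragments(actives, inactives, MiningConfig(max_fragment_atoms=5))
        assert "CS" in lib.smiles
        # the same marker in 1 of 200 actives (0.5%) falls below the minimum
        more = distinct_acyclic_smiles(220)
        actives2 = ds(more[:199] + ["CCS"], "act2")
        lib2 = mine_fragments(actives2, ds(more[199:219], "inact2"), MiningConfig(max_fragment_atoms=5))
        assert "CS" not in lib2.smiles

    def test_max_inactive_support_boundary(self):
        fillers = distinct_acyclic_smiles(140)
        carriers = [f"{c}S" for c in fillers[:50] if Chem.MolFromSmiles(f"{c}S") is not None]
        assert len(carriers) >= 31
        actives = ds(carriers[:10], "act")  # all carry the marker
        base_inact = fillers[50:130]  # 80 marker-free
        # exactly 20 of 100 inactives carry the marker: retained at 20%
        inact20 = ds(base_inact + carriers[10:30], "i20")
        assert len(inact20) == 100
        lib20 = mine_fragments(actives, inact20, MiningConfig(max_fragment_atoms=4))
        assert "S" in lib20.smiles
        # 21 of 100: excluded regardless of active support
        inact21 = ds(base_inact[:79] + carriers[10:31], "i21")
        assert len(inact21) == 100
        lib21 = mine_fragments(actives, inact21, MiningConfig(max_fragment_atoms=4))
        assert "S" not in lib21.smiles

    def test_matches_bruteforce_oracle_on_small_datasets(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            pick = rng.choice(len(SMALL_MOLECULES), size=12, replace=False)
            smiles = [SMALL_MOLECULES[i] for i in pick]
            actives, inactives = ds(smiles[:6], "a"), ds(smiles[6:], "i")
            cfg = MiningConfig(min_support_active=0.3, max_support_inactive=0.5, max_fragment_atoms=6)
            assert_library_equals_oracle(mine_fragments(actives, inactives, cfg), oracle_mine(actives, inactives, cfg))

    def test_antimonotone_supports(self, small_benchmark):
        ds_, _ = small_benchmark
        actives = ds_.subset("active")
        lib = mine_fragments(actives, ds_.subset("inactive"), MiningConfig(max_fragment_atoms=6))
        # removing one terminal atom from a retained fragment never lowers support
        by_smiles = {f.smiles: f for f in lib}
        checked = 0
        for f in lib.fragments[:30]:
            frag = parse_fragment_smiles(f.smiles)
            if frag.GetNumAtoms() < 2:
                continue
            from fragfocus.fragment_miner import fragment_from_subset, fragment_smiles

            for a in frag.GetAtoms():
                if a.GetDegree() != 1 or a.GetIsAromatic():
                    continue
                rest = [x.GetIdx() for x in frag.GetAtoms() if x.GetIdx() != a.GetIdx()]
                sub_smi = fragment_smiles(fragment_from_subset(frag, rest))
                if sub_smi in by_smiles:
                    assert by_smiles[sub_smi].support_active >= f.support_active
                    checked += 1
        assert checked > 0

    def test_tighter_thresholds_never_add_fragments(self):
        actives = ds(SMALL_MOLECULES[:10], "a")
        inactives = ds(SMALL_MOLECULES[10:20], "i")
        loose = mine_fragments(actives, inactives, MiningConfig(0.1, 0.5, max_fragment_atoms=6))
        tight = mine_fragments(actives, inactives, MiningConfig(0.3, 0.2, max_fragment_atoms=6))
        assert set(tight.smiles) <= set(loose.smiles)

    def test_no_partial_aromatic_rings(self, small_benchmark):
        ds_, _ = small_benchmark
        lib = mine_fragments(ds_.subset("active"), ds_.subset("inactive"), MiningConfig(max_fragment_atoms=8))
        for f in lib:
            frag = parse_fragment_smiles(f.smiles)
            ri = frag.GetRingInfo()
            for b in frag.GetBonds():
                if b.GetBondType() == Chem.BondType.AROMATIC:
                    assert ri.NumBondRings(b.GetIdx()) >= 1, f.smiles

    def test_deterministic_order(self):
        actives = ds(SMALL_MOLECULES[:8], "a")
        inactives = ds(SMALL_MOLECULES[8:16], "i")
        cfg = MiningConfig(0.2, 0.5, max_fragment_atoms=6)
        lib1 = mine_fragments(actives, inactives, cfg)
        lib2 = mine_fragments(actives, inactives, cfg)
        assert lib1.smiles == lib2.smiles
        sup = [f.support_active for f in lib1]
        assert sup == sorted(sup, reverse=True)


class TestLibraryRoundTrip:
    def _lib(self):
        frags = [Fragment("c1ccncc1", 6, 0.5, 0.1), Fragment("CO", 2, 0.25, 0.0)]
        return FragmentLibrary(frags, MiningConfig(), provenance="unit")

    def test_roundtrip_preserves_everything(self, tmp_path):
        lib = self._lib()
        path = tmp_path / "frags.tsv"
        write_fragment_library(lib, path)
        back = read_fragment_library(path)
        assert back.fragments == lib.fragments
        assert back.mining_config == lib.mining_config
        assert back.provenance == lib.provenance

    def test_empty_roundtrip(self, tmp_path):
        lib = FragmentLibrary([], MiningConfig(), "empty")
        path = tmp_path / "e.tsv"
        write_fragment_library(lib, path)
        assert len(read_fragment_library(path)) == 0

    def test_duplicate_fragment_lines_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        write_fragment_library(self._lib(), path)
        with open(path, "a") as fh:
            fh.write("c1ccncc1\t6\t0.5\t0.1\n")
        with pytest.raises(MiningError, match="duplicate"):
            read_fragment_library(path)

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "junk.tsv"
        path.write_text("hello\nworld\n")
        with pytest.raises(MiningError):
            read_fragment_library(path)


def test_config_validation():
    with pytest.raises(MiningError):
        MiningConfig(min_support_active=0.0)
    with pytest.raises(MiningError):
        MiningConfig(max_support_inactive=1.5)
    with pytest.raises(MiningError):
        MiningConfig(max_fragment_atoms=0)
    with pytest.raises(MiningError):
        MiningConfig(min_fragment_atoms=5, max_fragment_atoms=3)
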
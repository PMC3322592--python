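"""Fragment-to-molecule assembly: overlaps, seeds, symmetry, allocation, tidying."""

from collections import defaultdict

import networkx as nx
import numpy as np
import pytest

import fragweaver.fixtures as fx
from fragweaver import (
    ChainModel,
    RigidTransform,
    WorkModel,
    allocation_score,
    assemble_chains,
    candidate_transforms,
    find_seeds,
    grow_chains,
    overlap_entry,
    tidy_model,
)
from fragweaver.tidy import Assignment, TidyParams, max_overlap_clique, overlap_matrix


def docked_piece(chain, start, stop, seq="S", jitter=None, seed=0):
    piece = ChainModel(
        residues=[r.copy() for r in chain.residues[start:stop]],
        sequence_id=seq,
    )
    if jitter:
        rng = np.random.default_rng(seed)
        for r in piece.residues:
            for name in r.atoms:
                r.atoms[name] = r.atoms[name] + rng.normal(0, jitter, 3)
    return piece


class TestOverlapEntry:
    def test_thirteen_identical_residues_overlap(self, varied_chain):
        a = docked_piece(varied_chain, 10, 40)
        b = docked_piece(varied_chain, 27, 60)  # shares seqnums 28..40 = 13
        assert overlap_entry(a, b) == 13

    def test_exactly_twelve_is_not_enough(self, varied_chain):
        """'Exceeds 12' is strict: a 12-residue overlap scores 0."""
        a = docked_piece(varied_chain, 10, 40)
        b = docked_piece(varied_chain, 28, 60)  # shares 29..40 = 12
        assert overlap_entry(a, b) == 0

    def test_dissimilar_conformation_scores_zero(self, varied_chain):
        a = docked_piece(varied_chain, 10, 40)
        b = docked_piece(varied_chain, 20, 60)
        rng = np.random.default_rng(5)
        for r in b.residues:
            r.atoms["CA"] = r.atoms["CA"] + rng.normal(0, 4.0, 3)
        assert overlap_entry(a, b) == 0

    def test_noisy_copies_still_overlap(self, varied_chain):
        a = docked_piece(varied_chain, 10, 40)
        b = docked_piece(varied_chain, 15, 45, jitter=0.1, seed=2)
        assert overlap_entry(a, b) == 25

    def test_different_sequences_error(self, varied_chain):
        a = docked_piece(varied_chain, 10, 40, "S1")
        b = docked_piece(varied_chain, 20, 60, "S2")
        with pytest.raises(ValueError):
            overlap_entry(a, b)


class TestMaxClique:
    def test_agrees_with_exhaustive_enumeration(self):
        """200 random overlap graphs of <= 12 fragments vs subset enumeration."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            m = np.zeros((n, n), dtype=int)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.35:
                        m[i, j] = m[j, i] = int(rng.integers(13, 40))
            weights = rng.integers(10, 100, n).tolist()
            got = max_overlap_clique(m, weights)
            # exhaustive oracle over all subsets
            best = (0, 0, [])
            for mask in range(1, 1 << n):
                sub = [i for i in range(n) if mask >> i & 1]
                if all(m[a, b] > 0 for ai, a in enumerate(sub) for b in sub[ai + 1:]):
                    key = (len(sub), sum(weights[i] for i in sub))
                    if key > best[:2] or (key == best[:2] and sub < best[2]):
                        best = (key[0], key[1], sub)
            assert sorted(got) == best[2]

    def test_agrees_with_networkx_on_size(self):
        """Independent library cross-check on clique size."""
        rng = np.random.default_rng(7)
        for _ in range(20)            :
            n = 10
            m = np.zeros((n, n), dtype=int)
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        m[i, j] = m[j, i] = 20
                        g.add_edge(i, j)
            got = max_overlap_clique(m, [1] * n)
            expect = max((len(c) for c in nx.find_cliques(g)), default=0)
            assert len(got) == expect


class TestFindSeeds:
    def test_two_ncs_copies_give_two_seeds(self, varied_chain):
        frags = [
            docked_piece(varied_chain, 0, 30),
            docked_piece(varied_chain, 5, 35, jitter=0.05, seed=1),
            docked_piece(varied_chain, 60, 80),
        ]
        seeds = find_seeds(frags)
        assert set(seeds.indices) == {0, 1}
        assert seeds.seq_range == (6, 30)

    def test_no_overlaps_fall_back_to_longest(self, varied_chain):
        frags = [
            docked_piece(varied_chain, 0, 10),
            docked_piece(varied_chain, 20, 45),
            docked_piece(varied_chain, 50, 60),
        ]
        seeds = find_seeds(frags)
        assert seeds.indices == (1,)

    def test_tie_broken_on_total_residues(self, varied_chain):
        """Two size-2 cliques: the heavier pair of fragments wins."""
        frags = [
            docked_piece(varied_chain, 0, 20),                        # 0: 20 res
            docked_piece(varied_chain, 0, 20, jitter=0.05, seed=3),   # 1: 20 res
            docked_piece(varied_chain, 100, 150),                     # 2: 50 res
            docked_piece(varied_chain, 100, 150, jitter=0.05, seed=4),  # 3: 50
        ]
        m = overlap_matrix(frags)
        assert m[0, 1] > 0 and m[2, 3] > 0 and m[0, 2] == 0
        seeds = find_seeds(frags)
        assert set(seeds.indices) == {2, 3}

    def test_empty_input(self):
        assert find_seeds([]).indices == ()


class TestCandidateTransforms:
    def test_p1_shell0_is_identity(self):
        ts = candidate_transforms((50, 50, 50, 90, 90, 90), "P 1", 0)
        assert len(ts) == 1
        assert np.allclose(ts[0].rotation, np.eye(3))
        assert np.allclose(ts[0].translation, 0)

    def test_p212121_has_four_operators(self):
        ts = candidate_transforms((40, 50, 60, 90, 90, 90), "P 21 21 21", 0)
        assert len(ts) == 4

    def test_shell_multiplies_by_translations(self):
        ts = candidate_transforms((40, 50, 60, 90, 100, 90), "P 1 21 1", 1)
        assert len(ts) == 2 * 27

    def test_transforms_are_isometries(self, rng):
        tri = rng.normal(0, 5, (3, 3))
        d0 = np.linalg.norm(tri[:, None] - tri[None], axis=2)
        for t in candidate_transforms((40, 50, 60, 90, 104.5, 90), "P 1 21 1", 1):
            moved = t.apply(tri)
            d = np.linalg.norm(moved[:, None] - moved[None], axis=2)
            assert np.allclose(d, d0, atol=1e-6)

    def test_unknown_spacegroup_raises(self):
        with pytest.raises(ValueError):
            candidate_transforms((50, 50, 50, 90, 90, 90), "Q 9", 0)

    def test_no_cell_gives_identity_only(self):
        assert len(candidate_transforms(None, None, 2)) == 1


class TestAllocationScore:
    def test_contacts_count_plus_one_each(self, varied_chain):
        chain_ca = varied_chain.ca_array()[:20]
        frag = docked_piece(varied_chain, 20, 23)  # 3 residues at the junction
        near = sum(
            1 for ca in frag.ca_array()
            if np.min(np.linalg.norm(chain_ca - ca, axis=1)) <= 5.0
        )
        score, t = allocation_score(
            frag, chain_ca, set(range(1, 21)), [RigidTransform.identity()],
            same_sequence=True,
        )
        assert score == near
        assert np.allclose(t.rotation, np.eye(3))

    def test_seqnum_collision_penalty(self, varied_chain):
        chain_ca = varied_chain.ca_array()[:20]
        frag = docked_piece(varied_chain, 19, 22)  # seqnum 20 collides
        score, _ = allocation_score(
            frag, chain_ca, set(range(1, 21)), [RigidTransform.identity()],
            same_sequence=True,
        )
        no_penalty, _ = allocation_score(
            frag, chain_ca, set(range(1, 21)), [RigidTransform.identity()],
            same_sequence=False,
        )
        assert no_penalty - score == 2

    def test_symmetry_copy_reached_through_non_identity(self, varied_chain):
        cell = (60, 60, 60, 90, 90, 90)
        transforms = candidate_transforms(cell, "P 1 21 1", 0)
        non_identity = transforms[1]
        chain_ca = varied_chain.ca_array()[:20]
        frag = docked_piece(varied_chain, 20, 25)
        displaced = frag.transform(non_identity.inverse())
        score, best_t = allocation_score(
            displaced, chain_ca, set(), transforms, same_sequence=False
        )
        assert score > 0
        assert np.allclose(best_t.rotation, non_identity.rotation, atol=1e-9)


class TestGrowChains:
    def test_scattered_single_copy_fully_allocated(self, varied_chain):
        frags = [
            docked_piece(varied_chain, 0, 30),
            docked_piece(varied_chain, 30, 60),
            docked_piece(varied_chain, 60, 90),
        ]
        asg = grow_chains({"A": 0}, frags, [0, 1, 2],
                          [RigidTransform.identity()], TidyParams())
        assert sorted(asg.chains["A"]) == [0, 1, 2]
        assert all(score > 0 for _, _, score in asg.log)

    def test_distant_decoy_left_out(self, varied_chain):
        decoy = docked_piece(varied_chain, 40, 50)
        for r in decoy.residues:
            r.atoms["CA"] = r.atoms["CA"] + np.array([100.0, 0, 0])
        frags = [docked_piece(varied_chain, 0, 30), decoy]
        asg = grow_chains({"A": 0}, frags, [0, 1],
                          [RigidTransform.identity()], TidyParams())
        assert asg.chains["A"] == [0]

    def test_chained_recruitment_through_new_members(self, varied_chain):
        """A fragment touching only a newly added fragment is still recruited."""
        frags = [
            docked_piece(varied_chain, 0, 30),
            docked_piece(varied_chain, 30, 60),
            docked_piece(varied_chain, 60, 90),  # touches only fragment 1
        ]
        d02 = np.min([
            np.linalg.norm(a - b)
            for a in frags[0].ca_array() for b in frags[2].ca_array()
        ])
        asg = grow_chains({"A": 0}, frags, [0, 1, 2],
                          [RigidTransform.identity()], TidyParams())
        if d02 > 5.0:  # fragment 2 genuinely out of reach of the seed alone
            assert 2 in asg.chains["A"]


class TestAssembleChains:
    def _assignment(self, frags):
        asg = Assignment()
        asg.chains = {"A": list(range(len(frags)))}
        asg.transforms = {i: RigidTransform.identity() for i in range(len(frags))}
        asg.chain_sequence = {"A": "S"}
        return asg

    def test_disjoint_ranges_keep_numbering(self, varied_chain):
        frags = [docked_piece(varied_chain, 9, 20), docked_piece(varied_chain, 24, 40)]
        chains = assemble_chains(self._assignment(frags), frags)
        assert len(chains) == 1
        assert [r.seqnum for r in chains[0].residues] == (
            list(range(10, 21)) + list(range(25, 41))
        )
        assert all(r.inscode == "" for r in chains[0].residues)

    def test_collision_gets_insertion_code(self, varied_chain):
        frags = [docked_piece(varied_chain, 10, 31), docked_piece(varied_chain, 29, 45)]
        chains = assemble_chains(self._assignment(frags), frags)
        dupes = [r for r in chains[0].residues if r.seqnum == 30]
        assert [r.inscode for r in dupes] == ["", "A"]
        chains[0].check_unique_ids()

    def test_single_fragment_chain_unchanged(self, varied_chain):
        frags = [docked_piece(varied_chain, 10, 30)]
        chains = assemble_chains(self._assignment(frags), frags)
        assert [r.seqnum for r in chains[0].residues] == list(range(11, 31))


class TestTidyModel:
    def _purity(self, work, truth, report, tidied):
        frag_chain = {}
        for info in report["seeds"].values():
            for cid, fi in zip(info["chains"], info["seed_fragments"]):
                frag_chain[fi] = cid
        for d in report["decision_log"]:
            frag_chain[d["fragment"]] = d["chain"]
        chain_mols = defaultdict(list)
        for fi, cid in frag_chain.items():
            t = truth["fragments"][fi]
            chain_mols[cid].extend([t["molecule"]] * len(t["seqnums"]))
        seq_len = {sid: len(s) for sid, s in work.sequences}
        out = {}
        for chain in tidied.fragments:
            mols = chain_mols.get(chain.chain_id)
            if not mols:
                continue
            top = max(set(mols), key=mols.count)
            completeness = len(mols) / seq_len[chain.sequence_id]
            out[chain.chain_id] = (mols.count(top) / len(mols), completeness)
        return out

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_hetero_dimer_ncs_recovery(self, hairpin_db, seed):
        """4 chains recovered; every >=60%-complete chain is >=80% one molecule."""
        spec = fx.hetero_dimer_ncs_preset(seed=seed)
        work, truth = fx.scatter_model(spec)
        tidied, report = tidy_model(work, db=hairpin_db)
        seeded_chains = [c for info in report["seeds"].values()
                         for c in info["chains"]]
        assert len(seeded_chains) == 4
        purity = self._purity(work, truth, report, tidied)
        complete_enough = {c: p for c, (p, comp) in purity.items() if comp >= 0.6}
        assert complete_enough, "no chain reached 60% completeness"
        for cid, frac in complete_enough.items():
            assert frac >= 0.8

    def test_already_tidy_chain_is_idempotent(self, varied_chain):
        frag = docked_piece(varied_chain, 0, 100)
        work = WorkModel(fragments=[frag.copy()], sequences=[("S", "A" * 250)],
                         cell=(80, 60, 70, 90, 100, 90), spacegroup="P 1 21 1")
        tidied, _ = tidy_model(work)
        assert len(tidied.fragments) == 1
        out = tidied.fragments[0]
        assert [r.seqnum for r in out.residues] == [r.seqnum for r in frag.residues]
        assert np.allclose(out.ca_array(), frag.ca_array())

    def test_symmetry_displaced_fragment_returned(self, varied_chain):
        """A fragment parked in a neighbouring asymmetric unit is brought back."""
        cell = (60, 60, 60, 90, 90, 90)
        op = candidate_transforms(cell, "P 1 21 1", 0)[1]
        near = docked_piece(varied_chain, 0, 40)
        displaced = docked_piece(varied_chain, 40, 70).transform(op)
        work = WorkModel(fragments=[near, displaced],
                         sequences=[("S", "A" * 250)],
                         cell=cell, spacegroup="P 1 21 1")
        tidied, report = tidy_model(work)
        assert len(tidied.fragments) == 1
        moves = {d["fragment"]: d for d in report["decision_log"]}
        assert 1 in moves and moves[1]["score"] > 0
        # the applied transform restored spatial adjacency
        out_ca = tidied.fragments[0].ca_array()
        d = np.linalg.norm(out_ca[39] - out_ca[40])
        assert d < 5.0

    def test_empty_work_model_raises(self):
        with pytest.raises(ValueError):
            tidy_model(WorkModel(fragments=[], sequences=[]))

    def test_decision_log_reproducible(self, hairpin_db):
        spec = fx.hetero_dimer_ncs_preset(seed=2)
        work1, _ = fx.scatter_model(spec)
        work2, _ = fx.scatter_model(spec)
        _, r1 = tidy_model(work1, db=hairpin_db)
        _, r2 = tidy_model(work2, db=hairpin_db)
        assert r1["decision_log"] == r2["decision_log"]
        assert r1["transforms"] == r2["transforms"]
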
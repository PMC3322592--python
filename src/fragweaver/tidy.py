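"""Assembly of disconnected fragments into complete molecules.

The tidying procedure groups partially sequence-docked chain fragments into
molecules under crystallographic symmetry and NCS:

1. Fragments are sorted by the sequence they were docked to; each sequence is
   handled in turn.
2. *Seeds* — one fragment per NCS copy — are found as the largest clique of the
   fragment-overlap graph: two fragments "overlap" when they share more than 12
   sequence numbers in a similar conformation (the best-matched half of the
   overlapped Calphas superposes below 1 A RMSD).  Fragments covering the same
   sequence range in the same conformation must be distinct NCS copies.
3. Remaining fragments are allocated iteratively: each unallocated fragment is
   scored against each chain over all candidate symmetry transforms (+1 per
   Calpha within 5 A of a chain Calpha, -2 per sequence-number collision); the
   globally best positive move is applied and scores recomputed.
4. Chains are assembled in sequence-number order, with insertion codes
   disambiguating duplicated numbers, and remaining numbered breaks are
   bridged from the fragment database where possible.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, superpose
from .model import ChainModel, WorkModel
from .rebuild import apply_bridge, bridge_gap

#: A pair of fragments must share more than this many residues to overlap.
OVERLAP_MIN_EXCLUSIVE = 12

#: Conformation-similarity ceiling for the best-matched half (A RMSD).
OVERLAP_RMSD_MAX = 1.0

#: Contact distance for the +1 compactness reward (A).
CONTACT_RADIUS = 5.0

#: Penalty per duplicated sequence number when adding a fragment to a chain.
COLLISION_PENALTY = 2


@dataclass
class TidyParams:
    shell: int = 1
    contact_radius: float = CONTACT_RADIUS
    stem_rmsd_max: float = 0.75
    bridge: bool = True


@dataclass
class Assignment:
    """Outcome of chain growth: chain membership, transforms and decision log."""

    chains: dict = field(default_factory=dict)   # chain_id -> list of frag index
    transforms: dict = field(default_factory=dict)  # frag index -> RigidTransform
    chain_sequence: dict = field(default_factory=dict)  # chain_id -> sequence_id
    log: list = field(default_factory=list)      # (frag index, chain_id, score)

    def chain_of(self, frag_index: int) -> str | None:
        for cid, members in self.chains.items():
            if frag_index in members:
                return cid
        return None


def overlap_entry(frag_a: ChainModel, frag_b: ChainModel) -> int:
    """Overlap-matrix entry for two fragments docked to the same sequence.

    Counts the shared sequence numbers; returns that count iff it exceeds 12
    *and* the overlapped regions have similar conformations, else 0.  Similar
    conformation: superpose all overlapped Calpha pairs, keep the best-matched
    50% (smallest residuals), re-superpose the kept subset, and require its
    RMSD below 1 A.
    """
    if frag_a.sequence_id != frag_b.sequence_id or frag_a.sequence_id is None:
        raise ValueError("overlap is defined for fragments of one sequence")
    pos_a = {r.seqnum: r for r in frag_a.residues if "CA" in r.atoms}
    pos_b = {r.seqnum: r for r in frag_b.residues if "CA" in r.atoms}
    shared = sorted(set(pos_a) & set(pos_b))
    k = len(shared)
    if k <= OVERLAP_MIN_EXCLUSIVE:
        return 0
    a = np.array([pos_a[s].atoms["CA"] for s in shared], dtype=float)
    b = np.array([pos_b[s].atoms["CA"] for s in shared], dtype=float)
    t, _ = superpose(a, b)
    residuals = np.linalg.norm(t.apply(a) - b, axis=1)
    keep = np.argsort(residuals, kind="stable")[: max(3, int(np.ceil(k / 2)))]
    _, rmsd = superpose(a[keep], b[keep])
    return k if rmsd < OVERLAP_RMSD_MAX else 0


def overlap_matrix(fragments: list[ChainModel]) -> np.ndarray:
    n = len(fragments)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = overlap_entry(fragments[i], fragments[j])
    return m


def max_overlap_clique(matrix: np.ndarray, weights) -> list[int]:
    """Largest clique of the overlap graph; ties broken on total weight.

    Depth-first search with pruning: a branch is abandoned when even taking all
    remaining candidates cannot beat the best clique found.  ``weights`` are
    the fragments' residue counts; among equal-size cliques the one with the
    greatest total weight wins (further ties: lexicographically smallest index
    set, for determinism).
    """
    n = len(matrix)
    weights = list(weights)
    adj = [set(np.nonzero(matrix[i] > 0)[0].tolist()) for i in range(n)]
    best: tuple[int, int, list[int]] = (0, 0, [])

    def dfs(clique: list[int], cand: list[int], weight: int) -> None:
        nonlocal best
        key = (len(clique), weight)
        if key > best[:2] or (key == best[:2] and (not best[2] or clique < best[2])):
            best = (len(clique), weight, list(clique))
        if not cand:
            return
        if len(clique) + len(cand) < best[0]:
            return  # cannot beat best size
        for idx, v in enumerate(cand):
            rest = [u for u in cand[idx + 1:] if u in adj[v]]
            dfs(clique + [v], rest, weight + weights[v])

    dfs([], list(range(n)), 0)
    return best[2]


@dataclass(frozen=True)
class SeedSet:
    """One fragment per NCS copy, all sharing a sequence range in conformation."""

    indices: tuple
    seq_range: tuple | None = None


def find_seeds(fragments: list[ChainModel]) -> SeedSet:
    """Seed fragments for one sequence: the maximum clique of the overlap graph.

    With no passing overlaps at all there is a single NCS copy as far as the
    evidence goes; the longest fragment becomes the lone seed.
    """
    if not fragments:
        return SeedSet(indices=())
    m = overlap_matrix(fragments)
    clique = max_overlap_clique(m, [len(f) for f in fragments])
    if len(clique) <= 1:
        longest = max(range(len(fragments)),
                      key=lambda i: (len(fragments[i]), -i))
        return SeedSet(indices=(longest,))
    ranges = [set(fragments[i].seqnums()) for i in clique]
    common = sorted(set.intersection(*ranges))
    rng = (common[0], common[-1]) if common else None
    return SeedSet(indices=tuple(sorted(clique)), seq_range=rng)


def candidate_transforms(
    cell, spacegroup: str | None, shell: int = 1
) -> list[RigidTransform]:
    """Crystallographic symmetry operators (x lattice translations) as rigid motions.

    Space-group operations in fractional coordinates are conjugated into the
    orthogonal frame through the cell's orthogonalisation matrix, composed with
    every lattice translation of -shell..+shell cells per axis.  With no cell
    or space group only the identity is returned.
    """
    import gemmi

    if cell is None or spacegroup is None:
        return [RigidTransform.identity()]
    sg = gemmi.SpaceGroup(spacegroup)  # raises ValueError on unknown symbol
    uc = gemmi.UnitCell(*cell)
    orth = np.array(uc.orth.mat.tolist(), dtype=float)
    frac = np.linalg.inv(orth)
    out: list[RigidTransform] = []
    shifts = range(-shell, shell + 1)
    for op in sg.operations():
        r_frac = np.array(op.rot, dtype=float) / op.DEN
        t_frac = np.array(op.tran, dtype=float) / op.DEN
        r_orth = orth @ r_frac @ frac
        for u in shifts:
            for v in shifts:
                for w in shifts:
                    t = orth @ (t_frac + np.array([u, v, w], dtype=float))
                    out.append(RigidTransform(r_orth, t))
    return out


def allocation_score(
    fragment: ChainModel,
    chain_ca: np.ndarray,
    chain_seqnums: set,
    transforms: list[RigidTransform],
    same_sequence: bool,
    contact_radius: float = CONTACT_RADIUS,
) -> tuple[int, RigidTransform]:
    """Best score (and its transform) for adding `fragment` to a chain.

    For each candidate transform T: +1 for every fragment Calpha whose T-image
    lies within the contact radius of any chain Calpha (each fragment atom
    counts at most once), -2 for every docked residue whose sequence number is
    already present in the chain (only meaningful when fragment and chain share
    a sequence).  Ties keep the earliest transform in the candidate order.
    """
    if len(chain_ca) == 0:
        raise ValueError("chain-so-far must be nonempty")
    tree = cKDTree(chain_ca)
    frag_ca = fragment.ca_array()
    penalty = 0
    if same_sequence and fragment.sequence_id is not None:
        penalty = COLLISION_PENALTY * sum(
            1 for s in fragment.seqnums() if s in chain_seqnums
        )
    best_score = -(10 ** 9)
    best_t = transforms[0]
    for t in transforms:
        moved = t.apply(frag_ca)
        dists, _ = tree.query(moved, k=1, distance_upper_bound=contact_radius + 1e-9)
        contacts = int(np.isfinite(dists).sum())
        score = contacts - penalty
        if score > best_score:
            best_score = score
            best_t = t
    return best_score, best_t


def grow_chains(
    seeds: dict,
    fragments: list[ChainModel],
    frag_indices: list[int],
    transforms: list[RigidTransform],
    params: TidyParams,
    assignment: Assignment | None = None,
    geometric_only: bool = False,
    chain_ids: list | None = None,
) -> Assignment:
    """Iteratively allocate fragments to chains by the compactness score.

    ``seeds`` maps chain_id -> seed fragment index (seeds keep the identity
    transform).  Each round scores every unallocated fragment against every
    chain; the single best positive move is applied and, because the chain has
    grown, all scores are recomputed.  Terminates when no positive score
    remains (at most one move per fragment, so at most n iterations).
    """
    asg = assignment if assignment is not None else Assignment()
    for cid, si in seeds.items():
        asg.chains[cid] = [si]
        asg.transforms[si] = RigidTransform.identity()
        asg.chain_sequence[cid] = fragments[si].sequence_id
    pending = [i for i in frag_indices if i not in asg.transforms]
    active = set(chain_ids) if chain_ids is not None else set(asg.chains)
    while pending:
        best = None  # (score, chain_id, frag_index, transform)
        for cid, members in asg.chains.items():
            if cid not in active:
                continue
            chain_ca = np.vstack([
                asg.transforms[i].apply(fragments[i].ca_array()) for i in members
            ])
            chain_seqs = set()
            for i in members:
                if fragments[i].sequence_id == asg.chain_sequence[cid]:
                    chain_seqs.update(fragments[i].seqnums())
            for fi in pending:
                same_seq = (not geometric_only) and (
                    fragments[fi].sequence_id == asg.chain_sequence[cid]
                )
                score, t = allocation_score(
                    fragments[fi], chain_ca, chain_seqs, transforms,
                    same_sequence=same_seq,
                    contact_radius=params.contact_radius,
                )
                if best is None or score > best[0] or (
                    score == best[0] and (cid, fi) < (best[1], best[2])
                ):
                    best = (score, cid, fi, t)
        if best is None or best[0] <= 0:
            break
        score, cid, fi, t = best
        asg.chains[cid].append(fi)
        asg.transforms[fi] = t
        asg.log.append((fi, cid, score))
        pending.remove(fi)
    return asg


def assemble_chains(
    assignment: Assignment, fragments: list[ChainModel]
) -> list[ChainModel]:
    """Concatenate each chain's fragments in sequence order with insertion codes.

    Fragments are ordered by their first sequence number; residues keep their
    numbers, and when a number recurs the later occurrences get insertion codes
    A, B, ... in encounter order.
    """
    out = []
    for cid in sorted(assignment.chains):
        members = assignment.chains[cid]
        placed = [
            fragments[i].transform(assignment.transforms[i]) for i in members
        ]
        placed.sort(key=lambda f: (f.residues[0].seqnum if len(f) else 0))
        residues = []
        seen: dict[int, int] = {}
        for frag in placed:
            for r in frag.residues:
                rr = r.copy()
                count = seen.get(rr.seqnum, 0)
                if count == 0:
                    rr.inscode = ""
                else:
                    if count > 26:
                        raise ValueError("insertion codes exhausted")
                    rr.inscode = string.ascii_uppercase[count - 1]
                seen[rr.seqnum] = count + 1
                residues.append(rr)
        chain = ChainModel(residues=residues, chain_id=cid,
                           sequence_id=assignment.chain_sequence.get(cid))
        chain.check_unique_ids()
        out.append(chain)
    return out


def _dummy_ids(start: int):
    """Chain ids continuing the alphabet after the seeds, then two-character ids."""
    letters = string.ascii_uppercase
    i = start
    while True:
        if i < 26:
            yield letters[i]
        else:
            yield letters[(i // 26) - 1] + letters[i % 26]
        i += 1


def tidy_model(
    work: WorkModel,
    db=None,
    params: TidyParams | None = None,
) -> tuple[WorkModel, dict]:
    """Full tidying pipeline; returns the tidied model and a JSON-able report.

    Per sequence: find seeds, grow chains.  Undocked fragments are then
    allocated across all chains by the geometric term alone.  Chains are
    assembled with insertion codes, and — when a fragment database is supplied
    — every remaining numbered discontinuity is offered to the gap-bridging
    step.  Leftover fragments keep dummy chain identifiers.
    """
    work.validate()
    if params is None:
        params = TidyParams()
    if not work.fragments:
        raise ValueError("nothing to tidy: no fragments")
    transforms = candidate_transforms(work.cell, work.spacegroup, params.shell)
    fragments = work.fragments
    asg = Assignment()
    seeds: dict[str, int] = {}
    chain_counter = 0
    seed_report = {}
    for seq_id, _seq in work.sequences:
        idx = [i for i, f in enumerate(fragments)
               if f.sequence_id == seq_id and i not in asg.transforms]
        if not idx:
            continue
        sub = [fragments[i] for i in idx]
        seed_set = find_seeds(sub)
        # seeds ordered by descending fragment length for chain-id assignment
        seed_idx = sorted(
            (idx[k] for k in seed_set.indices),
            key=lambda i: (-len(fragments[i]), i),
        )
        ids = []
        local_seeds = {}
        for si in seed_idx:
            cid = next(_dummy_ids(chain_counter))
            chain_counter += 1
            local_seeds[cid] = si
            ids.append(cid)
        seed_report[seq_id] = {
            "chains": ids,
            "seed_fragments": seed_idx,
            "seq_range": list(seed_set.seq_range) if seed_set.seq_range else None,
        }
        asg = grow_chains(local_seeds, fragments, idx, transforms, params,
                          assignment=asg, chain_ids=list(local_seeds))
    # undocked fragments: geometric score only, across all chains
    undocked = [i for i, f in enumerate(fragments)
                if f.sequence_id is None and i not in asg.transforms]
    if undocked and asg.chains:
        asg = grow_chains({}, fragments, undocked, transforms, params,
                          assignment=asg, geometric_only=True)
    # leftovers -> dummy chains
    for i, f in enumerate(fragments):
        if i not in asg.transforms:
            cid = next(_dummy_ids(chain_counter))
            chain_counter += 1
            asg.chains[cid] = [i]
            asg.transforms[i] = RigidTransform.identity()
            asg.chain_sequence[cid] = f.sequence_id
    chains = assemble_chains(asg, fragments)
    bridges = []
    if db is not None and params.bridge:
        chains = [
            _bridge_discontinuities(c, db, params, bridges) for c in chains
        ]
    seq_len = dict(work.sequences)
    report = {
        "seeds": seed_report,
        "decision_log": [
            {"fragment": fi, "chain": cid, "score": sc} for fi, cid, sc in asg.log
        ],
        "transforms": {
            str(i): t.as_3x4() for i, t in sorted(asg.transforms.items())
        },
        "bridges": bridges,
        "chains": {
            c.chain_id: {
                "n_residues": len(c),
                "sequence": c.sequence_id,
                "completeness": (
                    round(len(c) / len(seq_len[c.sequence_id]), 4)
                    if c.sequence_id in seq_len else None
                ),
            }
            for c in chains
        },
    }
    tidied = WorkModel(
        fragments=chains,
        sequences=work.sequences,
        cell=work.cell,
        spacegroup=work.spacegroup,
    )
    return tidied, report


def _split_at_breaks(chain: ChainModel) -> list[ChainModel]:
    """Split an assembled chain at numbered discontinuities (gap or jump)."""
    pieces: list[list] = [[]]
    for r in chain.residues:
        if pieces[-1] and not (
            r.seqnum == pieces[-1][-1].seqnum + 1
            or (r.seqnum == pieces[-1][-1].seqnum and r.inscode)
        ):
            pieces.append([])
        pieces[-1].append(r)
    return [
        ChainModel(residues=p, chain_id=chain.chain_id,
                   sequence_id=chain.sequence_id)
        for p in pieces if p
    ]


def _bridge_discontinuities(chain, db, params: TidyParams, bridges: list):
    if chain.sequence_id is None:
        return chain
    pieces = _split_at_breaks(chain)
    if len(pieces) == 1:
        return chain
    merged = [pieces[0]]
    for nxt in pieces[1:]:
        cur = merged[-1]
        prop = None
        if len(cur) >= 2 and len(nxt) >= 2 and not any(r.inscode for r in cur.residues[-2:]) \
                and not any(r.inscode for r in nxt.residues[:2]):
            try:
                prop = bridge_gap(cur, nxt, db,
                                  stem_rmsd_max=params.stem_rmsd_max)
            except ValueError:
                prop = None
        if prop is not None:
            merged[-1] = apply_bridge(cur, nxt, prop)
            bridges.append({
                "chain": chain.chain_id,
                "after_seqnum": cur.residues[-1 - prop.prune_a].seqnum,
                "inserted": prop.insert_count,
                "stem_rmsd": round(prop.stem_rmsd, 4),
            })
        else:
            merged.append(nxt)
    residues = [r for piece in merged for r in piece.residues]
    return ChainModel(residues=residues, chain_id=chain.chain_id,
                      sequence_id=chain.sequence_id)
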
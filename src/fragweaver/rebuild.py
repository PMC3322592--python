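"""Database-driven model rebuilding.

All rebuilt coordinates are copied from database records and moved by a match's
rigid transform — never interpolated.  Operations:

* ``ca_to_mainchain`` — reconstruct N/C/O for a bare Calpha trace, one peptide
  bond at a time, from the best-matching six-residue database fragment centred
  on that bond.
* ``build_loop`` — fill a gap of known length between two-residue stems by
  searching with null placeholder slots.
* ``bridge_gap`` — close a numbered chain break, pruning duplicated/mistraced
  residues from both ends and testing multiple prunings; the whole bridging
  fragment (two overlap residues each side plus at most two inserted) is capped
  at six amino acids.
* ``link_termini`` — greedily join nearby N/C termini irrespective of sequence.
* ``correct_indel`` — rebuild one or three suspect residues with two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragdb import FragmentDatabase
from .fragsearch import Match, SearchParams, make_search_fragment, search
from .geometry import place_oxygen
from .model import ChainModel, Residue

#: Maximum total length of a bridging fragment (2 overlap + <=2 gap + 2 overlap).
BRIDGE_CAP = 6

#: Default stem-RMSD acceptance ceiling for rebuilt fragments (A).
STEM_RMSD_MAX = 0.75

#: Extra residues pruned per end beyond duplication removal when bridging.
P_MAX = 2


@dataclass(frozen=True)
class BridgeProposal:
    """A candidate chain-break repair.

    ``prune_a``/``prune_b``: residues removed from the upstream tail and the
    downstream head; ``insert_count``: new residues placed in the gap (0-2);
    ``stem_rmsd``: superposition RMSD of the four stem Calphas against the
    matched database fragment.
    """

    prune_a: int
    prune_b: int
    insert_count: int
    match: Match
    stem_rmsd: float
    loop: ChainModel

    def __post_init__(self):
        if 4 + self.insert_count > BRIDGE_CAP:
            raise ValueError("bridging fragment exceeds the six-residue cap")


def _db_residue(db: FragmentDatabase, i: int, match: Match, seqnum: int,
                res_type: str = "X") -> Residue:
    """A residue copied from db record `i`, moved into the query frame."""
    rec = db.record(i)
    t = match.transform
    return Residue(
        seqnum=seqnum,
        res_type=res_type,
        atoms={
            "N": t.apply(rec.n_xyz),
            "CA": t.apply(rec.ca_xyz),
            "C": t.apply(rec.c_xyz),
        },
        provenance=f"db:{rec.source_tag}",
    )


def _add_oxygens(chain: ChainModel) -> None:
    """Place carbonyl O for every residue followed by a located N (in place)."""
    for a, b in zip(chain.residues, chain.residues[1:]):
        if all(k in a.atoms for k in ("CA", "C")) and "N" in b.atoms:
            a.atoms["O"] = place_oxygen(a.atoms["CA"], a.atoms["C"], b.atoms["N"])


def ca_to_mainchain(
    ca_trace: np.ndarray,
    db: FragmentDatabase,
    params: SearchParams | None = None,
) -> ChainModel:
    """Reconstruct a full mainchain (N, Calpha, C, O) from a bare Calpha trace.

    For each peptide bond (i, i+1) a six-residue window of the trace centred on
    the bond (three residues either side, shrunk to a minimum of four at the
    termini) is matched against the database; C(i) and N(i+1) are copied from
    the middle peptide of the best-fitting fragment, transformed into the trace
    frame.  O atoms are then placed from the rebuilt peptide planes.  The
    Calpha positions are the input's own.
    """
    ca = np.asarray(ca_trace, dtype=float).reshape(-1, 3)
    n = len(ca)
    if n < 4:
        raise ValueError("Calpha trace must have at least 4 residues")
    if params is None:
        params = SearchParams(n_prescreen=500, n_return=1)
    residues = [Residue(seqnum=i + 1, atoms={"CA": ca[i].copy()}) for i in range(n)]
    for i in range(n - 1):
        lo = max(0, i - 2)
        hi = min(n, i + 4)
        # keep at least a 4-residue window at the termini
        if hi - lo < 4:
            lo, hi = max(0, hi - 4), min(n, lo + 4)
        sf = make_search_fragment(list(ca[lo:hi]), width=db.width)
        matches = search(db, sf, params)
        if not matches:
            continue
        m = matches[0]
        k = i - lo  # bond between window slots k, k+1
        rec_c = db.record(m.offset + k)
        rec_n = db.record(m.offset + k + 1)
        residues[i].atoms["C"] = m.transform.apply(rec_c.c_xyz)
        residues[i + 1].atoms["N"] = m.transform.apply(rec_n.n_xyz)
        residues[i].provenance = f"db:{rec_c.source_tag}"
        if i == 0:
            residues[0].atoms["N"] = m.transform.apply(rec_c.n_xyz)
        if i == n - 2:
            residues[n - 1].atoms["C"] = m.transform.apply(rec_n.c_xyz)
            residues[n - 1].provenance = f"db:{rec_n.source_tag}"
    out = ChainModel(residues=residues)
    _add_oxygens(out)
    return out


def _stem_ca(chain: ChainModel, head: bool) -> list[np.ndarray]:
    res = chain.residues[:2] if head else chain.residues[-2:]
    return [np.asarray(r.atoms["CA"], dtype=float) for r in res]


def _loop_search(
    stem_n_ca,
    stem_c_ca,
    gap: int,
    db: FragmentDatabase,
    params: SearchParams,
    stem_rmsd_max: float,
):
    """Search for `gap` missing residues between 2+2 stems; best passing match.

    Returns (match, loop_residues) or None.  The loop residues carry N/Calpha/C
    copied from the matched database records (transformed); their O atoms are
    placed afterwards by the caller once the following N is known.
    """
    slots = list(stem_n_ca) + [None] * gap + list(stem_c_ca)
    sf = make_search_fragment(slots, width=db.width)
    matches = search(db, sf, params)
    if not matches or matches[0].rmsd > stem_rmsd_max:
        return None
    m = matches[0]
    loop = [
        _db_residue(db, m.offset + 2 + j, m, seqnum=j + 1) for j in range(gap)
    ]
    return m, loop


def build_loop(
    stem_n: ChainModel,
    stem_c: ChainModel,
    gap: int,
    db: FragmentDatabase,
    params: SearchParams | None = None,
    stem_rmsd_max: float = STEM_RMSD_MAX,
) -> ChainModel | None:
    """Build `gap` missing residues between two 2-residue stems, or ``None``.

    The search fragment is the two residues before the gap, `gap` null
    placeholders and the two residues after; the best match whose stem RMSD
    passes supplies the null-slot coordinates.
    """
    if gap < 1:
        raise ValueError("gap must be >= 1")
    if len(stem_n) < 2 or len(stem_c) < 2:
        raise ValueError("each stem needs 2 residues with Calpha atoms")
    if 4 + gap > db.width + 1:
        raise ValueError("loop too long for the database window")
    if params is None:
        params = SearchParams(n_prescreen=500, n_return=1)
    hit = _loop_search(
        _stem_ca(stem_n, head=False), _stem_ca(stem_c, head=True),
        gap, db, params, stem_rmsd_max,
    )
    if hit is None:
        return None
    m, loop = hit
    first = stem_n.residues[-1].seqnum + 1
    for j, res in enumerate(loop):
        res.seqnum = first + j
    out = ChainModel(residues=loop, chain_id=stem_n.chain_id,
                     sequence_id=stem_n.sequence_id)
    # O placement needs the next N: use the stem_c first residue if it has one
    nxt = stem_c.residues[0]
    tail = loop + ([nxt] if "N" in nxt.atoms else [])
    _add_oxygens(ChainModel(residues=tail))
    return out


def bridge_gap(
    chain_a: ChainModel,
    chain_b: ChainModel,
    db: FragmentDatabase,
    params: SearchParams | None = None,
    stem_rmsd_max: float = STEM_RMSD_MAX,
    p_max: int = P_MAX,
) -> BridgeProposal | None:
    """Best repair of the numbered break between `chain_a`'s tail and `chain_b`'s head.

    Prunings of each end are enumerated — always at least enough that no
    sequence number appears on both sides (mistraced ends), plus up to `p_max`
    extra per end — and for each pruning the implied number of inserted
    residues must make the sequence numbering consistent and keep the whole
    bridging fragment within the six-residue cap.  The passing proposal with
    the lowest stem RMSD wins.
    """
    if chain_a.sequence_id != chain_b.sequence_id or chain_a.sequence_id is None:
        raise ValueError("both chains must be docked to the same sequence")
    if params is None:
        params = SearchParams(n_prescreen=500, n_return=1)
    a_nums = chain_a.seqnums()
    b_nums = chain_b.seqnums()
    # minimal pruning: remove duplicated sequence numbers from the facing ends
    overlap = max(0, a_nums[-1] - b_nums[0] + 1)
    best: BridgeProposal | None = None
    lim = overlap + p_max + 1
    # minimal-modification prunings first: ties in stem RMSD (below 1e-6 A)
    # keep the earliest, i.e. least destructive, proposal
    prunings = sorted(
        ((pa, pb) for pa in range(lim) for pb in range(lim)),
        key=lambda p: (p[0] + p[1], p[0]),
    )
    for pa, pb in prunings:
        if len(chain_a) - pa >= 2 and len(chain_b) - pb >= 2:
            a_end = a_nums[-1 - pa]
            b_start = b_nums[pb]
            if a_end >= b_start:
                continue  # duplicated numbering not yet removed
            gap = b_start - a_end - 1
            if gap > BRIDGE_CAP - 4:
                continue
            tail = chain_a.slice(0, len(chain_a) - pa)
            head = chain_b.slice(pb, len(chain_b))
            hit = _loop_search(
                _stem_ca(tail, head=False), _stem_ca(head, head=True),
                gap, db, params, stem_rmsd_max,
            )
            if hit is None:
                continue
            m, loop = hit
            for j, res in enumerate(loop):
                res.seqnum = a_end + 1 + j
            prop = BridgeProposal(
                prune_a=pa, prune_b=pb, insert_count=gap, match=m,
                stem_rmsd=m.rmsd,
                loop=ChainModel(residues=loop, chain_id=chain_a.chain_id,
                                sequence_id=chain_a.sequence_id),
            )
            if best is None or prop.stem_rmsd < best.stem_rmsd - 1e-6:
                best = prop
    return best


def apply_bridge(
    chain_a: ChainModel, chain_b: ChainModel, prop: BridgeProposal
) -> ChainModel:
    """Merge two docked chains using an accepted bridge proposal."""
    tail = chain_a.slice(0, len(chain_a) - prop.prune_a)
    head = chain_b.slice(prop.prune_b, len(chain_b))
    residues = tail.residues + [r.copy() for r in prop.loop.residues] + head.residues
    out = ChainModel(residues=residues, chain_id=chain_a.chain_id,
                     sequence_id=chain_a.sequence_id)
    _add_oxygens(out)
    out.check_unique_ids()
    return out


def link_termini(
    fragments: list[ChainModel],
    db: FragmentDatabase,
    params: SearchParams | None = None,
    stem_rmsd_max: float = STEM_RMSD_MAX,
    max_gap_distance: float = 15.0,
) -> list[ChainModel]:
    """Greedy merging of nearby C-/N-terminus pairs irrespective of sequence.

    For every ordered pair of fragments (C terminus of one, N terminus of
    another) and every insertion count 0-2, a loop search is run; candidate
    merges are applied in ascending stem-RMSD order, each terminus used at most
    once.  A self-link of a chain's own termini is only allowed when at least
    two residues would be inserted (a shorter self-loop is geometric nonsense).
    Merged chains are renumbered consecutively across the join.
    """
    if params is None:
        params = SearchParams(n_prescreen=500, n_return=1)
    frags = [f.copy() for f in fragments]
    proposals = []  # (stem_rmsd, i, j, gap, match, loop)
    for i, fa in enumerate(frags):
        if len(fa) < 2:
            continue
        for j, fb in enumerate(frags):
            if len(fb) < 2:
                continue
            end_ca = fa.residues[-1].atoms["CA"]
            start_ca = fb.residues[0].atoms["CA"]
            d = float(np.linalg.norm(np.asarray(end_ca) - np.asarray(start_ca)))
            if d > max_gap_distance:
                continue
            for gap in range(0, 3):
                if i == j and gap < 2:
                    continue  # self-link guard
                if i == j and len(fa) < 5:
                    continue
                if d > 4.2 * (gap + 1):
                    continue  # physically unreachable
                hit = _loop_search(
                    _stem_ca(fa, head=False), _stem_ca(fb, head=True),
                    gap, db, params, stem_rmsd_max,
                )
                if hit is None:
                    continue
                m, loop = hit
                proposals.append((m.rmsd, i, j, gap, m, loop))
    proposals.sort(key=lambda p: (p[0], p[1], p[2], p[3]))
    used_c: set[int] = set()
    used_n: set[int] = set()
    merges = []
    for rmsd_val, i, j, gap, m, loop in proposals:
        if i in used_c or j in used_n or i == j:
            continue
        used_c.add(i)
        used_n.add(j)
        merges.append((i, j, loop))
    # stitch merge chains (a fragment may gain both a predecessor and successor)
    succ = {i: (j, loop) for i, j, loop in merges}
    has_pred = {j for _, j, _ in merges}
    out: list[ChainModel] = []
    consumed: set[int] = set()
    for i in range(len(frags)):
        if i in has_pred or i in consumed:
            continue
        residues = [r.copy() for r in frags[i].residues]
        chain = frags[i]
        cur = i
        consumed.add(i)
        while cur in succ:
            nxt, loop = succ[cur]
            residues.extend(r.copy() for r in loop)
            residues.extend(r.copy() for r in frags[nxt].residues)
            consumed.add(nxt)
            cur = nxt
        merged = ChainModel(residues=residues, chain_id=chain.chain_id,
                            sequence_id=None)
        first = frags[i].residues[0].seqnum
        merged = merged.renumber(first)
        _add_oxygens(merged)
        out.append(merged)
    return out


def correct_indel(
    chain: ChainModel,
    site: int,
    site_len: int,
    db: FragmentDatabase,
    params: SearchParams | None = None,
    stem_rmsd_max: float = STEM_RMSD_MAX,
) -> ChainModel | None:
    """Rebuild 1 or 3 suspect residues with 2, fixing an insertion/deletion.

    ``site`` is the index of the first suspect residue in ``chain.residues``
    and ``site_len`` is 1 or 3.  A search fragment of two stems either side of
    two null slots replaces the site; downstream numbering shifts by +1
    (1 -> 2 residues) or -1 (3 -> 2).  Returns ``None`` when the site is too
    close to a chain end for two stems, or no match passes.
    """
    if site_len not in (1, 3):
        raise ValueError("site_len must be 1 or 3")
    if site < 2 or site + site_len + 2 > len(chain):
        return None
    if params is None:
        params = SearchParams(n_prescreen=500, n_return=1)
    stem_n = chain.slice(site - 2, site)
    stem_c = chain.slice(site + site_len, site + site_len + 2)
    hit = _loop_search(
        _stem_ca(stem_n, head=False), _stem_ca(stem_c, head=True),
        2, db, params, stem_rmsd_max,
    )
    if hit is None:
        return None
    m, loop = hit
    first = chain.residues[site - 1].seqnum + 1
    for j, res in enumerate(loop):
        res.seqnum = first + j
    shift = 2 - site_len
    downstream = []
    for r in chain.residues[site + site_len:]:
        rr = r.copy()
        rr.seqnum += shift
        downstream.append(rr)
    residues = [r.copy() for r in chain.residues[:site]] + loop + downstream
    out = ChainModel(residues=residues, chain_id=chain.chain_id,
                     sequence_id=chain.sequence_id)
    _add_oxygens(out)
    out.check_unique_ids()
    return out
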
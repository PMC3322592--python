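"""Gap-tolerant, mask-filtered fragment search.

The search proceeds in two stages.  A cheap pre-screen compares the query's
triangular Calpha distance matrix against the database's running distance
matrix by a sum of squared differences, keeping the best ``n_prescreen``
offsets; because a distance matrix is invariant under point inversion, this
stage cannot distinguish a fragment from its mirror image.  The surviving
candidates are therefore re-scored by full least-squares superposition (proper
rotations only), which demotes mirror hits, and re-sorted by Calpha RMSD.

Null slots in the query (unknown residues, e.g. a missing loop) simply
contribute no distance-matrix entries and are excluded from the superposition;
per-slot 20-bit residue-type masks restrict which database residues may occupy
each position.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .constants import FULL_MASK
from .fragdb import FragmentDatabase
from .geometry import RigidTransform, superpose_many

__all__ = [
    "SearchFragment",
    "SearchParams",
    "Match",
    "make_search_fragment",
    "prescreen",
    "mask_pass",
    "rescore",
    "search",
    "coverage_experiment",
]


@dataclass(frozen=True)
class SearchParams:
    """Knobs of the two-stage search.

    ``n_prescreen``: candidates kept by the distance-matrix pre-screen;
    ``n_return``: final matches returned; ``rmsd_max``: optional acceptance
    ceiling on the re-scored Calpha RMSD (A).
    """

    n_prescreen: int = 500
    n_return: int = 50
    rmsd_max: float | None = None

    def __post_init__(self):
        if self.n_return > self.n_prescreen:
            raise ValueError("n_return must not exceed n_prescreen")


@dataclass(frozen=True)
class Match:
    """A scored database hit.

    ``transform`` maps database coordinates into the query frame; ``rmsd`` is
    the Calpha RMSD over the query's non-null slots after superposition.
    """

    offset: int
    ssd: float
    transform: RigidTransform
    rmsd: float
    max_dev: float = float("nan")


class SearchFragment:
    """An ordered list of residue slots, some of which may be null.

    ``ca`` is an (n, 3) array with NaN rows at null slots; ``masks`` holds one
    20-bit allowed-type mask per slot (bit order: alphabetical one-letter
    codes).  The triangular distance matrix ``tdm`` stores, in row ``i``,
    the distances from slot i's Calpha to slots i+1..n-1, with the flag value
    wherever a null slot participates — the same layout as the diagonals of the
    database's running distance matrix, so pre-screen comparison is a direct
    window lookup.
    """

    def __init__(self, ca: np.ndarray, masks=None):
        ca = np.asarray(ca, dtype=float).reshape(-1, 3)
        n = len(ca)
        if n == 0:
            raise ValueError("empty search fragment")
        self.ca = ca
        self.defined = np.isfinite(ca).all(axis=1)
        if self.defined.sum() < 3:
            raise ValueError("search fragment needs at least 3 located residues")
        if masks is None:
            masks = np.full(n, FULL_MASK, dtype=np.uint32)
        self.masks = np.asarray(masks, dtype=np.uint32).reshape(n)
        # triangular-matrix entries among defined slots: (row i, column j) pairs
        # addressing rdm[offset + i, j], with j = slot gap - 1
        rows, cols, dists = [], [], []
        idx = np.nonzero(self.defined)[0]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, k = idx[a], idx[b]
                rows.append(i)
                cols.append(k - i - 1)
                dists.append(float(np.linalg.norm(ca[k] - ca[i])))
        self.entry_rows = np.array(rows, dtype=np.intp)
        self.entry_cols = np.array(cols, dtype=np.intp)
        self.entry_dists = np.array(dists, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.ca)

    @property
    def tdm(self) -> np.ndarray:
        """Dense (n, n-1) triangular distance matrix with flag at null entries."""
        from .constants import FLAG

        n = len(self)
        out = np.full((n, max(n - 1, 1)), FLAG, dtype=np.float64)
        out[self.entry_rows, self.entry_cols] = self.entry_dists
        return out

    def inverted(self) -> "SearchFragment":
        """The point inversion of this query (distance matrix unchanged)."""
        return SearchFragment(-self.ca, self.masks.copy())


def make_search_fragment(slots, masks=None, width: int = 20) -> SearchFragment:
    """Build a :class:`SearchFragment` from Calpha positions with ``None`` gaps.

    ``slots`` is a sequence of length-3 coordinates or ``None`` placeholders
    (e.g. two stem residues, four nulls, two stem residues for a 4-residue
    loop).  Fragments longer than ``width + 1`` cannot be scored against a
    database of that window width and are rejected.
    """
    ca = np.array(
        [[np.nan] * 3 if s is None else np.asarray(s, dtype=float) for s in slots],
        dtype=float,
    )
    if len(ca) > width + 1:
        raise ValueError(f"search fragment longer than window limit {width + 1}")
    return SearchFragment(ca, masks)


def mask_pass(db: FragmentDatabase, sf: SearchFragment, offset: int) -> bool:
    """True iff every slot's mask admits the database residue type at `offset`."""
    window = db.types[offset : offset + len(sf)]
    bits = (sf.masks >> window.astype(np.uint32)) & 1
    return bool(bits.all())


def _admissible_offsets(db: FragmentDatabase, sf: SearchFragment) -> np.ndarray:
    """Offsets whose window is continuous in db and passes every slot mask."""
    n, length = len(db), len(sf)
    if length > db.width + 1:
        raise ValueError(
            f"search fragment of {length} residues exceeds database window "
            f"limit {db.width + 1}"
        )
    n_off = n - length + 1
    if n_off <= 0:
        return np.empty(0, dtype=np.intp)
    ok = db.frag_id[: n_off] == db.frag_id[length - 1 :]
    if not np.all(sf.masks == FULL_MASK):
        shifts = db.types.astype(np.uint32)
        for i in range(length):
            ok = ok & (((sf.masks[i] >> shifts[i : i + n_off]) & 1).astype(bool))
    return np.nonzero(ok)[0]


def prescreen(
    db: FragmentDatabase,
    sf: SearchFragment,
    params: SearchParams = SearchParams(),
    early_exit: bool = True,
) -> list[tuple[int, float]]:
    """Distance-matrix pre-screen: best `n_prescreen` offsets by SSD, ascending.

    SSD at offset r sums, over the query's defined distance-matrix entries,
    the squared difference between the query distance and the database's
    running-distance-matrix entry in the corresponding position.  Offsets whose
    window spans a chain break (flag entries) are rejected outright, as are
    offsets failing a residue-type mask.  Ties order by lower offset.

    With ``early_exit`` the per-offset sum stops as soon as it exceeds the
    current worst retained score (a bounded max-heap maintains that threshold);
    the result is identical to the full computation, term-for-term.
    """
    offsets = _admissible_offsets(db, sf)
    if len(offsets) == 0:
        return []
    k = min(params.n_prescreen, len(offsets))
    er, ec, ed = sf.entry_rows, sf.entry_cols, sf.entry_dists
    if not early_exit:
        # accumulate entry-by-entry, in the same order as the early-exit loop,
        # so the two paths produce bit-identical sums
        ssd = np.zeros(len(offsets), dtype=np.float64)
        for e in range(len(er)):
            d = db.rdm[offsets + er[e], ec[e]] - ed[e]
            ssd += d * d
        order = np.lexsort((offsets, ssd))[:k]
        return [(int(offsets[i]), float(ssd[i])) for i in order]
    # heap of (-ssd, -offset): root is the worst retained candidate
    heap: list[tuple[float, int]] = []
    rdm = db.rdm
    n_entries = len(er)
    for off in offsets:
        threshold = -heap[0][0] if len(heap) == k else np.inf
        s = 0.0
        rejected = False
        for e in range(n_entries):
            d = rdm[off + er[e], ec[e]] - ed[e]
            s += d * d
            if s > threshold:
                rejected = True
                break
        if rejected or (len(heap) == k and s >= threshold):
            continue
        item = (-s, -int(off))
        if len(heap) < k:
            heapq.heappush(heap, item)
        else:
            heapq.heappushpop(heap, item)
    out = sorted((-s, -noff) for s, noff in heap)
    return [(off, s) for s, off in out]


def rescore(
    db: FragmentDatabase,
    sf: SearchFragment,
    candidates,
    params: SearchParams = SearchParams(),
) -> list[Match]:
    """Superposition re-scoring of pre-screen candidates, sorted by Calpha RMSD.

    Each candidate window's Calphas (at the query's non-null slot positions)
    are superposed onto the query by proper-rotation least squares; mirror-image
    hits, which the distance-matrix pre-screen cannot reject, acquire a large
    RMSD here.  Ties order by lower SSD then lower offset; matches above
    ``rmsd_max`` are dropped and the best ``n_return`` kept.
    """
    candidates = list(candidates)
    if not candidates:
        return []
    idx = np.nonzero(sf.defined)[0]
    fixed = sf.ca[idx]
    offs = np.array([c[0] for c in candidates], dtype=np.intp)
    ssds = np.array([c[1] for c in candidates], dtype=np.float64)
    moving = db.ca[offs[:, None] + idx[None, :]]
    rots, trans, rmsds = superpose_many(moving, fixed)
    moved = np.einsum("bij,bkj->bki", rots, moving) + trans[:, None, :]
    max_devs = np.linalg.norm(moved - fixed[None], axis=2).max(axis=1)
    order = np.lexsort((offs, ssds, rmsds))
    out: list[Match] = []
    for i in order:
        if params.rmsd_max is not None and rmsds[i] > params.rmsd_max:
            continue
        out.append(
            Match(
                offset=int(offs[i]),
                ssd=float(ssds[i]),
                transform=RigidTransform(rots[i], trans[i]),
                rmsd=float(rmsds[i]),
                max_dev=float(max_devs[i]),
            )
        )
        if len(out) == params.n_return:
            break
    return out


def search(
    db: FragmentDatabase,
    sf: SearchFragment,
    params: SearchParams = SearchParams(),
    early_exit: bool = True,
) -> list[Match]:
    """Full two-stage search: pre-screen (with masks) then superposition re-score."""
    cands = prescreen(db, sf, params, early_exit=early_exit)
    return rescore(db, sf, cands, params)


def coverage_experiment(
    db: FragmentDatabase,
    length: int,
    metric: str = "rmsd",
    params: SearchParams | None = None,
) -> np.ndarray:
    """Second-best self-match statistics over every length-`length` fragment.

    Every continuous window of the database is used in turn as a query; the
    best match is always the window itself and is discarded, and the chosen
    statistic of the second-best match (Calpha RMSD, or the displacement of the
    worst-matching Calpha) is recorded.  Returns the sorted vector of
    statistics — the tail-plot data answering "how well can each fragment be
    represented by some *other* fragment of the database".
    """
    if metric not in ("rmsd", "max_dev"):
        raise ValueError("metric must be 'rmsd' or 'max_dev'")
    if params is None:
        params = SearchParams(n_prescreen=max(500, len(db)), n_return=2)
    stats: list[float] = []
    for start, stop in db.fragment_ranges():
        for off in range(start, stop - length + 1):
            sf = SearchFragment(db.ca[off : off + length].copy())
            cands = prescreen(db, sf, params, early_exit=False)
            cands = [c for c in cands if c[0] != off]
            matches = rescore(db, sf, cands, SearchParams(
                n_prescreen=params.n_prescreen, n_return=1,
            ))
            if matches:
                m = matches[0]
                stats.append(m.rmsd if metric == "rmsd" else m.max_dev)
    return np.sort(np.array(stats, dtype=float))
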
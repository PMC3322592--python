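"""Build, store and index the database of real protein fragments.

The database is a single flat list of amino-acid records (residue type + N,
Calpha, C coordinates), with chain-break structure, plus a precomputed
``n_db x W`` "running distance matrix": row ``r`` holds the distances from
Calpha(r) to the following W Calphas, so the internal distances of any
fragment of up to W+1 residues can be read off in O(1) without recomputation.
Entries spanning a chain break hold a negative flag value.
"""

from __future__ import annotations

import io
import logging
import struct
from dataclasses import dataclass

import numpy as np

from .constants import (
    AA_ALPHABET,
    AA_INDEX,
    CONTINUITY_CN_MAX,
    DEFAULT_B_MAX,
    DEFAULT_WIDTH,
    FLAG,
    MODIFIED_PARENT,
    THREE_TO_ONE,
)

logger = logging.getLogger(__name__)

_MAGIC = b"FRGWDB"
_VERSION = 1


class DatabaseFormatError(ValueError):
    """Raised on magic/version mismatch or truncated database files."""


@dataclass(frozen=True)
class ResidueRecord:
    """One database amino acid: type code plus N/Calpha/C coordinates (A).

    ``source_tag`` is an opaque provenance string (structure id + chain +
    author seqnum) carried through to rebuilt atoms.
    """

    res_type: str
    n_xyz: np.ndarray
    ca_xyz: np.ndarray
    c_xyz: np.ndarray
    source_tag: str = ""

    @property
    def type_index(self) -> int:
        return AA_INDEX[self.res_type]


class FragmentDatabase:
    """Flat record store with break structure and running distance matrix.

    Internally array-backed for speed: ``types`` (n,) int8 indices into the
    20-letter alphabet, ``coords`` (n, 3, 3) stacked N/Calpha/C positions,
    ``break_after`` the set of indices ending a continuous fragment (the last
    record is always a break), ``rdm`` the (n, width) running distance matrix.
    """

    def __init__(self, types, coords, break_after, tags, width=DEFAULT_WIDTH, rdm=None):
        self.types = np.asarray(types, dtype=np.int8)
        self.coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3, 3)
        if len(self.types) != len(self.coords):
            raise ValueError("types/coords length mismatch")
        if len(self.types) and (self.types.min() < 0 or self.types.max() > 19):
            raise ValueError("residue type index out of range 0-19")
        self.break_after = frozenset(int(i) for i in break_after)
        if len(self.types) and (len(self.types) - 1) not in self.break_after:
            raise ValueError("last record must terminate a fragment")
        self.tags = list(tags)
        if len(self.tags) != len(self.types):
            raise ValueError("tags length mismatch")
        self.width = int(width)
        if self.width < 1:
            raise ValueError("width must be >= 1")
        self.rdm = (
            np.asarray(rdm, dtype=np.float64)
            if rdm is not None
            else running_distance_matrix(self)
        )
        if self.rdm.shape != (len(self.types), self.width):
            raise ValueError("rdm shape mismatch")
        # fragment id per record: equal ids <=> same continuous fragment
        fid = np.zeros(len(self.types), dtype=np.int32)
        nxt = 0
        for i in range(len(self.types)):
            fid[i] = nxt
            if i in self.break_after:
                nxt += 1
        self.frag_id = fid

    def __len__(self) -> int:
        return len(self.types)

    @property
    def n_fragments(self) -> int:
        return len(self.break_after)

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, 1, :]

    def record(self, i: int) -> ResidueRecord:
        return ResidueRecord(
            res_type=AA_ALPHABET[self.types[i]],
            n_xyz=self.coords[i, 0].copy(),
            ca_xyz=self.coords[i, 1].copy(),
            c_xyz=self.coords[i, 2].copy(),
            source_tag=self.tags[i],
        )

    @property
    def records(self) -> list[ResidueRecord]:
        return [self.record(i) for i in range(len(self))]

    def fragment_ranges(self) -> list[tuple[int, int]]:
        """Half-open (start, stop) index ranges of the continuous fragments."""
        ranges = []
        start = 0
        for i in sorted(self.break_after):
            ranges.append((start, i + 1))
            start = i + 1
        return ranges

    def is_continuous(self, offset: int, length: int) -> bool:
        if offset < 0 or offset + length > len(self):
            return False
        return self.frag_id[offset] == self.frag_id[offset + length - 1]

    # --- serialization ----------------------------------------------------------

    def save(self, path) -> None:
        """Write the versioned binary database file (bit-exact round trip)."""
        n = len(self)
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<III", _VERSION, n, self.width))
            fh.write(self.types.tobytes())
            breaks = np.array(sorted(self.break_after), dtype=np.uint32)
            fh.write(struct.pack("<I", len(breaks)))
            fh.write(breaks.tobytes())
            fh.write(self.coords.tobytes())
            fh.write(self.rdm.tobytes())
            blob = b"".join(
                struct.pack("<H", len(t.encode())) + t.encode() for t in self.tags
            )
            fh.write(struct.pack("<I", len(blob)))
            fh.write(blob)

    @classmethod
    def load(cls, path) -> "FragmentDatabase":
        with open(path, "rb") as fh:
            data = fh.read()
        buf = io.BytesIO(data)

        def take(k: int) -> bytes:
            b = buf.read(k)
            if len(b) != k:
                raise DatabaseFormatError("truncated database file")
            return b

        if take(len(_MAGIC)) != _MAGIC:
            raise DatabaseFormatError("not a fragment database file (bad magic)")
        version, n, width = struct.unpack("<III", take(12))
        if version != _VERSION:
            raise DatabaseFormatError(f"unsupported database version {version}")
        types = np.frombuffer(take(n), dtype=np.int8)
        (n_breaks,) = struct.unpack("<I", take(4))
        breaks = np.frombuffer(take(4 * n_breaks), dtype=np.uint32)
        coords = np.frombuffer(take(8 * n * 9), dtype=np.float64).reshape(n, 3, 3)
        rdm = np.frombuffer(take(8 * n * width), dtype=np.float64).reshape(n, width)
        (blob_len,) = struct.unpack("<I", take(4))
        blob = io.BytesIO(take(blob_len))
        tags = []
        for _ in range(n):
            raw = blob.read(2)
            if len(raw) != 2:
                raise DatabaseFormatError("truncated tag block")
            (tlen,) = struct.unpack("<H", raw)
            tags.append(blob.read(tlen).decode())
        return cls(types.copy(), coords.copy(), set(breaks.tolist()), tags,
                   width=width, rdm=rdm.copy())


def running_distance_matrix(db: FragmentDatabase, width: int | None = None) -> np.ndarray:
    """Recompute the (n, width) running distance matrix from records + breaks.

    Entry (r, j) is |Calpha(r) - Calpha(r+j+1)| when both residues lie in the
    same continuous fragment, else the flag value.  The final rows of each
    fragment are progressively all-flag (no following residues).
    """
    w = db.width if width is None else int(width)
    if w < 1:
        raise ValueError("width must be >= 1")
    n = len(db)
    rdm = np.full((n, w), FLAG, dtype=np.float64)
    if n == 0:
        return rdm
    ca = db.coords[:, 1, :]
    fid = getattr(db, "frag_id", None)
    if fid is None:
        fid = np.zeros(n, dtype=np.int32)
        nxt = 0
        for i in range(n):
            fid[i] = nxt
            if i in db.break_after:
                nxt += 1
    for j in range(1, w + 1):
        if j >= n:
            break
        d = np.linalg.norm(ca[j:] - ca[:-j], axis=1)
        ok = fid[j:] == fid[:-j]
        rdm[: n - j, j - 1] = np.where(ok, d, FLAG)
    return rdm


def _residue_one_letter(name: str) -> str | None:
    name = name.upper()
    name = MODIFIED_PARENT.get(name, name)
    return THREE_TO_ONE.get(name)


def build_database(
    chains,
    b_max: float = DEFAULT_B_MAX,
    width: int = DEFAULT_WIDTH,
) -> FragmentDatabase:
    """Build a database from well-refined chains (:class:`~.model.ChainModel`).

    Admission rules: a residue needs all of N, Calpha, C; a Calpha B-factor of at
    most ``b_max``; a standard residue type (modified residues are mapped to the
    parent type); and N-Calpha / Calpha-C bond lengths in (1.0, 2.0) A.
    Continuity breaks are inserted at chain ends, at every excluded residue and
    wherever the peptide C(i)-N(i+1) distance exceeds the continuity threshold.
    """
    if b_max <= 0:
        raise ValueError("b_max must be positive")
    chains = list(chains)
    if not chains:
        raise ValueError("no input chains")
    types: list[int] = []
    coords: list[np.ndarray] = []
    tags: list[str] = []
    breaks: set[int] = set()
    for chain in chains:
        prev_admitted = False
        has_ca = any("CA" in r.atoms for r in chain.residues)
        if not has_ca:
            logger.warning("chain %s has no Calpha atoms; skipped", chain.chain_id)
            continue
        for res in chain.residues:
            one = res.res_type if res.res_type in AA_INDEX else _residue_one_letter(
                res.res_type
            )
            admit = (
                one is not None
                and all(a in res.atoms for a in ("N", "CA", "C"))
                and res.bfac <= b_max
            )
            if admit:
                n_xyz = np.asarray(res.atoms["N"], dtype=float)
                ca = np.asarray(res.atoms["CA"], dtype=float)
                c_xyz = np.asarray(res.atoms["C"], dtype=float)
                d_nca = np.linalg.norm(ca - n_xyz)
                d_cac = np.linalg.norm(c_xyz - ca)
                admit = 1.0 < d_nca < 2.0 and 1.0 < d_cac < 2.0
            if not admit:
                if prev_admitted:
                    breaks.add(len(types) - 1)
                prev_admitted = False
                continue
            if prev_admitted:
                # break on a stretched/broken peptide bond
                d_cn = np.linalg.norm(n_xyz - coords[-1][2])
                if d_cn > CONTINUITY_CN_MAX:
                    breaks.add(len(types) - 1)
            types.append(AA_INDEX[one])
            coords.append(np.stack([n_xyz, ca, c_xyz]))
            tags.append(f"{chain.chain_id}/{res.seqnum}{res.inscode}")
            prev_admitted = True
        if types:
            breaks.add(len(types) - 1)
    if not types:
        raise ValueError("no residues passed the admission filters")
    return FragmentDatabase(
        np.array(types, dtype=np.int8),
        np.stack(coords),
        breaks,
        tags,
        width=width,
    )
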
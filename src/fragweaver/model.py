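"""In-memory protein model containers shared across the package.

A :class:`ChainModel` is an ordered list of residues with mainchain atoms; it is
both the input to database building (well-refined chains) and the unit of the
tidying problem (a built fragment, optionally docked to a target sequence).  A
:class:`WorkModel` bundles fragments with target sequences and crystal metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import RigidTransform

#: Mainchain atom names handled throughout.
MAINCHAIN_ATOMS = ("N", "CA", "C", "O", "CB")


@dataclass
class Residue:
    """One residue: author numbering, one-letter type and mainchain atoms.

    ``atoms`` maps atom names (N, CA, C, O, CB) to length-3 float arrays.
    ``res_type`` is a one-letter code, or 'X' for unknown. ``provenance`` records
    where rebuilt coordinates came from (database source tags), empty for input
    atoms.
    """

    seqnum: int
    res_type: str = "X"
    inscode: str = ""
    atoms: dict = field(default_factory=dict)
    bfac: float = 20.0
    provenance: str = ""

    def copy(self) -> "Residue":
        return Residue(
            seqnum=self.seqnum,
            res_type=self.res_type,
            inscode=self.inscode,
            atoms={k: np.array(v, dtype=float) for k, v in self.atoms.items()},
            bfac=self.bfac,
            provenance=self.provenance,
        )

    @property
    def id(self) -> tuple[int, str]:
        return (self.seqnum, self.inscode)


@dataclass
class ChainModel:
    """An ordered run of residues; a built fragment or an assembled chain.

    ``sequence_id`` names the target sequence the fragment is docked to (its
    residues then carry meaningful sequence numbers); ``None`` for undocked
    fragments.
    """

    residues: list = field(default_factory=list)
    chain_id: str = "A"
    sequence_id: str | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def copy(self) -> "ChainModel":
        return ChainModel(
            residues=[r.copy() for r in self.residues],
            chain_id=self.chain_id,
            sequence_id=self.sequence_id,
        )

    def ca_array(self) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.residues], dtype=float)

    def seqnums(self) -> list[int]:
        return [r.seqnum for r in self.residues]

    def transform(self, t: RigidTransform) -> "ChainModel":
        out = self.copy()
        for res in out.residues:
            for name, xyz in res.atoms.items():
                res.atoms[name] = t.apply(xyz)
        return out

    def slice(self, start: int, stop: int) -> "ChainModel":
        return ChainModel(
            residues=[r.copy() for r in self.residues[start:stop]],
            chain_id=self.chain_id,
            sequence_id=self.sequence_id,
        )

    def renumber(self, first: int) -> "ChainModel":
        out = self.copy()
        for i, res in enumerate(out.residues):
            res.seqnum = first + i
            res.inscode = ""
        return out

    def check_unique_ids(self) -> None:
        ids = [r.id for r in self.residues]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate (seqnum, inscode) in chain {self.chain_id}")


@dataclass
class WorkModel:
    """Tidying input/output: fragments + target sequences + crystal metadata.

    ``cell`` is (a, b, c, alpha, beta, gamma) in angstroms/degrees; ``spacegroup``
    a Hermann-Mauguin symbol.  Either may be ``None``, in which case symmetry-aware
    scoring falls back to the identity transform only.
    """

    fragments: list = field(default_factory=list)
    sequences: list = field(default_factory=list)
    cell: tuple | None = None
    spacegroup: str | None = None

    def validate(self) -> None:
        seq_ids = {sid for sid, _ in self.sequences}
        if len(seq_ids) != len(self.sequences):
            raise ValueError("duplicate sequence ids")
        for frag in self.fragments:
            if frag.sequence_id is not None and frag.sequence_id not in seq_ids:
                raise ValueError(
                    f"fragment docked to unknown sequence {frag.sequence_id!r}"
                )
        if self.cell is not None and any(v <= 0 for v in self.cell[:3]):
            raise ValueError("cell lengths must be positive")
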
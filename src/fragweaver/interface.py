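"""File I/O: PDB/mmCIF models (through gemmi), FASTA sequences, run configuration.

Residue numbering follows author numbering (1-based, as deposited); all
internal indices are 0-based — the conversion happens only in this layer.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import gemmi
import numpy as np

from .constants import AA_ALPHABET, DEFAULT_B_MAX, DEFAULT_WIDTH, ONE_TO_THREE, THREE_TO_ONE
from .model import MAINCHAIN_ATOMS, ChainModel, Residue, WorkModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables with their defaults; echoed into every report.

    Defaults reproduce the published constants: B-factor ceiling 40 A^2,
    window width 20, bridging cap 6 residues, 5 A contact radius, +1/-2
    allocation scores, overlap strictly greater than 12 residues and a
    best-half conformation RMSD below 1 A.
    """

    b_max: float = DEFAULT_B_MAX
    width: int = DEFAULT_WIDTH
    n_prescreen: int = 500
    n_return: int = 50
    rmsd_max: float | None = None
    stem_rmsd_max: float = 0.75
    bridge_cap: int = 6
    contact_radius: float = 5.0
    overlap_min_exclusive: int = 12
    overlap_rmsd_max: float = 1.0
    shell: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = open(path).read()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        cfg = cls()
        for key, value in (data or {}).items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, value)
        return cfg


def read_sequences(path) -> list[tuple[str, str]]:
    """Read target sequences from FASTA; ids must be unique, letters standard.

    Lowercase letters are uppercased; ambiguity codes (B, Z, J, O, U, X) are
    rejected because the 20-bit residue-type machinery has no bit for them.
    """
    out: list[tuple[str, str]] = []
    seen = set()
    name = None
    chunks: list[str] = []

    def flush():
        if name is None:
            return
        seq = "".join(chunks).upper()
        bad = sorted(set(seq) - set(AA_ALPHABET))
        if bad:
            raise ValueError(
                f"sequence {name!r} contains unsupported letters {bad}"
            )
        if not seq:
            raise ValueError(f"empty sequence {name!r}")
        out.append((name, seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                if name in seen:
                    raise ValueError(f"duplicate sequence id {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ValueError("FASTA data before first header")
                chunks.append(line)
    flush()
    if not out:
        raise ValueError("no sequences in FASTA file")
    return out


def _structure_to_work(st: gemmi.Structure) -> WorkModel:
    st.setup_entities()
    cell = st.cell
    has_cell = cell.a > 1.0 and not (
        cell.a == cell.b == cell.c == 1.0
    )
    spacegroup = st.spacegroup_hm if st.spacegroup_hm else None
    if not has_cell or spacegroup is None:
        warnings.warn(
            "no usable cell/space group; symmetry-aware scoring limited to identity"
        )
        cell_tuple = None
        spacegroup = None
    else:
        cell_tuple = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    fragments: list[ChainModel] = []
    model = st[0]
    for chain in model:
        current: list[Residue] = []
        prev = None
        for res in chain:
            one = THREE_TO_ONE.get(res.name.upper(), "X")
            atoms = {}
            bfac = 20.0
            for atom in res:
                if atom.name in MAINCHAIN_ATOMS and (atom.altloc in ("", "A", "\x00")):
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z]
                    )
                    if atom.name == "CA":
                        bfac = atom.b_iso
            if "CA" not in atoms:
                continue
            r = Residue(
                seqnum=res.seqid.num,
                res_type=one,
                inscode=(res.seqid.icode or "").strip(),
                atoms=atoms,
                bfac=bfac,
            )
            broke = prev is not None and not (
                r.seqnum == prev.seqnum + 1
                or (r.seqnum == prev.seqnum and r.inscode)
            )
            if broke and prev is not None and "C" in prev.atoms and "N" in r.atoms:
                # numbering gap but covalently continuous counts as continuous
                broke = np.linalg.norm(prev.atoms["C"] - r.atoms["N"]) > 2.5
            if broke and current:
                fragments.append(
                    ChainModel(residues=current, chain_id=chain.name)
                )
                current = []
            current.append(r)
            prev = r
        if current:
            fragments.append(ChainModel(residues=current, chain_id=chain.name))
    return WorkModel(fragments=fragments, sequences=[], cell=cell_tuple,
                     spacegroup=spacegroup)


def read_model(path, sequences: list[tuple[str, str]] | None = None) -> WorkModel:
    """Read a PDB or mmCIF model into a WorkModel.

    Fragments are the contiguous runs within each chain (split at numbering
    gaps that are also broken covalently).  If target ``sequences`` are given,
    each fragment is docked to the sequence whose letters match the fragment's
    residue types at its sequence numbers exactly (plain coordinate files
    cannot carry docking assignments, so they are reconstructed this way).
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    work = _structure_to_work(st)
    if sequences:
        work.sequences = list(sequences)
        for frag in work.fragments:
            for seq_id, seq in sequences:
                if _docks(frag, seq):
                    frag.sequence_id = seq_id
                    break
        work.validate()
    return work


def _docks(frag: ChainModel, seq: str) -> bool:
    for r in frag.residues:
        idx = r.seqnum - 1
        if idx < 0 or idx >= len(seq):
            return False
        if r.res_type != "X" and seq[idx] != r.res_type:
            return False
    return True


def write_model(work: WorkModel, path) -> None:
    """Write a WorkModel as PDB or mmCIF (by extension)."""
    st = gemmi.Structure()
    st.name = "fragweaver"
    if work.cell is not None:
        st.cell = gemmi.UnitCell(*work.cell)
    if work.spacegroup is not None:
        st.spacegroup_hm = work.spacegroup
    model = gemmi.Model("1")
    used = {}
    for frag in work.fragments:
        cid = frag.chain_id or "A"
        chain = used.get(cid)
        if chain is None:
            chain = gemmi.Chain(cid)
            used[cid] = chain
        for r in frag.residues:
            res = gemmi.Residue()
            res.name = ONE_TO_THREE.get(r.res_type, "UNK")
            res.seqid = gemmi.SeqId(r.seqnum, r.inscode or " ")
            for name in MAINCHAIN_ATOMS:
                if name not in r.atoms:
                    continue
                atom = gemmi.Atom()
                atom.name = name
                x, y, z = (float(v) for v in r.atoms[name])
                atom.pos = gemmi.Position(x, y, z)
                atom.element = gemmi.Element("N" if name == "N" else (
                    "O" if name == "O" else "C"))
                atom.b_iso = r.bfac
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
    for chain in used.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if str(path).endswith(".cif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
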
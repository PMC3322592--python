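"""Deterministic synthetic-structure and scattered-model generators.

Every generator is a pure function of its arguments (including the seed), so
the whole package is testable without downloading any structure set.  Chains
are built by internal-coordinate chain extension (NeRF) with ideal bond
lengths and angles, driven by per-residue (phi, psi) torsions: ideal helices
and strands, and "varied" chains whose torsions are drawn from the allowed
Ramachandran regions — a stand-in for the conformational diversity of a real
well-refined structure set.

``scatter_model`` emulates a fragmentary autobuilt model: a ground-truth
molecule (or NCS copies of it) is cut into fragments, junction residues are
deleted, fragments are displaced by crystallographic symmetry operators and
perturbed with Gaussian coordinate noise.  The ground-truth mapping from each
fragment back to its source molecule is returned alongside, which is what the
tidying tests score against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ANGLE_C_N_CA,
    ANGLE_CA_C_N,
    ANGLE_N_CA_C,
    BOND_C_N,
    BOND_CA_C,
    BOND_N_CA,
    OMEGA_TRANS,
)
from .fragdb import FragmentDatabase, build_database
from .geometry import RigidTransform, place_oxygen
from .model import ChainModel, Residue, WorkModel
from .tidy import candidate_transforms

#: Allowed Ramachandran regions sampled by the varied-chain generator:
#: (phi centre, psi centre, half-width) in degrees.
RAMACHANDRAN_REGIONS = (
    (-63.0, -43.0, 12.0),   # alpha helix
    (-120.0, 130.0, 20.0),  # beta strand
    (-75.0, 150.0, 15.0),   # polyproline II
    (57.0, 40.0, 8.0),      # left-handed helix (rare)
)
RAMACHANDRAN_WEIGHTS = (0.45, 0.30, 0.18, 0.07)


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF: position of atom d given chain a-b-c, bond |cd|, angle bcd, torsion abcd."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    d2 = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    rot = np.stack([bc, m, n], axis=1)
    return c + rot @ d2


def chain_from_torsions(
    torsions,
    res_types: str | None = None,
    first_seqnum: int = 1,
    chain_id: str = "A",
) -> ChainModel:
    """Build an ideal-geometry mainchain from per-residue (phi, psi) pairs.

    ``torsions`` is a length-n sequence of (phi, psi) in degrees (phi of the
    first and psi of the last residue are not used).  All bond lengths and
    angles take their ideal values; omega is trans.  O atoms are placed from
    the peptide planes; the last residue gets no O (no following N).
    """
    torsions = list(torsions)
    n = len(torsions)
    if n < 2:
        raise ValueError("need at least 2 residues")
    if res_types is None:
        res_types = "A" * n
    # seed the first residue in a canonical frame
    coords = []  # flat list of (N, CA, C) triples
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append((n0, ca0, c0))
    for i in range(1, n):
        n_prev, ca_prev, c_prev = coords[-1]
        psi_prev = torsions[i - 1][1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = _place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        phi_i = torsions[i][0]
        c_i = _place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        coords.append((n_i, ca_i, c_i))
    residues = []
    for i, (nx, cax, cx) in enumerate(coords):
        residues.append(
            Residue(
                seqnum=first_seqnum + i,
                res_type=res_types[i],
                atoms={"N": nx, "CA": cax, "C": cx},
            )
        )
    for i in range(n - 1):
        residues[i].atoms["O"] = place_oxygen(
            residues[i].atoms["CA"], residues[i].atoms["C"],
            residues[i + 1].atoms["N"],
        )
    return ChainModel(residues=residues, chain_id=chain_id)


def make_ideal_helix(n: int, phi: float = -57.0, psi: float = -47.0,
                     **kw) -> ChainModel:
    """Ideal alpha helix of `n` residues (default classic -57/-47 torsions)."""
    if n < 2:
        raise ValueError("helix needs at least 2 residues")
    return chain_from_torsions([(phi, psi)] * n, **kw)


def make_ideal_strand(n: int, phi: float = -120.0, psi: float = 130.0,
                      **kw) -> ChainModel:
    """Ideal extended beta strand of `n` residues."""
    if n < 2:
        raise ValueError("strand needs at least 2 residues")
    return chain_from_torsions([(phi, psi)] * n, **kw)


def make_varied_chain(n: int, seed: int = 0, **kw) -> ChainModel:
    """A chain with torsions drawn from the allowed Ramachandran regions.

    Runs of 3-8 residues share a region (secondary-structure-like persistence)
    so the chain contains recognisable helical and extended stretches as well
    as diverse turns.  Residue types are drawn uniformly from the 20-letter
    alphabet.
    """
    if n < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    torsions = []
    while len(torsions) < n:
        region = RAMACHANDRAN_REGIONS[
            rng.choice(len(RAMACHANDRAN_REGIONS), p=RAMACHANDRAN_WEIGHTS)
        ]
        run = int(rng.integers(3, 9))
        for _ in range(min(run, n - len(torsions))):
            phi = region[0] + rng.uniform(-region[2], region[2])
            psi = region[1] + rng.uniform(-region[2], region[2])
            torsions.append((phi, psi))
    from .constants import AA_ALPHABET

    types = "".join(rng.choice(list(AA_ALPHABET)) for _ in range(n))
    return chain_from_torsions(torsions, res_types=types, **kw)


def make_helix_hairpin(n_helix: int = 22, seed: int = 0, **kw) -> ChainModel:
    """A compact two-helix hairpin: helix, tight turn, antiparallel helix.

    The turn torsions are fixed values chosen to fold the second helix back
    against the first, giving the inter-fragment contacts that the tidying
    score relies on.  Compactness is asserted by the fixture tests.
    """
    turn = [(88.6, -113.4), (2.1, 151.4)]
    torsions = (
        [(-57.0, -47.0)] * n_helix + turn + [(-57.0, -47.0)] * n_helix
    )
    if seed:
        rng = np.random.default_rng(seed)
        torsions = [(p + rng.uniform(-3, 3), s + rng.uniform(-3, 3))
                    for p, s in torsions]
    return chain_from_torsions(torsions, **kw)


def make_test_database(motifs, b_max: float = 40.0, width: int = 20) -> FragmentDatabase:
    """Concatenate motif chains into a database (breaks between motifs)."""
    motifs = list(motifs)
    if not motifs:
        raise ValueError("no motifs")
    chains = []
    for i, m in enumerate(motifs):
        c = m.copy()
        c.chain_id = f"M{i}"
        chains.append(c)
    return build_database(chains, b_max=b_max, width=width)


@dataclass
class ScatterSpec:
    """Recipe for a synthetic fragmentary autobuilt model.

    ``molecules``: list of (sequence_id, ChainModel) ground-truth molecules —
    repeat a sequence_id to model NCS copies.  Each molecule is cut into
    roughly ``n_fragments_per_molecule`` pieces; ``deletion_rate`` is the
    chance of deleting a residue at each junction (incompleteness),
    ``undock_rate`` the chance a fragment loses its sequence docking,
    ``noise_sigma`` the isotropic Gaussian coordinate noise (A), and each
    fragment is displaced by a random crystallographic symmetry operator of
    the given cell/space group.
    """

    molecules: list
    cell: tuple = (80.0, 60.0, 70.0, 90.0, 100.0, 90.0)
    spacegroup: str = "P 1 21 1"
    n_fragments_per_molecule: int | list = 3
    min_fragment_len: int = 6
    deletion_rate: float = 0.5
    max_deletion: int = 2
    undock_rate: float = 0.0
    noise_sigma: float = 0.1
    seed: int = 0
    #: lattice-translation shell for the *scattering* operators; kept at 0 so a
    #: tidy search with shell 1 can represent any composition S_a . S_b^-1
    shell: int = 0


def scatter_model(spec: ScatterSpec) -> tuple[WorkModel, dict]:
    """Cut, displace and perturb ground-truth molecules into a WorkModel.

    Returns the scattered model plus the ground truth: for every fragment, the
    index of its source molecule and the sequence numbers it carries.  With
    zero noise, one fragment per molecule and no deletions/undocking the output
    equals the source (identity transform is always a valid symmetry pick only
    when the rng says so; pass ``spacegroup='P 1'`` and ``shell=0`` for a
    strict identity round trip).
    """
    rng = np.random.default_rng(spec.seed)
    sym = candidate_transforms(spec.cell, spec.spacegroup, spec.shell)
    sequences: dict[str, str] = {}
    fragments: list[ChainModel] = []
    truth_entries = []
    for mol_idx, (seq_id, mol) in enumerate(spec.molecules):
        if seq_id not in sequences:
            sequences[seq_id] = "".join(
                r.res_type if r.res_type != "X" else "A" for r in mol.residues
            )
        n = len(mol)
        k = (
            spec.n_fragments_per_molecule[mol_idx]
            if isinstance(spec.n_fragments_per_molecule, (list, tuple))
            else spec.n_fragments_per_molecule
        )
        if k > n:
            raise ValueError("more fragments than residues")
        # choose cut points keeping every piece >= min_fragment_len
        for _attempt in range(200):
            cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False)) \
                if k > 1 else np.array([], dtype=int)
            bounds = [0, *cuts.tolist(), n]
            if all(b - a >= spec.min_fragment_len for a, b in zip(bounds, bounds[1:])):
                break
        else:
            raise ValueError("could not cut molecule with the given constraints")
        for a, b in zip(bounds, bounds[1:]):
            piece = mol.slice(a, b)
            # junction deletions: trim residues at the cut ends
            if a > 0 and rng.random() < spec.deletion_rate:
                piece = piece.slice(min(int(rng.integers(1, spec.max_deletion + 1)),
                                        len(piece) - spec.min_fragment_len + 1), len(piece))
            if b < n and rng.random() < spec.deletion_rate and len(piece) > spec.min_fragment_len:
                piece = piece.slice(0, len(piece) - 1)
            piece.sequence_id = seq_id
            piece.chain_id = "Z"
            if rng.random() < spec.undock_rate:
                piece.sequence_id = None
            t = sym[int(rng.integers(len(sym)))]
            placed = piece.transform(t)
            if spec.noise_sigma > 0:
                for res in placed.residues:
                    for name in res.atoms:
                        res.atoms[name] = res.atoms[name] + rng.normal(
                            0.0, spec.noise_sigma, 3
                        )
            fragments.append(placed)
            truth_entries.append({
                "molecule": mol_idx,
                "sequence": seq_id,
                "seqnums": piece.seqnums(),
            })
    order = rng.permutation(len(fragments))
    fragments = [fragments[i] for i in order]
    truth_entries = [truth_entries[i] for i in order]
    work = WorkModel(
        fragments=fragments,
        sequences=sorted(sequences.items()),
        cell=spec.cell,
        spacegroup=spec.spacegroup,
    )
    truth = {"fragments": truth_entries,
             "n_molecules": len(spec.molecules)}
    return work, truth


def hetero_dimer_ncs_preset(seed: int = 1, completeness: str = "high") -> ScatterSpec:
    """Two sequences, two NCS copies each, scattered into ~14 fragments.

    Molecule A is a 48-residue helix hairpin, molecule B a 34-residue hairpin
    with shorter helices; the second NCS copy of each is a rotated/translated
    duplicate placed elsewhere in the asymmetric unit.  ``completeness`` picks
    the junction-deletion pressure ("high" ~ near-complete chains, "low" ~
    around 60-80%).
    """
    mol_a = make_helix_hairpin(n_helix=22)
    mol_b = make_helix_hairpin(n_helix=15)
    # placements keep every pair of molecules (and their symmetry images in the
    # default cell) more than ~10 A apart, so ground-truth membership is
    # unambiguous; real crystals pack tighter — see the methods note
    rot0 = RigidTransform(np.eye(3), np.array([5.0, 5.0, 5.0]))
    rot1 = RigidTransform(
        np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
        np.array([14.3, 37.4, 8.8]),
    )
    rot2 = RigidTransform(
        np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]]),
        np.array([12.8, 43.0, 40.9]),
    )
    rot3 = RigidTransform(
        np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]]),
        np.array([28.5, 15.1, 44.4]),
    )
    molecules = [
        ("seqA", mol_a.transform(rot0)),
        ("seqA", mol_a.transform(rot1)),
        ("seqB", mol_b.transform(rot2)),
        ("seqB", mol_b.transform(rot3)),
    ]
    deletion_rate = 0.35 if completeness == "high" else 0.9
    max_deletion = 1 if completeness == "high" else 2
    return ScatterSpec(
        molecules=molecules,
        n_fragments_per_molecule=[3, 3, 2, 2],
        min_fragment_len=13,
        deletion_rate=deletion_rate,
        max_deletion=max_deletion,
        noise_sigma=0.1,
        seed=seed,
    )
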
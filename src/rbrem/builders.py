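"""Generators for every input the simulator needs in tests and demos.

* zigzag carbon nanotubes of chirality (n, 0);
* the telomeric duplex sequence [5′-GGG(TTAGGG)ₙ]:[3′-CCC(ATTCCC)ₙ];
* an idealized hemiprotonated i-motif hydrogen-bond fixture with
  canonical C:C⁺ Hoogsteen pairs (three donor–acceptor contacts each);
* small toy rigid-body systems with brute-force-checkable minima.

The i-motif fixture is a geometric test object, not a physically folded
structure: only the hydrogen-bond-bearing atoms carry meaningful
relative geometry, which is all the hydrogen-bond counter and the
RMSD collective variable need.  Nanotube tips are left bare — any
functional groups enter as ordinary atoms of a user-supplied PDB body.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import SystemState, make_system
from .structures import Structure, select_atoms

__all__ = [
    "Chirality",
    "ToySystemSpec",
    "GRAPHENE_LATTICE",
    "CC_BOND",
    "build_nanotube",
    "nanotube_unit_cell_length",
    "build_ig_sequence",
    "build_imotif_fixture",
    "imotif_donors_acceptors",
    "build_toy_system",
]

#: Graphene lattice constant a, Å (standard value).
GRAPHENE_LATTICE = 2.46
#: C–C bond length a/√3, Å.
CC_BOND = GRAPHENE_LATTICE / math.sqrt(3.0)


@dataclass(frozen=True)
class Chirality:
    """Nanotube roll-up vector (n, m); only zigzag (m = 0) is generated."""

    n: int
    m: int = 0

    def __post_init__(self) -> None:
        if not (self.n >= self.m >= 0) or self.n <= 0:
            raise ValueError(f"invalid chirality ({self.n},{self.m}): need n >= m >= 0, n > 0")

    @property
    def radius(self) -> float:
        """Cylinder radius a·n/(2π) for a zigzag tube, Å."""
        return GRAPHENE_LATTICE * self.n / (2.0 * math.pi)


def _zigzag_geometry(n: int) -> tuple[float, float, float]:
    """(radius, diagonal rise δ, unit-cell length) of an (n,0) tube.

    The diagonal rise is chosen so that every C–C bond measures exactly
    a/√3 *after* rolling (the flat-sheet value shrinks chords slightly);
    the axial period is then 2·(δ + d).
    """
    radius = GRAPHENE_LATTICE * n / (2.0 * math.pi)
    chord = 2.0 * radius * math.sin(math.pi / (2.0 * n))
    delta = math.sqrt(CC_BOND ** 2 - chord ** 2)
    return radius, delta, 2.0 * (delta + CC_BOND)


def nanotube_unit_cell_length(chirality: Chirality) -> float:
    """Axial length of one translational unit cell, Å."""
    if chirality.m != 0:
        raise NotImplementedError("only zigzag (n,0) nanotubes are generated")
    return _zigzag_geometry(chirality.n)[2]


def build_nanotube(chirality: Chirality, length: float) -> Structure:
    """Carbon atoms of an (n, 0) nanotube, axis along z, centered at origin.

    ``length`` (Å) is truncated to whole unit cells (4n atoms each); it
    must cover at least one cell.  Atom rings alternate angular offsets
    of π/n so every atom has three neighbors at exactly a/√3.
    """
    if chirality.m != 0:
        raise NotImplementedError("only zigzag (n,0) nanotubes are generated")
    n = chirality.n
    radius, delta, period = _zigzag_geometry(n)
    n_cells = int(math.floor(length / period + 1e-9))
    if n_cells < 1:
        raise ValueError(
            f"length {length} Å is shorter than one unit cell ({period:.3f} Å)")
    # four rings per cell: (z offset, angular offset in half-steps)
    rings = [(0.0, 0.0), (delta, 0.5), (delta + CC_BOND, 0.5),
             (2.0 * delta + CC_BOND, 0.0)]
    coords = []
    for cell in range(n_cells):
        z0 = cell * period
        for z_off, ang_off in rings:
            phi = 2.0 * math.pi * (np.arange(n) + ang_off) / n
            ring = np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                                    np.full(n, z0 + z_off)])
            coords.append(ring)
    xyz = np.concatenate(coords)
    xyz[:, 2] -= xyz[:, 2].mean()  # center on origin
    n_atoms = len(xyz)
    return Structure.from_arrays(
        positions=xyz,
        name=np.full(n_atoms, "C", dtype=object),
        element=np.full(n_atoms, "C", dtype=object),
        res_name=np.full(n_atoms, "CNT", dtype=object),
        res_id=np.ones(n_atoms, dtype=int),
        chain_id=np.full(n_atoms, "A", dtype=object),
        body_label=f"cnt_{n}_0",
        provenance=f"zigzag ({n},0) nanotube, {n_cells} unit cells")


def build_ig_sequence(repeats: int) -> tuple[str, str]:
    """Strands of the telomeric duplex hosting the G-quadruplex/i-motif.

    Returns ``(strand_g, strand_c)`` where the guanine-rich strand reads
    5′→3′ and the cytosine-rich strand is written in the conventional
    3′→5′ repeat grouping of the telomeric C-strand.  ``repeats=7``
    gives the 45 + 45 = 90-nucleotide construct whose middle hosts the
    G-quadruplex (G-strand) and the i-motif (C-strand).
    """
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    strand_g = "GGG" + "TTAGGG" * repeats
    strand_c = "CCC" + "ATTCCC" * repeats
    return strand_g, strand_c


# ---------------------------------------------------------------------------
# i-motif hydrogen-bond fixture
# ---------------------------------------------------------------------------

#: Heavy-atom donor–acceptor distance in the idealized C:C⁺ pair, Å.
_PAIR_DISTANCE = 2.9
#: Lateral spacing of the three H-bond columns within a pair, Å.
_COLUMN_SPACING = 2.2
#: Inter-pair stacking rise, Å.
_STACK_RISE = 3.1
#: Donor–H bond length, Å.
_DH_BOND = 1.0


def build_imotif_fixture(n_pairs: int = 6) -> tuple[Structure, np.ndarray]:
    """Idealized hemiprotonated i-motif core: stacked C:C⁺ Hoogsteen pairs.

    Each pair joins a protonated cytosine (residue ``CYP``, donors
    N4–H and N3–H⁺, acceptor O2) to a neutral cytosine (``CYT``, donor
    N4–H, acceptors N3 and O2) through three parallel donor–acceptor
    contacts at 2.9 Å with perfectly linear D–H···A geometry.  The
    default six pairs therefore present 18 hydrogen bonds.

    Returns the structure and the (sorted) indices of the heavy atoms
    engaged in those contacts — the natural RMSD collective-variable
    atom set.  The generator is deterministic.
    """
    names, elements, res_names, res_ids, chains, coords = [], [], [], [], [], []
    hbond_atoms: list[int] = []

    def add(name: str, element: str, res: str, rid: int, chain: str,
            xyz: tuple[float, float, float], cv: bool) -> None:
        if cv:
            hbond_atoms.append(len(names))
        names.append(name)
        elements.append(element)
        res_names.append(res)
        res_ids.append(rid)
        chains.append(chain)
        coords.append(xyz)

    d, w, h = _PAIR_DISTANCE, _COLUMN_SPACING, _DH_BOND
    for p in range(n_pairs):
        z = p * _STACK_RISE
        rid = p + 1
        # protonated cytosine (chain I): donors N4-H, N3-H+; acceptor O2
        add("N4", "N", "CYP", rid, "I", (0.0, w, z), True)
        add("H4", "H", "CYP", rid, "I", (h, w, z), False)
        add("N3", "N", "CYP", rid, "I", (0.0, 0.0, z), True)
        add("H3", "H", "CYP", rid, "I", (h, 0.0, z), False)
        add("O2", "O", "CYP", rid, "I", (0.0, -w, z), True)
        # neutral cytosine (chain J): acceptors O2, N3; donor N4-H
        add("O2", "O", "CYT", rid, "J", (d, w, z), True)
        add("N3", "N", "CYT", rid, "J", (d, 0.0, z), True)
        add("N4", "N", "CYT", rid, "J", (d, -w, z), True)
        add("H4", "H", "CYT", rid, "J", (d - h, -w, z), False)
    structure = Structure.from_arrays(
        positions=np.array(coords, dtype=float),
        name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        res_name=np.array(res_names, dtype=object),
        res_id=np.array(res_ids, dtype=int),
        chain_id=np.array(chains, dtype=object),
        body_label="imotif_fixture",
        provenance=f"idealized hemiprotonated i-motif core, {n_pairs} C:C+ pairs")
    return structure, np.array(sorted(hbond_atoms), dtype=int)


def imotif_donors_acceptors(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Donor and acceptor heavy-atom indices of the i-motif fixture.

    Donors: N4 of both cytosines plus N3 of the protonated one;
    acceptors: O2 of both plus N3 of the neutral one.
    """
    donors = select_atoms(
        structure, "resname CYP and name N4,N3 or resname CYT and name N4")
    acceptors = select_atoms(
        structure, "resname CYT and name O2,N3 or resname CYP and name O2")
    return donors, acceptors


# ---------------------------------------------------------------------------
# Toy rigid-body systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToySystemSpec:
    """Reproducible two-body toy system for oracle-checked tests.

    ``body_atoms`` gives the atom count of each body; multi-atom bodies
    get deterministic random offsets of scale ``spread`` around their
    center.  ``charges`` are per-atom charges, one value per body.
    Identical spec + seed → identical coordinates bit for bit.
    """

    body_atoms: tuple[int, ...] = (1, 1)
    separation: float = 5.0
    charges: tuple[float, ...] = (0.0, 0.0)
    lj_epsilon: float = 1.0
    lj_sigma: float = 3.4
    mass: float = 12.0
    spread: float = 1.2
    box_extent: float = 20.0
    n_ions: int = 0
    ion_charge: float = 1.0
    ion_mass: float = 22.99
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.body_atoms) != len(self.charges):
            raise ValueError("need one charge entry per body")
        if any(n < 1 for n in self.body_atoms):
            raise ValueError("each body needs at least one atom")


def build_toy_system(spec: ToySystemSpec, temperature: float = 300.0) -> SystemState:
    """Realize a :class:`ToySystemSpec` as a parameterized SystemState.

    Bodies are laid out along the z axis ``spec.separation`` apart,
    optional monovalent ions are scattered uniformly in the box.  Atom
    pairs closer than 0.5 Å are rejected as overlapping.
    """
    rng = np.random.default_rng(spec.seed)
    positions, charges = [], []
    body_selections = []
    cursor = 0
    for b, (n_at, q) in enumerate(zip(spec.body_atoms, spec.charges)):
        center = np.array([0.0, 0.0, b * spec.separation])
        pts = [center]
        for _ in range(n_at - 1):
            # deterministic rejection sampling keeps intra-body spacing sane
            for _attempt in range(200):
                cand = center + rng.uniform(-spec.spread, spec.spread, 3)
                if all(np.linalg.norm(cand - p) >= 0.8
                       for p in positions + pts):
                    break
            else:
                raise ValueError(
                    "could not place non-overlapping atoms; increase spread")
            pts.append(cand)
        positions.extend(pts)
        charges.extend([q] * n_at)
        body_selections.append(list(range(cursor, cursor + n_at)))
        cursor += n_at
    xyz = np.asarray(positions)
    n = len(xyz)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(dist, np.inf)
    if np.min(dist) < 0.5:
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        raise ValueError(f"overlapping atoms {i} and {j} at {dist[i, j]:.3f} Å")
    chain_ids = np.concatenate([
        np.full(n_at, chr(ord("A") + b), dtype=object)
        for b, n_at in enumerate(spec.body_atoms)])
    structure = Structure.from_arrays(
        positions=xyz,
        name=np.full(n, "X", dtype=object),
        element=np.full(n, "C", dtype=object),
        res_name=np.full(n, "TOY", dtype=object),
        res_id=np.concatenate([np.full(n_at, b + 1, dtype=int)
                               for b, n_at in enumerate(spec.body_atoms)]),
        chain_id=chain_ids,
        charge=np.asarray(charges, dtype=float),
        lj_epsilon=np.full(n, spec.lj_epsilon),
        lj_sigma=np.full(n, spec.lj_sigma),
        mass=np.full(n, spec.mass),
        body_label="toy")
    ions = None
    if spec.n_ions:
        ion_xyz = rng.uniform(-spec.box_extent / 2, spec.box_extent / 2,
                              (spec.n_ions, 3))
        ions = Structure.from_arrays(
            positions=ion_xyz,
            name=np.full(spec.n_ions, "NA", dtype=object),
            element=np.full(spec.n_ions, "Na", dtype=object),
            res_name=np.full(spec.n_ions, "ION", dtype=object),
            res_id=np.arange(1, spec.n_ions + 1),
            chain_id=np.full(spec.n_ions, "S", dtype=object),
            charge=np.full(spec.n_ions, spec.ion_charge),
            lj_epsilon=np.full(spec.n_ions, 0.3),
            lj_sigma=np.full(spec.n_ions, 2.6),
            mass=np.full(spec.n_ions, spec.ion_mass),
            body_label="ions")
    return make_system(structure, body_selections, temperature=temperature,
                       ions=ions)
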
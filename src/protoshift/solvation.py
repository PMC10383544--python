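"""Solvation-shell statistics from coordinate frames.

Given trajectory frames of a rigid solute (with labelled acceptor oxygens
O1, O2, O3 on its ring system) in a periodic box of water and a cosolvent,
this module computes

* geometric hydrogen bonds: donor-acceptor distance <= 0.35 nm AND
  acceptor-donor-hydrogen angle <= 30 deg, where the angle is measured at
  the donor heavy atom between the donor->hydrogen and donor->acceptor
  directions (both criteria boundary-inclusive);
* per-acceptor H-bond occupancies classified by donor species;
* minimum-distance distribution functions (MDDF): the distribution of each
  solvent molecule's closest-atom distance to any solute atom, normalized
  by uniform random re-placements of the same molecules in the same box;
* preferential-interaction coefficients
  Gamma = n_cosolvent(r) - (N_c/N_w) n_water(r), positive when the
  cosolvent is locally enriched at the solute surface.

All distances use the orthorhombic minimum-image convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Frame",
    "HBondOccupancy",
    "MDDFResult",
    "PreferentialInteraction",
    "read_trajectory",
    "write_trajectory",
    "detect_hbonds",
    "occupancy",
    "mddf",
    "preferential_interaction",
    "GRO_RESNAME_MAP",
]

SOLUTE = "SOLUTE"
WATER = "WAT"
ACCEPTOR_NAMES = ("O1", "O2", "O3")
OCCUPANCY_STATES = ("water-only", "cosolvent-only", "both", "none")

#: default mapping of GRO residue names onto the species tags of this module
GRO_RESNAME_MAP = {
    "SOL": WATER,
    "WAT": WATER,
    "TIP3": WATER,
    "HOH": WATER,
    "GOL": "GLY",
    "GLY": "GLY",
    "SUC": "SUC",
    "FLU": SOLUTE,
    "LIG": SOLUTE,
    "MOL": SOLUTE,
    "UNL": SOLUTE,
}

_DIST_TOL = 1e-9  # boundary-inclusive comparisons survive float round-off
_ANGLE_TOL = 1e-7


@dataclass
class Frame:
    box: np.ndarray  # (3,) nm, orthorhombic
    species: np.ndarray  # (N,) str tags: SOLUTE, WAT, GLY, SUC
    molid: np.ndarray  # (N,) int
    names: np.ndarray  # (N,) atom names
    xyz: np.ndarray  # (N, 3) nm

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.species = np.asarray(self.species, dtype=object)
        self.molid = np.asarray(self.molid, dtype=int)
        self.names = np.asarray(self.names, dtype=object)
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        n = self.xyz.shape[0]
        if not (self.species.size == self.molid.size == self.names.size == n):
            raise ValueError("per-atom arrays must be aligned")

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[0]

    def acceptor_indices(self) -> dict:
        """Indices of the solute acceptor oxygens O1, O2, O3."""
        out = {}
        solute = self.species == SOLUTE
        for name in ACCEPTOR_NAMES:
            idx = np.flatnonzero(solute & (self.names == name))
            if idx.size != 1:
                raise ValueError(f"acceptor label {name} missing or duplicated on solute")
            out[name] = int(idx[0])
        return out

    def donor_pairs(self):
        """Hydroxyl (O, H) donor pairs of all non-solute molecules.

        Naming convention: within each molecule's atom list, an atom whose
        name starts with 'O' donates through every immediately following
        atom whose name starts with 'H'.
        """
        o_idx, h_idx, mids, specs = [], [], [], []
        order = np.argsort(self.molid, kind="stable")
        solv = order[self.species[order] != SOLUTE]
        for mid in np.unique(self.molid[solv]):
            atoms = solv[self.molid[solv] == mid]
            current_o = None
            for ia in atoms:
                name = str(self.names[ia])
                if name.startswith("O"):
                    current_o = ia
                elif name.startswith("H") and current_o is not None:
                    o_idx.append(current_o)
                    h_idx.append(ia)
                    mids.append(int(self.molid[ia]))
                    specs.append(str(self.species[ia]))
                else:
                    current_o = None
        return (
            np.asarray(o_idx, dtype=int),
            np.asarray(h_idx, dtype=int),
            np.asarray(mids, dtype=int),
            np.asarray(specs, dtype=object),
        )


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    return vectors - box * np.round(vectors / box)


# ---------------------------------------------------------------------------
# trajectory I/O


def write_trajectory(frames: Sequence[Frame], path) -> None:
    """Extended-XYZ dialect: N / BOX ex ey ez / per-atom SPECIES MOLID NAME X Y Z."""
    lines = []
    for fr in frames:
        lines.append(str(fr.n_atoms))
        lines.append("BOX " + " ".join(repr(float(e)) for e in fr.box))
        for sp, mid, name, pos in zip(fr.species, fr.molid, fr.names, fr.xyz):
            lines.append(
                f"{sp} {mid} {name} " + " ".join(repr(float(x)) for x in pos)
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_xyz_dialect(path) -> list[Frame]:
    raw = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    frames: list[Frame] = []
    pos = 0
    while pos < len(raw):
        frame_idx = len(frames)
        try:
            n_atoms = int(raw[pos])
        except ValueError as exc:
            raise ValueError(f"frame {frame_idx}: bad atom-count header {raw[pos]!r}") from exc
        if pos + 1 >= len(raw) or not raw[pos + 1].startswith("BOX"):
            raise ValueError(f"frame {frame_idx}: missing BOX line")
        box = np.array([float(x) for x in raw[pos + 1].split()[1:4]])
        body = raw[pos + 2 : pos + 2 + n_atoms]
        if len(body) < n_atoms:
            raise ValueError(
                f"frame {frame_idx}: truncated (expected {n_atoms} atoms, got {len(body)})"
            )
        species, molid, names, xyz = [], [], [], []
        for ln in body:
            parts = ln.split()
            if len(parts) != 6:
                raise ValueError(f"frame {frame_idx}: malformed atom line {ln!r}")
            species.append(parts[0])
            molid.append(int(parts[1]))
            names.append(parts[2])
            xyz.append([float(parts[3]), float(parts[4]), float(parts[5])])
        frames.append(Frame(box, species, molid, names, np.array(xyz)))
        pos += 2 + n_atoms
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def _read_gro(path, resname_map: Optional[dict] = None) -> list[Frame]:
    import MDAnalysis as mda

    resname_map = dict(GRO_RESNAME_MAP, **(resname_map or {}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    unknown = sorted({r for r in u.atoms.resnames if r not in resname_map})
    if unknown:
        raise ValueError(f"unknown GRO residue name(s): {', '.join(unknown)}")
    box = u.dimensions[:3] / 10.0  # Angstrom -> nm
    species = np.array([resname_map[r] for r in u.atoms.resnames], dtype=object)
    return [
        Frame(
            box=box,
            species=species,
            molid=u.atoms.resids.astype(int),
            names=u.atoms.names.astype(object),
            xyz=u.atoms.positions / 10.0,
        )
    ]


def read_trajectory(path, resname_map: Optional[dict] = None) -> list[Frame]:
    """Read frames from the extended-XYZ dialect or a (single-frame) GRO file."""
    if str(path).lower().endswith(".gro"):
        return _read_gro(path, resname_map)
    return _read_xyz_dialect(path)


# ---------------------------------------------------------------------------
# hydrogen bonds


def detect_hbonds(
    frame: Frame, d_max_nm: float = 0.35, a_max_deg: float = 30.0
) -> list[tuple]:
    """All (acceptor name, donor molecule id, donor species) H-bond triples.

    A donor hydroxyl (O, H) bonds to a solute acceptor when the
    acceptor-donor distance is <= d_max_nm and the angle at the donor oxygen
    between the O->H and O->acceptor directions is <= a_max_deg; both
    criteria are boundary-inclusive and evaluated under the minimum image.
    """
    acceptors = frame.acceptor_indices()
    o_idx, h_idx, mids, specs = frame.donor_pairs()
    bonds: list[tuple] = []
    if o_idx.size == 0:
        return bonds
    o_pos = frame.xyz[o_idx]
    h_vec = minimum_image(frame.xyz[h_idx] - o_pos, frame.box)
    for name, ai in acceptors.items():
        a_vec = minimum_image(frame.xyz[ai] - o_pos, frame.box)
        dist = np.linalg.norm(a_vec, axis=1)
        close = dist <= d_max_nm + _DIST_TOL
        if not np.any(close):
            continue
        hv, av = h_vec[close], a_vec[close]
        cosang = np.einsum("ij,ij->i", hv, av) / (
            np.linalg.norm(hv, axis=1) * np.linalg.norm(av, axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = ang <= a_max_deg + _ANGLE_TOL
        for mid, sp in zip(mids[close][ok], specs[close][ok]):
            bonds.append((name, int(mid), str(sp)))
    return sorted(set(bonds))


@dataclass
class HBondOccupancy:
    """Per-acceptor fractions of frames by donor-species composition."""

    fractions: dict  # acceptor -> {state -> fraction}
    n_frames: int

    def __post_init__(self) -> None:
        for acc, states in self.fractions.items():
            total = sum(states.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"{acc}: occupancy fractions sum to {total}, not 1")
            if any(not (0.0 <= v <= 1.0) for v in states.values()):
                raise ValueError(f"{acc}: fraction outside [0, 1]")


def occupancy(bonds_per_frame: Sequence[Sequence[tuple]], n_frames: int) -> HBondOccupancy:
    """Classify each frame per acceptor by donor species present.

    States: water-only, cosolvent-only (any non-water donor), both, none;
    fractions are over n_frames.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    counts = {acc: dict.fromkeys(OCCUPANCY_STATES, 0) for acc in ACCEPTOR_NAMES}
    for bonds in bonds_per_frame:
        per_acc: dict = {acc: set() for acc in ACCEPTOR_NAMES}
        for acc, _mid, sp in bonds:
            per_acc[acc].add("water" if sp == WATER else "cosolvent")
        for acc, kinds in per_acc.items():
            if kinds == {"water"}:
                state = "water-only"
            elif kinds == {"cosolvent"}:
                state = "cosolvent-only"
            elif kinds:
                state = "both"
            else:
                state = "none"
            counts[acc][state] += 1
    fractions = {
        acc: {state: c / n_frames for state, c in states.items()}
        for acc, states in counts.items()
    }
    return HBondOccupancy(fractions=fractions, n_frames=n_frames)


# ---------------------------------------------------------------------------
# MDDF and preferential interaction


@dataclass
class MDDFResult:
    r: np.ndarray  # bin centers, nm
    bin_edges: np.ndarray
    mddf: dict  # species -> ideal-normalized distribution
    n_cumulative: dict  # species -> mean count of molecules with min dist <= edge
    n_cumulative_ideal: dict  # same, for the uniform re-placement reference
    n_molecules: dict  # species -> molecules per frame
    bulk_ratio: Optional[float]  # N_cosolvent / N_water, if both present

    def _edge_index(self, r_nm: float) -> int:
        i = np.flatnonzero(np.isclose(self.bin_edges[1:], r_nm, atol=1e-9))
        if i.size != 1:
            raise ValueError(f"r = {r_nm} nm is not on the distribution grid")
        return int(i[0])

    def cumulative_at(self, species: str, r_nm: float) -> float:
        return float(self.n_cumulative[species][self._edge_index(r_nm)])

    def ideal_cumulative_at(self, species: str, r_nm: float) -> float:
        """Expected count under uniform random placement of the same molecules.

        The baseline against which finite-molecular-size effects on
        minimum-distance counts (and hence on Gamma) should be judged.
        """
        return float(self.n_cumulative_ideal[species][self._edge_index(r_nm)])


def _min_distances(solv_xyz, solute_xyz, box, molid_sorted):
    """Per-molecule minimum atom-atom distance to the solute (min image)."""
    diff = solv_xyz[:, None, :] - solute_xyz[None, :, :]
    diff = minimum_image(diff, box)
    d_atom = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff)).min(axis=1)
    starts = np.flatnonzero(np.r_[True, molid_sorted[1:] != molid_sorted[:-1]])
    return np.minimum.reduceat(d_atom, starts)


def mddf(
    frames: Sequence[Frame],
    species: Optional[Sequence[str]] = None,
    bin_width_nm: float = 0.02,
    r_max_nm: Optional[float] = None,
    n_ref: int = 10,
    seed: int = 0,
) -> MDDFResult:
    """Minimum-distance distribution functions of solvent species.

    For every solvent molecule and frame, the minimum over all
    (solvent atom, solute atom) distances is histogrammed; each bin is
    normalized by the mean count from n_ref uniform random re-placements
    (random position and orientation) of the same molecules in the same box,
    so an unstructured solvent gives mddf = 1.  Raw mean cumulative counts
    n(r) are also returned for preferential-interaction analysis.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    from scipy.spatial.transform import Rotation

    box = frames[0].box
    half_min_edge = 0.5 * float(np.min(box))
    if r_max_nm is None:
        r_max_nm = bin_width_nm * int(half_min_edge / bin_width_nm)
    if r_max_nm > half_min_edge + 1e-12:
        raise ValueError(
            f"r_max {r_max_nm} nm exceeds half the smallest box edge ({half_min_edge} nm)"
        )
    edges = np.arange(0.0, r_max_nm + 0.5 * bin_width_nm, bin_width_nm)
    present = sorted({str(s) for fr in frames for s in fr.species if s != SOLUTE})
    if species is None:
        species_list = present
    else:
        species_list = [species] if isinstance(species, str) else list(species)
        missing = [s for s in species_list if s not in present]
        if missing:
            raise ValueError(f"species not present in frames: {missing}")
    rng = np.random.default_rng(seed)

    hist_real = {s: np.zeros(edges.size - 1) for s in species_list}
    hist_ideal = {s: np.zeros(edges.size - 1) for s in species_list}
    n_mol = {}
    for fr in frames:
        solute_xyz = fr.xyz[fr.species == SOLUTE]
        if solute_xyz.size == 0:
            raise ValueError("frame has no solute atoms")
        for sp in species_list:
            sel = np.flatnonzero(fr.species == sp)
            order = sel[np.argsort(fr.molid[sel], kind="stable")]
            mids = fr.molid[order]
            uniq, starts = np.unique(mids, return_index=True)
            n_mol.setdefault(sp, uniq.size)
            if n_mol[sp] != uniq.size:
                raise ValueError(f"{sp}: molecule count varies between frames")
            xyz = fr.xyz[order]
            d = _min_distances(xyz, solute_xyz, fr.box, mids)
            hist_real[sp] += np.histogram(d, bins=edges)[0]
            # ideal reference: same molecules, uniform random placement;
            # molecules are unwrapped (min image about their first atom) so
            # boundary-split molecules keep their true shape
            sizes = np.diff(np.r_[starts, xyz.shape[0]])
            first = np.repeat(xyz[starts], sizes, axis=0)
            rel = minimum_image(xyz - first, fr.box)
            centroids_rel = np.add.reduceat(rel, starts, axis=0) / sizes[:, None]
            local = rel - np.repeat(centroids_rel, sizes, axis=0)
            for _ in range(n_ref):
                rots = Rotation.random(uniq.size, rng=rng).as_matrix()
                new_centroids = rng.uniform(0.0, 1.0, (uniq.size, 3)) * fr.box
                rep = np.repeat(np.arange(uniq.size), sizes)
                new_xyz = (
                    np.einsum("nij,nj->ni", rots[rep], local) + new_centroids[rep]
                )
                d_ref = _min_distances(new_xyz, solute_xyz, fr.box, mids)
                hist_ideal[sp] += np.histogram(d_ref, bins=edges)[0]

    n_frames = len(frames)
    result_mddf, cumulative, cumulative_ideal = {}, {}, {}
    for sp in species_list:
        real = hist_real[sp] / n_frames
        ideal = hist_ideal[sp] / (n_frames * n_ref)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(ideal > 0, real / np.where(ideal > 0, ideal, 1.0), 0.0)
        result_mddf[sp] = g
        cumulative[sp] = np.cumsum(real)
        cumulative_ideal[sp] = np.cumsum(ideal)
    bulk_ratio = None
    non_water = [s for s in species_list if s != WATER]
    if WATER in n_mol and len(non_water) == 1:
        bulk_ratio = n_mol[non_water[0]] / n_mol[WATER]
    return MDDFResult(
        r=0.5 * (edges[:-1] + edges[1:]),
        bin_edges=edges,
        mddf=result_mddf,
        n_cumulative=cumulative,
        n_cumulative_ideal=cumulative_ideal,
        n_molecules=n_mol,
        bulk_ratio=bulk_ratio,
    )


@dataclass
class PreferentialInteraction:
    gamma: float
    r_cut_nm: float
    species: str
    reference_species: str
    n_species_at_rcut: float
    n_reference_at_rcut: float
    bulk_ratio: float
    #: the same estimator evaluated on the ideal uniform-placement counts;
    #: nonzero when the two species differ in molecular size, and the proper
    #: zero point when judging enrichment vs. depletion
    gamma_ideal_baseline: float = 0.0

    @property
    def gamma_excess(self) -> float:
        """Gamma relative to the finite-size ideal baseline."""
        return self.gamma - self.gamma_ideal_baseline


def preferential_interaction(
    m: MDDFResult, r_cut_nm: float = 0.8, species: Optional[str] = None
) -> PreferentialInteraction:
    """Gamma = n_s(r_cut) - (N_s/N_ref) n_ref(r_cut) from cumulative MDDF counts.

    By default the cosolvent is analysed against water; passing
    species='WAT' gives the complementary water coefficient against the
    cosolvent.  Positive Gamma means local enrichment of `species` at the
    solute surface.  A warning is raised when Gamma(r) has not plateaued at
    r_cut (>10% change over the preceding 0.1 nm).
    """
    species_present = sorted(m.n_molecules)
    if species is None:
        candidates = [s for s in species_present if s != WATER]
        if len(candidates) != 1:
            raise ValueError("specify species explicitly (no unique cosolvent present)")
        species = candidates[0]
    if species == WATER:
        refs = [s for s in species_present if s != WATER]
        if len(refs) != 1:
            raise ValueError("water Gamma needs exactly one cosolvent as reference")
        reference = refs[0]
    else:
        reference = WATER
    if species not in m.n_molecules or reference not in m.n_molecules:
        raise ValueError(f"species {species!r} / reference {reference!r} not in MDDF result")
    ratio = m.n_molecules[species] / m.n_molecules[reference]

    def gamma_at(r):
        return m.cumulative_at(species, r) - ratio * m.cumulative_at(reference, r)

    gamma = gamma_at(r_cut_nm)
    gamma_ideal = m.ideal_cumulative_at(species, r_cut_nm) - ratio * m.ideal_cumulative_at(
        reference, r_cut_nm
    )
    r_prev = r_cut_nm - 0.1
    if r_prev > m.bin_edges[1]:
        try:
            g_prev = gamma_at(round(r_prev, 10))
            if abs(gamma - g_prev) > 0.1 * max(abs(gamma), 1e-12):
                warnings.warn(
                    f"Gamma({species}) not plateaued at r_cut={r_cut_nm} nm "
                    f"(changed {g_prev:.3g} -> {gamma:.3g} over the last 0.1 nm)",
                    RuntimeWarning,
                    stacklevel=2,
                )
        except ValueError:
            pass
    return PreferentialInteraction(
        gamma=float(gamma),
        r_cut_nm=r_cut_nm,
        species=species,
        reference_species=reference,
        n_species_at_rcut=m.cumulative_at(species, r_cut_nm),
        n_reference_at_rcut=m.cumulative_at(reference, r_cut_nm),
        bulk_ratio=ratio,
        gamma_ideal_baseline=float(gamma_ideal),
    )
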
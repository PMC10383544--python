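"""Synthetic solvent boxes with controllable local cosolvent enrichment.

Statistical stand-ins for explicit-solvent simulation frames: a rigid
10-atom solute fragment with three labelled acceptor oxygens (O1, O2, O3)
sits at the centre of a cubic periodic box; water and cosolvent molecules
(each hydroxyl carrying an explicit hydrogen) are placed uniformly at
random, except that cosolvent placement inside a spherical shell around the
solute is re-weighted by an enrichment factor.  Frames are independent
draws, deterministic given the seed.  No energetics are modelled; the boxes
exist to give the solvation statistics known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .solvation import Frame, SOLUTE, WATER

__all__ = ["BoxGroundTruth", "generate_solvation_box", "generate_hbond_fixture"]

OH_BOND_NM = 0.0957

# Rigid solute fragment (nm, centred on the origin): a flat ring-like core
# with a hydroxyl-type oxygen (O1), ring heteroatom (O2) and carbonyl-type
# oxygen (O3) echoing the xanthene numbering of the probe.
SOLUTE_TEMPLATE = (
    ("C1", (-0.25, 0.00, 0.0)),
    ("C2", (-0.125, 0.07, 0.0)),
    ("C3", (0.00, 0.00, 0.0)),
    ("C4", (0.125, 0.07, 0.0)),
    ("C5", (0.25, 0.00, 0.0)),
    ("C6", (0.00, -0.14, 0.0)),
    ("C7", (0.00, 0.14, 0.0)),
    ("O1", (-0.37, 0.05, 0.0)),
    ("O2", (0.00, 0.26, 0.0)),
    ("O3", (0.37, 0.05, 0.0)),
)

# Solvent molecule templates; each hydroxyl oxygen is immediately followed
# by its hydrogen(s) so donor pairing by naming convention works.
_WATER_TEMPLATE = (
    ("OW", (0.0, 0.0, 0.0)),
    ("HW1", (OH_BOND_NM, 0.0, 0.0)),
    ("HW2", (-0.02397, 0.09267, 0.0)),  # 104.5 deg H-O-H
)
_GLYCEROL_TEMPLATE = (
    ("C1", (0.0, 0.0, 0.0)),
    ("O1", (0.14, 0.0, 0.0)),
    ("H1", (0.14 + OH_BOND_NM, 0.0, 0.0)),
    ("O2", (-0.07, 0.121, 0.0)),
    ("H2", (-0.118, 0.204, 0.0)),
    ("O3", (-0.07, -0.121, 0.0)),
    ("H3", (-0.118, -0.204, 0.0)),
)
_SUCROSE_TEMPLATE = (
    ("C1", (0.0, 0.0, 0.0)),
    ("C2", (0.15, 0.0, 0.0)),
    ("O1", (0.075, 0.14, 0.0)),
    ("H1", (0.075, 0.236, 0.0)),
    ("O2", (-0.10, 0.10, 0.08)),
    ("H2", (-0.167, 0.167, 0.134)),
    ("O3", (-0.10, -0.10, 0.08)),
    ("H3", (-0.167, -0.167, 0.134)),
    ("O4", (0.25, 0.10, -0.08)),
    ("H4", (0.317, 0.167, -0.134)),
    ("O5", (0.25, -0.10, -0.08)),
    ("H5", (0.317, -0.167, -0.134)),
)
SOLVENT_TEMPLATES = {WATER: _WATER_TEMPLATE, "GLY": _GLYCEROL_TEMPLATE, "SUC": _SUCROSE_TEMPLATE}

_MAX_PACK_ITER = 200


@dataclass
class BoxGroundTruth:
    """Generative parameters of the synthetic solvent box."""

    box_edge: float = 4.0  # nm, cubic
    n_water: int = 200
    n_cosolvent: int = 20
    cosolvent: str = "GLY"
    enrichment: float = 1.0  # 1 = bulk composition near the solute
    shell_radius: float = 1.0  # nm, sphere around the solute centroid
    hbond_fraction: float = 0.0
    n_frames: int = 20
    seed: int = 0
    min_center_distance: float = 0.15  # nm

    def __post_init__(self) -> None:
        if self.n_water < 1:
            raise ValueError("need at least one water molecule")
        if self.n_cosolvent < 0:
            raise ValueError("n_cosolvent must be >= 0")
        if self.enrichment < 0:
            raise ValueError("enrichment must be >= 0")
        if not (0.0 <= self.hbond_fraction <= 1.0):
            raise ValueError("hbond_fraction must be in [0, 1]")
        if self.shell_radius >= self.box_edge / 2:
            raise ValueError("shell_radius must be below half the box edge")
        if self.cosolvent not in SOLVENT_TEMPLATES or self.cosolvent == WATER:
            raise ValueError(f"unknown cosolvent tag {self.cosolvent!r}")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def _template_xyz(template) -> np.ndarray:
    return np.array([pos for _name, pos in template], dtype=float)


def _sample_centers(rng, gt: BoxGroundTruth, solute_xyz: np.ndarray):
    """Rejection-sampled molecule centres honouring enrichment and clashes."""
    box = gt.box_edge
    center = np.full(3, box / 2.0)
    v_shell = 4.0 / 3.0 * np.pi * gt.shell_radius**3
    p0 = v_shell / box**3
    e = gt.enrichment
    p_shell = e * p0 / (e * p0 + (1.0 - p0)) if (e * p0 + (1.0 - p0)) > 0 else 1.0
    in_shell = rng.random(gt.n_cosolvent) < p_shell

    def draw_in_shell(n):
        # uniform in the sphere via radius ~ U^(1/3)
        u = rng.random(n)
        r = gt.shell_radius * u ** (1.0 / 3.0)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        return center + r[:, None] * v

    def draw_outside_shell(n):
        out = np.empty((n, 3))
        filled = 0
        for _ in range(_MAX_PACK_ITER):
            if filled == n:
                break
            cand = rng.uniform(0.0, box, (n - filled, 3))
            keep = np.linalg.norm(cand - center, axis=1) > gt.shell_radius
            k = int(keep.sum())
            out[filled : filled + k] = cand[keep]
            filled += k
        if filled < n:
            raise RuntimeError("packing failure: could not place cosolvent outside shell")
        return out

    def draw(region, n):
        if region == "shell":
            return draw_in_shell(n)
        if region == "outside":
            return draw_outside_shell(n)
        return rng.uniform(0.0, box, (n, 3))

    regions = ["shell" if s else "outside" for s in in_shell] + ["any"] * gt.n_water
    centers = np.vstack(
        [draw(r, 1) for r in regions] if regions else [np.empty((0, 3))]
    )

    d_min = gt.min_center_distance
    for _ in range(_MAX_PACK_ITER):
        diff = centers[:, None, :] - centers[None, :, :]
        diff -= box * np.round(diff / box)
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.fill_diagonal(dist, np.inf)
        sdiff = centers[:, None, :] - solute_xyz[None, :, :]
        sdiff -= box * np.round(sdiff / box)
        sdist = np.sqrt(np.einsum("ijk,ijk->ij", sdiff, sdiff)).min(axis=1)
        bad = np.flatnonzero((dist.min(axis=1) < d_min) | (sdist < d_min))
        if bad.size == 0:
            return centers[: gt.n_cosolvent], centers[gt.n_cosolvent :]
        # resample clashing molecules within their assigned region
        keep_mask = np.ones(len(centers), bool)
        keep_mask[bad] = False
        resampled = []
        for i in bad:
            resampled.append(draw(regions[i], 1)[0])
        centers[bad] = np.array(resampled)
    raise RuntimeError("packing failure: clash resolution did not converge")


def _build_molecules(rng, species, start_molid, centers, box, template):
    names0 = [name for name, _ in template]
    local = _template_xyz(template)
    n = centers.shape[0]
    rots = Rotation.random(n, rng=rng).as_matrix() if n else np.empty((0, 3, 3))
    species_l, molid_l, names_l, xyz_l = [], [], [], []
    for i in range(n):
        xyz = local @ rots[i].T + centers[i]
        xyz %= box  # keep every coordinate inside the box
        species_l += [species] * local.shape[0]
        molid_l += [start_molid + i] * local.shape[0]
        names_l += names0
        xyz_l.append(xyz)
    return species_l, molid_l, names_l, xyz_l


def _force_hbond(frame_xyz, names, acceptor_pos, solute_center, water_offset):
    """Reposition one water into ideal donor geometry toward an acceptor."""
    u = acceptor_pos - solute_center
    norm = np.linalg.norm(u)
    u = u / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    o_pos = acceptor_pos + 0.30 * u  # donor O, 0.30 nm outward
    h1 = o_pos - OH_BOND_NM * u  # points straight back at the acceptor (0 deg)
    perp = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(u, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    h2 = o_pos + OH_BOND_NM * perp
    frame_xyz[water_offset] = o_pos
    frame_xyz[water_offset + 1] = h1
    frame_xyz[water_offset + 2] = h2


def generate_solvation_box(gt: BoxGroundTruth) -> list[Frame]:
    """Independent solvated frames with known enrichment ground truth.

    When hbond_fraction > 0, the first round(f * n_frames) frames have one
    water per acceptor repositioned into ideal hydrogen-bond geometry
    (0.30 nm, 0 deg); this needs n_water >= 3.
    """
    rng = np.random.default_rng(gt.seed)
    box = np.full(3, gt.box_edge)
    solute_xyz = _template_xyz(SOLUTE_TEMPLATE) + gt.box_edge / 2.0
    solute_names = [name for name, _ in SOLUTE_TEMPLATE]
    n_forced = int(round(gt.hbond_fraction * gt.n_frames))
    if n_forced > 0 and gt.n_water < 3:
        raise ValueError("hbond_fraction > 0 requires at least 3 waters")
    frames = []
    acceptor_pos = {
        name: solute_xyz[i] for i, name in enumerate(solute_names) if name.startswith("O")
    }
    for i_frame in range(gt.n_frames):
        cos_centers, wat_centers = _sample_centers(rng, gt, solute_xyz)
        species = [SOLUTE] * len(solute_names)
        molid = [0] * len(solute_names)
        names = list(solute_names)
        xyz = [solute_xyz]
        s, m, n, x = _build_molecules(
            rng, gt.cosolvent, 1, cos_centers, gt.box_edge, SOLVENT_TEMPLATES[gt.cosolvent]
        )
        species += s; molid += m; names += n; xyz += x
        s, m, n, x = _build_molecules(
            rng, WATER, 1 + gt.n_cosolvent, wat_centers, gt.box_edge, _WATER_TEMPLATE
        )
        species += s; molid += m; names += n; xyz += x
        coords = np.vstack(xyz)
        if i_frame < n_forced:
            n_solute = len(solute_names)
            n_cos_atoms = gt.n_cosolvent * len(SOLVENT_TEMPLATES[gt.cosolvent])
            water_start = n_solute + n_cos_atoms
            for k, acc in enumerate(("O1", "O2", "O3")):
                _force_hbond(
                    coords,
                    names,
                    acceptor_pos[acc],
                    solute_xyz.mean(axis=0),
                    water_start + 3 * k,
                )
        frames.append(Frame(box.copy(), species, molid, names, coords))
    return frames


def generate_hbond_fixture(
    distance_nm: float, angle_deg: float, acceptor: str = "O1", box_edge: float = 4.0
) -> Frame:
    """One solute plus a single water at exact H-bond test geometry.

    The donor oxygen sits distance_nm from the chosen acceptor along the
    outward direction; the first hydrogen is placed so the angle at the
    donor between O->H and O->acceptor equals angle_deg.
    """
    if distance_nm <= 0:
        raise ValueError("distance must be positive")
    solute_xyz = _template_xyz(SOLUTE_TEMPLATE) + box_edge / 2.0
    solute_names = [name for name, _ in SOLUTE_TEMPLATE]
    if acceptor not in solute_names or not acceptor.startswith("O"):
        raise ValueError(f"unknown acceptor {acceptor!r}")
    a_pos = solute_xyz[solute_names.index(acceptor)]
    center = solute_xyz.mean(axis=0)
    u = a_pos - center
    u /= np.linalg.norm(u)
    o_pos = a_pos + distance_nm * u
    toward_acceptor = -u
    # rotate the O->acceptor direction by angle_deg about a perpendicular axis
    perp = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(u, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * perp)
    h1 = o_pos + OH_BOND_NM * rot.apply(toward_acceptor)
    h2 = o_pos + OH_BOND_NM * perp  # 90 deg, never satisfies the criterion alone
    species = [SOLUTE] * len(solute_names) + [WATER] * 3
    molid = [0] * len(solute_names) + [1] * 3
    names = solute_names + ["OW", "HW1", "HW2"]
    xyz = np.vstack([solute_xyz, o_pos, h1, h2])
    return Frame(np.full(3, box_edge), species, molid, names, xyz)
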
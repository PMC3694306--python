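"""MTSSL spin-label ensembles and inter-label distance distributions.

The nitroxide label is modeled with the accessible-volume approach: a
coarse-grained side chain (pseudo-atoms CB-SG-SD-CE-C3 ending in the N-O bond
midpoint) grown from the labeled residue's backbone with uniformly random
dihedral angles, keeping only conformers that do not clash with protein heavy
atoms.  No rotamer library or energy model is used: every sterically allowed
conformer carries equal weight.

Distances between two label ensembles are summarized as a probability density
P(r) on a distance grid, with the modal distance (position of the global
maximum) and the width at half height (distance between the outermost
half-maximum crossings) as scalar summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structures import StructureModel

__all__ = [
    "LabelEnsemble",
    "DistanceDistribution",
    "attach_label",
    "ensemble_distance_distribution",
    "distance_distribution_between_sites",
    "modal_distance",
    "width_at_half_height",
    "default_r_grid",
]

# pseudo-bond internal coordinates grown from CB: (length A, angle deg)
# lengths follow the disulfide-linked MTSSL side chain; the last entry spans
# the pyrroline ring from its attachment carbon to the N-O bond midpoint
_CHAIN_GEOMETRY = [
    ("SG", 1.81, 114.0),
    ("SD", 2.03, 104.0),
    ("CE", 1.81, 104.0),
    ("C3", 1.50, 114.0),
    ("NO", 2.90, 135.0),
]
# uniform heavy-atom van der Waals radius; cutoff = sum - clash_tolerance
_VDW_RADIUS = 1.7

_CB_LENGTH = 1.526

# internal sterics of the label itself, applied during conformer generation
# (a conformer folding back on its own backbone is never a valid rotamer and
# is re-sampled rather than counted against the site's accessibility):
# pairs of label/backbone atoms three or more bonds apart must keep at least
# _SELF_CUTOFF; the bulky nitroxide ring additionally keeps _RING_BACKBONE
# from the residue backbone (N, CA, C).
_SELF_CUTOFF = 2.8
_RING_BACKBONE = 4.0


@dataclass
class LabelEnsemble:
    """Clash-free nitroxide midpoint positions for one labeled site."""

    site: tuple[str, int]
    positions: np.ndarray  # (n_accepted, 3) in A
    weights: np.ndarray  # sums to 1 when accessible
    n_attempted: int
    n_accepted: int

    @property
    def accessible(self) -> bool:
        return self.n_accepted > 0

    @property
    def acceptance_fraction(self) -> float:
        return self.n_accepted / self.n_attempted if self.n_attempted else 0.0

    def transformed(self, T) -> "LabelEnsemble":
        pos = T.apply(self.positions) if self.n_accepted else self.positions
        return LabelEnsemble(
            self.site, pos, self.weights, self.n_attempted, self.n_accepted
        )


@dataclass
class DistanceDistribution:
    """Probability density P(r) on a strictly increasing distance grid (A)."""

    r: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.p.shape:
            raise ValueError("r and p must be 1-D arrays of equal length")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be strictly increasing")
        if np.any(self.p < -1e-12):
            raise ValueError("density must be non-negative")

    def normalized(self) -> "DistanceDistribution":
        area = np.trapezoid(self.p, self.r)
        if area <= 0:
            raise ValueError("cannot normalize an all-zero density")
        return DistanceDistribution(self.r, self.p / area)

    @property
    def modal_distance(self) -> float:
        return modal_distance(self)

    @property
    def width_at_half_height(self) -> float:
        return width_at_half_height(self)


def default_r_grid(r_min: float = 10.0, r_max: float = 100.0, dr: float = 0.5):
    """PELDOR-relevant distance grid, 0.5 A bins from 10 to 100 A."""
    n = int(round((r_max - r_min) / dr))
    return r_min + dr * np.arange(n + 1)


# ---------------------------------------------------------------------------
# conformer construction
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond, angle_deg, dihedral_rad):
    """Natural-extension (NeRF) placement of the next chain atom."""
    theta = np.deg2rad(angle_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(dihedral_rad),
            bond * np.sin(theta) * np.sin(dihedral_rad),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _ideal_cb(n, ca, c):
    """Rebuild an ideal tetrahedral CB from backbone N, CA, C."""
    b1 = n - ca
    b2 = c - ca
    b1 = b1 / np.linalg.norm(b1)
    b2 = b2 / np.linalg.norm(b2)
    bis = b1 + b2
    bis = bis / np.linalg.norm(bis)
    perp = np.cross(b2, b1)
    perp = perp / np.linalg.norm(perp)
    # tetrahedral direction opposite the N/C bisector, tilted out of plane
    d = -np.sqrt(1.0 / 3.0) * bis + np.sqrt(2.0 / 3.0) * perp
    return ca + _CB_LENGTH * d


def _grow_conformer(rng, n_at, ca, c_at, cb, max_resample: int = 200):
    """One internally valid label conformer, or None if generation stalls.

    Atom order along the bond graph: N, CA, CB, then the grown chain.  Pairs
    three or more bonds apart obey the self-clash cutoffs; invalid draws are
    re-sampled (they are not rotamers at all, so they never count against a
    site's accessibility).
    """
    base = [n_at, ca, cb]
    for _ in range(max_resample):
        pts = list(base)
        a, b, c = n_at, ca, cb
        for _, bond, ang in _CHAIN_GEOMETRY:
            nxt = _place_atom(a, b, c, bond, ang, rng.uniform(0.0, 2.0 * np.pi))
            pts.append(nxt)
            a, b, c = b, c, nxt
        P = np.asarray(pts)
        ok = True
        n_tot = len(P)
        for i in range(n_tot):
            for j in range(i + 3, n_tot):
                cut = _SELF_CUTOFF
                if j == n_tot - 1 and i <= 1:  # ring vs backbone N/CA
                    cut = _RING_BACKBONE
                if np.linalg.norm(P[i] - P[j]) < cut:
                    ok = False
                    break
            if not ok:
                break
        if ok and np.linalg.norm(P[-1] - c_at) >= _RING_BACKBONE:
            return P[3:]  # grown pseudo-atoms only
    return None


def attach_label(
    structure: StructureModel,
    site: tuple[str, int],
    n_conformers: int = 200,
    clash_tolerance: float = 0.0,
    seed: int | None = None,
    return_chains: bool = False,
):
    """Sample an MTSSL nitroxide-midpoint ensemble at ``site``.

    ``n_conformers`` internally valid conformers are attempted; one is
    accepted when none of its pseudo-atoms lies closer than
    ``2 * 1.7 - clash_tolerance`` angstroms to any protein heavy atom outside
    the labeled residue.  Deterministic for a fixed ``seed``.  A site where no
    conformer survives is returned flagged inaccessible, not raised.
    """
    if seed is None:
        raise ValueError("labeling requires an explicit seed")
    chain_id, res_id = site
    try:
        n_at = structure.atom_coord(chain_id, res_id, "N")
        ca = structure.atom_coord(chain_id, res_id, "CA")
        c_at = structure.atom_coord(chain_id, res_id, "C")
    except KeyError as exc:
        raise ValueError(f"site {site} lacks backbone atoms: {exc}") from exc
    try:
        cb = structure.atom_coord(chain_id, res_id, "CB")
    except KeyError:
        cb = _ideal_cb(n_at, ca, c_at)

    env_mask = ~structure.residue_mask(chain_id, res_id)
    env = structure.coords[env_mask]
    tree = cKDTree(env) if env.shape[0] else None
    cutoff = 2.0 * _VDW_RADIUS - clash_tolerance

    rng = np.random.default_rng(seed)

    accepted = []
    chains = []
    for _ in range(n_conformers):
        pts = _grow_conformer(rng, n_at, ca, c_at, cb)
        if pts is None:
            continue
        ok = True
        if tree is not None and cutoff > 0:
            hits = tree.query_ball_point(pts, r=cutoff)
            ok = all(len(h) == 0 for h in hits)
        if ok:
            accepted.append(pts[-1])
            if return_chains:
                chains.append(pts)

    n_acc = len(accepted)
    positions = np.asarray(accepted, dtype=float).reshape(n_acc, 3)
    weights = (
        np.full(n_acc, 1.0 / n_acc) if n_acc else np.zeros(0)
    )
    ens = LabelEnsemble(site, positions, weights, n_conformers, n_acc)
    if return_chains:
        return ens, chains
    return ens


# ---------------------------------------------------------------------------
# distance distributions
# ---------------------------------------------------------------------------

def gaussian_kernel(sigma_bins: float) -> np.ndarray:
    """Normalized Gaussian smoothing kernel on histogram bins."""
    radius = max(int(np.ceil(3.0 * sigma_bins)), 1)
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma_bins) ** 2)
    return k / k.sum()


def ensemble_distance_distribution(
    a: LabelEnsemble,
    b: LabelEnsemble,
    r_grid: np.ndarray | None = None,
    smooth_bins: float = 0.0,
) -> DistanceDistribution:
    """Weighted histogram of all pairwise |a_i - b_j| distances on ``r_grid``.

    The grid points are bin centers; the returned density integrates to 1
    (trapezoid rule).  ``smooth_bins`` > 0 convolves the histogram with a
    Gaussian of that width (in bins) before normalizing - useful when the
    finite conformer sample makes the raw histogram jagged.
    """
    if not a.accessible or not b.accessible:
        raise ValueError("cannot form a distance distribution from an empty ensemble")
    r = default_r_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
    d = cdist(a.positions, b.positions).ravel()
    w = np.outer(a.weights, b.weights).ravel()
    dr = np.diff(r)
    if np.ptp(dr) > 1e-9 * dr[0]:
        raise ValueError("r grid must be uniform")
    half = dr[0] / 2.0
    if d.min() < r[0] - half or d.max() > r[-1] + half:
        raise ValueError(
            f"r grid [{r[0]}, {r[-1]}] does not cover distances "
            f"[{d.min():.1f}, {d.max():.1f}]"
        )
    edges = np.concatenate([r - half, [r[-1] + half]])
    counts, _ = np.histogram(d, bins=edges, weights=w)
    if smooth_bins > 0:
        counts = np.convolve(counts, gaussian_kernel(smooth_bins), mode="same")
    dist = DistanceDistribution(r, counts)
    return dist.normalized()


def distance_distribution_between_sites(
    structure: StructureModel,
    site_a: tuple[str, int],
    site_b: tuple[str, int],
    n_conformers: int = 200,
    clash_tolerance: float = 0.0,
    seed: int = 0,
    r_grid: np.ndarray | None = None,
) -> DistanceDistribution:
    """Label two sites of one structure and return their P(r)."""
    ea = attach_label(structure, site_a, n_conformers, clash_tolerance, seed)
    eb = attach_label(structure, site_b, n_conformers, clash_tolerance, seed)
    for e in (ea, eb):
        if not e.accessible:
            raise ValueError(f"site {e.site} is inaccessible to the label")
    return ensemble_distance_distribution(ea, eb, r_grid)


def modal_distance(dist: DistanceDistribution) -> float:
    """Grid distance at the global density maximum; ties break to smaller r."""
    if not np.any(dist.p > 0):
        raise ValueError("all-zero density has no modal distance")
    return float(dist.r[int(np.argmax(dist.p))])


def width_at_half_height(dist: DistanceDistribution) -> float:
    """Full width between the outermost crossings of half the peak maximum,
    linearly interpolated between grid points."""
    p, r = dist.p, dist.r
    if not np.any(p > 0):
        raise ValueError("all-zero density has no width")
    half = p.max() / 2.0
    above = np.flatnonzero(p >= half)
    i_lo, i_hi = above[0], above[-1]
    if i_lo == 0 or i_hi == len(r) - 1:
        warnings.warn(
            "density does not fall below half maximum inside the grid; "
            "width is truncated",
            RuntimeWarning,
        )
    if i_lo == 0:
        r_lo = r[0]
    else:
        f = (half - p[i_lo - 1]) / (p[i_lo] - p[i_lo - 1])
        r_lo = r[i_lo - 1] + f * (r[i_lo] - r[i_lo - 1])
    if i_hi == len(r) - 1:
        r_hi = r[-1]
    else:
        f = (p[i_hi] - half) / (p[i_hi] - p[i_hi + 1])
        r_hi = r[i_hi] + f * (r[i_hi + 1] - r[i_hi])
    return float(r_hi - r_lo)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_distribution(dist: DistanceDistribution, path) -> None:
    np.savetxt(path, np.column_stack([dist.r, dist.p]), header="r_A  P_per_A")


def read_distribution(path) -> DistanceDistribution:
    data = np.loadtxt(path)
    return DistanceDistribution(data[:, 0], data[:, 1])


def write_ensemble_xyz(ens: LabelEnsemble, path) -> None:
    """Nitroxide midpoints as a plain x/y/z table."""
    np.savetxt(
        path,
        ens.positions,
        header=f"site {ens.site[0]}{ens.site[1]}  "
        f"accepted {ens.n_accepted}/{ens.n_attempted}",
    )


def write_ensemble_pdb(ens: LabelEnsemble, path) -> None:
    """Midpoints as a multi-MODEL PDB of single pseudo-atoms."""
    lines = []
    for i, pos in enumerate(ens.positions, start=1):
        lines.append(f"MODEL     {i:4d}")
        lines.append(
            f"HETATM{1:5d}  NO  MTS {ens.site[0]:>1}{ens.site[1]:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00           N"
        )
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
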
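"""Synthetic fixtures: idealized helical dimers, distance distributions and
noisy PELDOR traces with full ground truth.

The generator stands in for real crystal structures: a protomer is a pair of
antiparallel ideal alpha-helices (backbone N, CA, C, O plus CB), and the
dimer's second protomer is the image of the first under a planted two-fold.
Every output carries machine-readable ground truth (the planted transform,
site-site distances, true distributions and trace parameters) so that each
pipeline stage can be tested by recovery rather than against prose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst

from .labeling import (
    DistanceDistribution,
    _ideal_cb,
    attach_label,
    default_r_grid,
    ensemble_distance_distribution,
)
from .structures import RigidTransform, StructureModel, apply_transform
from . import deer
from .docking import Restraint, RestraintSet

__all__ = [
    "SyntheticDimerSpec",
    "BenchmarkCase",
    "make_helical_dimer",
    "make_monomer",
    "make_distribution",
    "make_benchmark_case",
]

# canonical alpha-helix parameters
_RISE = 1.5  # A per residue along the axis
_TWIST = 100.0  # degrees per residue
_CA_RADIUS = 2.3  # A


def _default_transform() -> RigidTransform:
    # two-fold perpendicular to the helix axes, crossing mid-chain: the
    # protomers stack across the interface (~7 A closest heavy-atom
    # approach) and labeled sites sit on both sides of the axis, which makes
    # the docking problem well conditioned
    return RigidTransform.about_axis([1.0, 0.0, 0.0], np.pi, point=[0.0, 6.5, 21.75])


@dataclass
class SyntheticDimerSpec:
    """Geometry of the planted C2 helical dimer.

    ``n_residues`` is per helix; the protomer has two antiparallel helices,
    so the chain runs 1..2*n_residues.  ``sites`` are residue numbers that
    carry spin labels; the planted ``transform`` must be an exact involution.
    """

    n_residues: int = 30
    rise: float = _RISE
    twist: float = _TWIST
    radius: float = _CA_RADIUS
    transform: RigidTransform = field(default_factory=_default_transform)
    # surface residues chosen for informative geometry: inter-label modal
    # distances span ~39-55 A (the well-measurable PELDOR window) and the
    # site pattern constrains all four C2 degrees of freedom (worst-case
    # pose uncertainty ~1 A at the restraint resolution)
    sites: tuple[int, ...] = (3, 28, 29, 34, 59)
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 6:
            raise ValueError("need at least 6 residues per helix")
        if not self.transform.is_involution():
            raise ValueError("planted transform is not a two-fold (C2)")
        for s in self.sites:
            if not 1 <= s <= 2 * self.n_residues:
                raise ValueError(f"site {s} outside sequence 1..{2*self.n_residues}")


def _helix_backbone(n_res, rise, twist, radius, z_dir=1.0, origin=(0.0, 0.0, 0.0)):
    """Ideal helix backbone coordinates: per-residue N, CA, C, O, CB."""
    origin = np.asarray(origin, dtype=float)
    tw = np.deg2rad(twist) * z_dir

    def on_helix(i, phase, dz, r):
        ang = (i + phase) * tw
        return origin + np.array(
            [r * np.cos(ang), r * np.sin(ang) * z_dir, (i + dz) * rise * z_dir]
        )

    atoms = []
    for i in range(n_res):
        n = on_helix(i, -0.35, -0.35, 1.55)
        ca = on_helix(i, 0.0, 0.0, radius)
        c = on_helix(i, 0.38, 0.38, 1.65)
        radial = np.array([np.cos((i + 0.38) * tw), np.sin((i + 0.38) * tw) * z_dir, 0.0])
        o = c + 1.23 * radial
        cb = _ideal_cb(n, ca, c)
        atoms.append({"N": n, "CA": ca, "C": c, "O": o, "CB": cb})
    return atoms


def make_monomer(spec: SyntheticDimerSpec, chain_id: str = "A") -> StructureModel:
    """One protomer: two antiparallel ideal helices, residues 1..2n."""
    h1 = _helix_backbone(spec.n_residues, spec.rise, spec.twist, spec.radius)
    h2 = _helix_backbone(
        spec.n_residues,
        spec.rise,
        spec.twist,
        spec.radius,
        z_dir=-1.0,
        origin=(10.5, 0.0, (spec.n_residues - 1) * spec.rise),
    )
    names = ["N", "CA", "C", "O", "CB"]
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    records = []
    for res_off, helix in ((0, h1), (spec.n_residues, h2)):
        for i, res in enumerate(helix):
            for nm in names:
                records.append((res_off + i + 1, nm, res[nm]))
    coords = np.array([r[2] for r in records], dtype=np.float64)
    arr = bst.AtomArray(len(records))
    arr.coord = coords
    arr.chain_id = np.full(len(records), chain_id)
    arr.res_id = np.array([r[0] for r in records])
    arr.res_name = np.full(len(records), "ALA")
    arr.atom_name = np.array([r[1] for r in records])
    arr.element = np.array([elements[r[1]] for r in records])
    return StructureModel(arr, metadata="synthetic helical protomer", coord64=coords)


def make_helical_dimer(
    spec: SyntheticDimerSpec | None = None,
) -> tuple[StructureModel, dict]:
    """Planted C2 dimer plus its ground-truth record.

    The record holds the planted transform, per-site CA positions and the
    inter-protomer site-site CA distances recomputed from the emitted
    coordinates; ``interface_sites`` flags residues whose CA lies within 10 A
    of the partner protomer.
    """
    spec = spec or SyntheticDimerSpec()
    mono = make_monomer(spec, chain_id="A")
    partner = apply_transform(mono, spec.transform)
    arr_b = partner.array.copy()
    arr_b.chain_id = np.full(arr_b.array_length(), "B")
    from scipy.spatial.distance import cdist

    min_sep = cdist(mono.coords, partner.coords).min()
    if min_sep < 1.5:
        raise ValueError(
            f"planted transform overlaps the protomers (min separation {min_sep:.2f} A)"
        )
    dimer = StructureModel(
        mono.array + arr_b,
        metadata="synthetic C2 dimer",
        coord64=np.vstack([mono.coords, partner.coords]),
    )
    site_ca = {s: mono.atom_coord("A", s, "CA") for s in spec.sites}
    site_dist = {
        s: float(np.linalg.norm(site_ca[s] - spec.transform.apply(site_ca[s])))
        for s in spec.sites
    }
    ca_mask = mono.array.atom_name == "CA"
    ca_a = mono.coords[ca_mask]
    d_ab = cdist(ca_a, arr_b.coord)
    res_ids = mono.array.res_id[ca_mask]
    interface = {int(r): bool(d_ab[i].min() < 10.0) for i, r in enumerate(res_ids)}
    truth = {
        "transform": spec.transform,
        "site_ca": site_ca,
        "site_ca_distances": site_dist,
        "interface_sites": interface,
        "min_interprotomer_separation": float(min_sep),
        "spec": spec,
    }
    return dimer, truth


def make_distribution(kind: str, params: dict, r_grid=None) -> DistanceDistribution:
    """Analytic test distribution: gaussian, bimodal or rectangular.

    gaussian: mean, fwhm.  bimodal: means (2,), fwhms (2,), fractions (2,).
    rectangular: lo, hi.  Normalized on the grid; support must lie inside it.
    """
    r = default_r_grid() if r_grid is None else np.asarray(r_grid, dtype=float)

    def gauss(mean, fwhm):
        if not (r[0] < mean < r[-1]):
            raise ValueError(f"mean {mean} outside grid [{r[0]}, {r[-1]}]")
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((r - mean) / sigma) ** 2)

    if kind == "gaussian":
        p = gauss(params["mean"], params["fwhm"])
    elif kind == "bimodal":
        fr = params.get("fractions", (0.5, 0.5))
        p = fr[0] * gauss(params["means"][0], params["fwhms"][0]) + fr[1] * gauss(
            params["means"][1], params["fwhms"][1]
        )
    elif kind == "rectangular":
        lo, hi = params["lo"], params["hi"]
        if lo < r[0] or hi > r[-1] or lo >= hi:
            raise ValueError("rectangle support outside grid")
        p = ((r >= lo) & (r <= hi)).astype(float)
    else:
        raise ValueError(f"unknown distribution kind {kind!r}")
    return DistanceDistribution(r, p).normalized()


@dataclass
class BenchmarkCase:
    """End-to-end fixture with full ground truth."""

    dimer: StructureModel
    monomer: StructureModel
    truth: dict
    sites: tuple[int, ...]
    distributions: dict  # site -> true label-label DistanceDistribution
    modal: dict  # site -> true modal distance (A)
    width: dict  # site -> true width at half height (A)
    traces: dict  # site -> noisy DeerTrace
    restraints: RestraintSet
    label_cfg: dict  # labeling settings the restraint targets were measured with
    lam: float
    k: float
    noise_sd: float
    seed: int


def make_benchmark_case(
    seed: int = 0,
    lam: float = 0.3,
    k: float = 0.05,
    noise_sd: float = 0.005,
    n_conformers: int = 200,
    t_max: float = 8.0,
) -> BenchmarkCase:
    """Dimer + sites + true distributions + noisy traces + restraint table.

    The trace conditions (modulation depth 0.3, background 0.05 /us, noise sd
    0.005) emulate well-oscillating four-pulse PELDOR data of a labeled,
    detergent-solubilized dimer; all randomness derives from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    label_seed, *trace_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(9)]
    spec = SyntheticDimerSpec(seed=seed)
    dimer, truth = make_helical_dimer(spec)
    monomer = dimer.chain("A")
    # wider than the PELDOR default: interface-adjacent label clouds on the
    # compact synthetic dimer reach slightly below 10 A
    r_grid = default_r_grid(5.0, 100.0)
    distributions, modal, width, traces = {}, {}, {}, {}
    entries = []
    t_grid = deer.default_time_grid(t_max)
    for i, site in enumerate(spec.sites):
        ea = attach_label(dimer, ("A", site), n_conformers=n_conformers, seed=label_seed)
        eb = attach_label(dimer, ("B", site), n_conformers=n_conformers, seed=label_seed)
        # smoothed like the docking statistic, so the restraint table and the
        # docking energy measure the same quantity
        P = ensemble_distance_distribution(ea, eb, r_grid, smooth_bins=1.5)
        distributions[site] = P
        modal[site] = P.modal_distance
        width[site] = P.width_at_half_height
        traces[site] = deer.simulate_trace(
            P, t_grid, lam=lam, k=k, noise_sd=noise_sd, seed=trace_seeds[i]
        )
        entries.append(
            Restraint(site=("A", site), target=modal[site], width=width[site])
        )
    return BenchmarkCase(
        dimer=dimer,
        monomer=monomer,
        truth=truth,
        sites=spec.sites,
        distributions=distributions,
        modal=modal,
        width=width,
        traces=traces,
        restraints=RestraintSet(entries),
        label_cfg={
            "n_conformers": n_conformers,
            "clash_tolerance": 0.0,
            "seed": label_seed,
        },
        lam=lam,
        k=k,
        noise_sd=noise_sd,
        seed=seed,
    )
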
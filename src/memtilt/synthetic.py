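"""Synthetic trajectories, charge systems and correlated series with ground truth.

Every analysis stage in this package is tested against fixtures generated
here, because the quantities of interest (tilt angles, contact counts, sheet
potentials, order parameters, standard errors) can all be constructed with
known answers.  Fixtures use pseudo-atoms: no chemistry, no dynamics — every
in-scope analysis is purely geometric or electrostatic on coordinates and
charges.

The dimer generator builds a rigid two-lobed "receptor": two parallel lobes
(segments A and B) of body atoms with membrane-proximal (``PRX``) and
membrane-distal (``DST``) marker rings, optionally a block of engineered
inter-monomer contact pairs (``CPA``/``CPB``, one atom per monomer at a fixed
sub-cutoff distance), a flat slab of lipid pseudo-atoms (``P``, segment M)
below it, and optionally static protein–membrane contact pairs (``MCP``
atoms, which deliberately do not follow the tilt schedule so their count
stays exact).  Each frame the dimer is rigidly rotated about its proximal
centroid to a scheduled tilt (plus Gaussian angular noise) whose direction is
set by an azimuth: 0 deg tilts along the inter-monomer ("lateral") axis,
90 deg perpendicular to it ("forward", the default).

Scenario presets named after four receptor/membrane systems (+/-LPS,
+/-GluCer) carry scheduled tilts 33/15/57/19 deg with engineered contact
levels 337/165/322/187 and run counts 3/3/3/1, so the demo pipeline
reproduces the qualitative shapes of the reference analyses from synthetic
data; the presets are illustrative, not a simulation of the physics.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import Frame, Topology, Trajectory, AtomSelection

__all__ = [
    "TiltSegment",
    "DimerFixtureSpec",
    "BilayerFixtureSpec",
    "ChargeFixtureSpec",
    "ScheduleGapError",
    "gen_dimer_trajectory",
    "gen_bilayer",
    "gen_charge_system",
    "gen_ar1_series",
    "analytic_sheet_potential",
    "vmf_order_parameter",
    "PRESETS",
    "preset_spec",
]


class ScheduleGapError(ValueError):
    """Tilt schedule does not cover every frame exactly once."""


@dataclass(frozen=True)
class TiltSegment:
    """Constant-target schedule segment over frames [start, stop)."""

    start: int
    stop: int
    overall_deg: float
    azimuth_deg: float = 90.0  # 0 = lateral, 90 = forward


@dataclass
class DimerFixtureSpec:
    """Parameters of the rigid-dimer fixture (lengths in nm, angles in deg)."""

    n_frames: int = 200
    schedule: list[TiltSegment] = field(
        default_factory=lambda: [TiltSegment(0, 200, 0.0)])
    noise_deg: float = 2.0
    monomer_separation: float = 3.0
    lobe_length: float = 6.0
    contact_pairs: int = 0
    contact_distance: float = 0.55
    membrane_contact_pairs: int = 0
    clearance: float = 2.0
    lower_with_tilt: bool = False  # pivot height clearance*(1 - tilt/90)
    box: tuple[float, float, float] = (16.0, 16.0, 30.0)
    dt_ns: float = 1.0
    seed: int = 0


@dataclass
class BilayerFixtureSpec:
    """Parameters of the toy-bilayer fixture.

    ``composition`` mirrors the outer-leaflet mixture of the reference
    membrane (45 mol% cholesterol, 25 mol% sphingomyelin, 10 mol%
    glucosylceramide, 20 mol% phosphatidylcholine).  Every pseudo-lipid
    carries a ``P`` marker regardless of species — the fixture is geometric,
    not chemical.
    """

    lipids_per_leaflet: int = 100
    composition: dict[str, float] = field(default_factory=lambda: {
        "CHOL": 0.45, "SM": 0.25, "GCER": 0.10, "POPC": 0.20})
    separation: float = 4.8          # phosphate plane separation, nm
    kappa: float | None = 20.0       # vMF concentration; None = fully aligned
    jitter: float = 0.0              # per-atom Gaussian jitter SD, nm
    n_chain_atoms: int = 8
    chain_spacing: float = 0.13      # nm between successive chain atoms
    grid_spacing: float = 0.8        # nm between lipids in the leaflet plane
    n_frames: int = 1
    seed: int = 0


@dataclass
class ChargeFixtureSpec:
    """Planar charge sheets: list of (z offset from box center nm, e/nm^2)."""

    sheets: list[tuple[float, float]] = field(
        default_factory=lambda: [(-0.5, 1.0), (0.5, -1.0)])
    box: tuple[float, float, float] = (5.0, 5.0, 10.0)
    grid_n: int = 20                 # each sheet discretized as grid_n^2 charges
    require_neutral: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# dimer


def _validate_schedule(spec: DimerFixtureSpec) -> None:
    segs = sorted(spec.schedule, key=lambda s: s.start)
    pos = 0
    for seg in segs:
        if seg.start != pos:
            raise ScheduleGapError(
                f"schedule gap/overlap at frame {pos} (segment starts at {seg.start})"
            )
        if seg.stop <= seg.start:
            raise ScheduleGapError("empty schedule segment")
        pos = seg.stop
    if pos != spec.n_frames:
        raise ScheduleGapError(
            f"schedule covers frames up to {pos}, trajectory has {spec.n_frames}"
        )


def _segment_targets(spec: DimerFixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    theta = np.empty(spec.n_frames)
    azimuth = np.empty(spec.n_frames)
    for seg in spec.schedule:
        theta[seg.start:seg.stop] = seg.overall_deg
        azimuth[seg.start:seg.stop] = seg.azimuth_deg
    return theta, azimuth


def _rotation_to(u: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping +z onto the unit vector u (minimal rotation)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, u))
    axis = np.cross(z, u)
    s = float(np.linalg.norm(axis))
    if s < 1e-15:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def _dimer_template(spec: DimerFixtureSpec):
    """Body-frame atoms (proximal centroid at origin, long axis +z, A->B +x)."""
    names, resnames, segids, coords = [], [], [], []
    half = spec.monomer_separation / 2.0
    ring = 0.3
    for seg_id, xc in (("A", -half), ("B", half)):
        for marker, zc in (("PRX", 0.0), ("DST", spec.lobe_length)):
            for k in range(4):
                ang = np.pi / 2 * k
                coords.append([xc + ring * np.cos(ang), ring * np.sin(ang), zc])
                names.append(marker)
                resnames.append("MON" + seg_id)
                segids.append(seg_id)
        for z in np.arange(0.0, spec.lobe_length + 1e-9, 0.5):
            coords.append([xc, 0.0, z])
            names.append("CA")
            resnames.append("MON" + seg_id)
            segids.append(seg_id)
    # engineered inter-monomer contact pairs on a sparse grid above the lobes
    if spec.contact_pairs:
        spacing = 1.3
        side = 7
        placed = 0
        layer = 0
        while placed < spec.contact_pairs:
            for iy in range(side):
                for ix in range(side):
                    if placed >= spec.contact_pairs:
                        break
                    x = (ix - (side - 1) / 2) * spacing
                    y = (iy - (side - 1) / 2) * spacing
                    z = spec.lobe_length + 1.0 + layer * spacing
                    coords.append([x, y, z])
                    names.append("CPA")
                    resnames.append("MONA")
                    segids.append("A")
                    coords.append([x + spec.contact_distance, y, z])
                    names.append("CPB")
                    resnames.append("MONB")
                    segids.append("B")
                    placed += 1
                if placed >= spec.contact_pairs:
                    break
            layer += 1
    return (np.array(coords), np.array(names), np.array(resnames),
            np.array(segids))


def gen_dimer_trajectory(
    spec: DimerFixtureSpec,
) -> tuple[Trajectory, pd.DataFrame, dict[str, AtomSelection]]:
    """Generate the rigid-dimer fixture.

    Returns the trajectory, a ground-truth table (per frame: the true overall
    / lateral / forward angles, the signed scheduled+noise tilt, and the
    engineered contact counts), and ready-made selections for every analysis
    role.
    """
    _validate_schedule(spec)
    rng = np.random.default_rng(spec.seed)
    body, names_b, resnames_b, segids_b = _dimer_template(spec)
    box = np.asarray(spec.box, dtype=float)
    pivot_xy = box[:2] / 2.0
    pivot_z0 = 12.0 if box[2] >= 20 else box[2] / 2.0
    slab_z0 = pivot_z0 - spec.clearance

    # lipid slab
    slab_pts = []
    for x in np.arange(0.4, box[0], 0.8):
        for y in np.arange(0.4, box[1], 0.8):
            slab_pts.append([x, y, slab_z0])
    slab = np.array(slab_pts)
    names_m = np.array(["P"] * len(slab))
    resnames_m = np.array(["LIP"] * len(slab))
    segids_m = np.array(["M"] * len(slab))

    # static protein-side membrane-contact atoms above the first slab atoms
    n_mcp = spec.membrane_contact_pairs
    if n_mcp > len(slab):
        raise ValueError("more membrane contact pairs than slab atoms")
    mcp = slab[:n_mcp] + np.array([0.0, 0.0, spec.contact_distance])
    names_p = np.array(["MCP"] * n_mcp)
    resnames_p = np.array(["MONA"] * n_mcp)
    segids_p = np.array(["A"] * n_mcp)

    n_body = len(body)
    topo = Topology(
        names=np.concatenate([names_b, names_m, names_p]),
        resnames=np.concatenate([resnames_b, resnames_m, resnames_p]),
        resids=np.concatenate([
            np.ones(n_body, dtype=int),
            np.full(len(slab), 2, dtype=int),
            np.full(n_mcp, 3, dtype=int),
        ]),
        segids=np.concatenate([segids_b, segids_m, segids_p]),
    )

    theta_sched, azimuth = _segment_targets(spec)
    theta_noisy = theta_sched + rng.normal(0.0, spec.noise_deg, spec.n_frames)

    frames = []
    truth = {k: np.empty(spec.n_frames) for k in
             ("overall_deg", "lateral_deg", "forward_deg", "signed_tilt_deg")}
    for i in range(spec.n_frames):
        th = np.radians(theta_noisy[i])
        chi = np.radians(azimuth[i])
        u = np.array([np.sin(th) * np.cos(chi),
                      np.sin(th) * np.sin(chi),
                      np.cos(th)])
        rot = _rotation_to(u)
        if spec.lower_with_tilt:
            pivot_z = slab_z0 + spec.clearance * max(
                0.0, 1.0 - theta_sched[i] / 90.0)
        else:
            pivot_z = pivot_z0
        pivot = np.array([pivot_xy[0], pivot_xy[1], pivot_z])
        coords = np.concatenate([body @ rot.T + pivot, slab, mcp])
        frames.append(Frame(coords=coords, box=box.copy(),
                            time=i * spec.dt_ns))
        uz = abs(float(u[2]))
        truth["overall_deg"][i] = np.degrees(np.arccos(min(uz, 1.0)))
        truth["lateral_deg"][i] = np.degrees(np.arctan2(u[0], u[2]))
        truth["forward_deg"][i] = np.degrees(np.arctan2(u[1], u[2]))
        truth["signed_tilt_deg"][i] = theta_noisy[i]

    traj = Trajectory(topology=topo, frames=frames)
    table = pd.DataFrame({
        "frame": np.arange(spec.n_frames),
        "time_ns": traj.times,
        **truth,
        "n_dimer_contacts": np.full(spec.n_frames, spec.contact_pairs),
        "n_membrane_contacts": np.full(spec.n_frames, n_mcp),
    })

    def _sel(name: str, mask: np.ndarray) -> AtomSelection:
        return AtomSelection(name=name, indices=np.flatnonzero(mask))

    body_mask = np.zeros(topo.n_atoms, dtype=bool)
    body_mask[:n_body] = True
    selections = {
        "proximal": _sel("name PRX", topo.names == "PRX"),
        "distal": _sel("name DST", topo.names == "DST"),
        "monomer_a": _sel("segment A body", (topo.segids == "A") & body_mask),
        "monomer_b": _sel("segment B body", (topo.segids == "B") & body_mask),
        "ecd_a": _sel("segment A", topo.segids == "A"),
        "ecd_b": _sel("segment B", topo.segids == "B"),
        "protein": _sel("protein", topo.segids != "M"),
        "lipids": _sel("segment M", topo.segids == "M"),
    }
    return traj, table, selections


# ---------------------------------------------------------------------------
# bilayer


def vmf_order_parameter(kappa: float | None) -> float:
    """Analytic S of chain directions drawn from a von Mises–Fisher
    distribution with concentration kappa about the leaflet normal.

    E[cos^2 theta] = 1 - 2 coth(kappa)/kappa + 2/kappa^2, so
    S = (3 E[cos^2 theta] - 1)/2; kappa=None (perfect alignment) gives 1.
    """
    if kappa is None:
        return 1.0
    if kappa <= 0:
        raise ValueError("kappa must be positive (or None for aligned chains)")
    u2 = 1.0 - 2.0 / (kappa * np.tanh(kappa)) + 2.0 / kappa**2
    return float((3.0 * u2 - 1.0) / 2.0)


def _sample_vmf_cos(kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sample of cos(theta) for vMF on the sphere about +z."""
    xi = rng.random(n)
    return 1.0 + np.log(xi + (1.0 - xi) * np.exp(-2.0 * kappa)) / kappa


def gen_bilayer(
    spec: BilayerFixtureSpec,
) -> tuple[Trajectory, dict, dict[str, object]]:
    """Generate the toy-bilayer fixture.

    Each pseudo-lipid is a ``P`` phosphate marker on its leaflet plane plus a
    straight chain of carbons descending toward the bilayer center along a
    direction drawn from a vMF distribution about the inward normal.  Ground
    truth: the phosphate-plane separation and the analytic chain order
    parameter.
    """
    if spec.lipids_per_leaflet <= 0:
        raise ValueError("need at least one lipid per leaflet")
    fr_sum = sum(spec.composition.values())
    if abs(fr_sum - 1.0) > 1e-9:
        raise ValueError(f"composition fractions sum to {fr_sum}, not 1")
    if spec.separation <= 0:
        raise ValueError("phosphate plane separation must be positive")
    rng = np.random.default_rng(spec.seed)

    n = spec.lipids_per_leaflet
    side = int(np.ceil(np.sqrt(n)))
    lx = ly = side * spec.grid_spacing
    lz = spec.separation + 2.0 * (
        spec.n_chain_atoms * spec.chain_spacing) + 2.0
    box = np.array([lx, ly, lz])
    center_z = lz / 2.0

    # largest-remainder species counts per leaflet
    species = sorted(spec.composition)
    ideal = {s: spec.composition[s] * n for s in species}
    counts = {s: int(np.floor(ideal[s])) for s in species}
    remainder = sorted(species, key=lambda s: ideal[s] - counts[s], reverse=True)
    k = n - sum(counts.values())
    for s in remainder[:k]:
        counts[s] += 1
    species_per_lipid = [s for s in species for _ in range(counts[s])]

    names, resnames, resids, segids = [], [], [], []
    chains: list[np.ndarray] = []
    base_xy = []
    for j in range(n):
        base_xy.append([(j % side + 0.5) * spec.grid_spacing,
                        (j // side + 0.5) * spec.grid_spacing])
    base_xy = np.array(base_xy)

    atom_positions_per_frame = []
    resid = 0
    atom = 0
    static_meta_done = False
    for frame_i in range(spec.n_frames):
        coords = []
        resid = 0
        atom = 0
        for leaflet, sign, seg in (("upper", 1.0, "U"), ("lower", -1.0, "L")):
            plane_z = center_z + sign * spec.separation / 2.0
            inward = -sign  # chains descend toward the bilayer center
            if spec.kappa is None:
                cos_t = np.ones(n)
            else:
                cos_t = _sample_vmf_cos(spec.kappa, n, rng)
            phi = rng.random(n) * 2.0 * np.pi
            sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
            dirs = np.stack([
                sin_t * np.cos(phi),
                sin_t * np.sin(phi),
                inward * cos_t,
            ], axis=1)
            for j in range(n):
                resid += 1
                head = np.array([base_xy[j, 0], base_xy[j, 1], plane_z])
                lipid_atoms = [head]
                for c in range(1, spec.n_chain_atoms + 1):
                    lipid_atoms.append(head + c * spec.chain_spacing * dirs[j])
                if not static_meta_done:
                    sp = species_per_lipid[j]
                    names.append("P")
                    resnames.append(sp)
                    resids.append(resid)
                    segids.append(seg)
                    chain_idx = []
                    for c in range(1, spec.n_chain_atoms + 1):
                        names.append(f"C{c}")
                        resnames.append(sp)
                        resids.append(resid)
                        segids.append(seg)
                        chain_idx.append(atom + c)
                    chains.append(np.array(chain_idx))
                atom += 1 + spec.n_chain_atoms
                coords.extend(lipid_atoms)
        static_meta_done = True
        coords = np.array(coords)
        if spec.jitter > 0:
            coords = coords + rng.normal(0.0, spec.jitter, coords.shape)
        atom_positions_per_frame.append(coords)

    topo = Topology(names=np.array(names), resnames=np.array(resnames),
                    resids=np.array(resids), segids=np.array(segids))
    frames = [Frame(coords=c, box=box.copy(), time=float(i))
              for i, c in enumerate(atom_positions_per_frame)]
    traj = Trajectory(topology=topo, frames=frames)
    truth = {
        "thickness_nm": spec.separation,
        "s_analytic": vmf_order_parameter(spec.kappa),
    }
    phosphates = AtomSelection(name="name P",
                               indices=np.flatnonzero(topo.names == "P"))
    return traj, truth, {"phosphates": phosphates, "chains": chains}


# ---------------------------------------------------------------------------
# charge sheets


def analytic_sheet_potential(sheets: list[tuple[float, float]],
                             z: np.ndarray) -> np.ndarray:
    """Closed-form psi(z) in volts for ideal charge sheets.

    With the reference psi = dpsi/dz = 0 below every sheet,
    psi(z) = -(1/eps0) * sum_i sigma_i * max(z - z_i, 0).
    """
    from .electrostatics import E_OVER_EPS0_NM_VOLT
    z = np.asarray(z, dtype=float)
    psi = np.zeros_like(z)
    for z_i, sigma in sheets:
        psi -= E_OVER_EPS0_NM_VOLT * sigma * np.clip(z - z_i, 0.0, None)
    return psi


def gen_charge_system(
    spec: ChargeFixtureSpec, n_bins: int = 100,
) -> tuple[Trajectory, pd.DataFrame]:
    """Discretize charge sheets into point charges plus the analytic psi table.

    Each sheet becomes ``grid_n^2`` equal point charges on a regular xy grid
    at its z plane; the topology carries the per-atom charges.  The returned
    table holds the closed-form potential on the bin centers that
    ``charge_density_profile(..., n_bins=n_bins)`` will use.
    """
    box = np.asarray(spec.box, dtype=float)
    if spec.require_neutral:
        total = sum(s for _, s in spec.sheets)
        if abs(total) > 1e-12:
            raise ValueError(f"sheets are not globally neutral (sum {total})")
    names, resnames, resids, segids, coords, charges = [], [], [], [], [], []
    area = box[0] * box[1]
    for si, (z_off, sigma) in enumerate(spec.sheets):
        if abs(z_off) >= box[2] / 2.0:
            raise ValueError(f"sheet at z={z_off} lies outside the box")
        q = sigma * area / spec.grid_n**2
        z_abs = box[2] / 2.0 + z_off
        for iy in range(spec.grid_n):
            for ix in range(spec.grid_n):
                coords.append([(ix + 0.5) * box[0] / spec.grid_n,
                               (iy + 0.5) * box[1] / spec.grid_n,
                               z_abs])
                charges.append(q)
                names.append("Q")
                resnames.append("SHT")
                resids.append(si + 1)
                segids.append("Q")
    topo = Topology(names=np.array(names), resnames=np.array(resnames),
                    resids=np.array(resids), segids=np.array(segids),
                    charges=np.array(charges))
    frame = Frame(coords=np.array(coords), box=box, time=0.0)
    traj = Trajectory(topology=topo, frames=[frame])
    dz = box[2] / n_bins
    centers = (np.arange(n_bins) + 0.5) * dz - box[2] / 2.0
    table = pd.DataFrame({
        "z_nm": centers,
        "psi_V": analytic_sheet_potential(spec.sheets, centers),
    })
    return traj, table


# ---------------------------------------------------------------------------
# AR(1) series


def gen_ar1_series(n: int, phi: float, seed: int = 0) -> tuple[np.ndarray, float]:
    """Unit-marginal-variance AR(1) series plus the analytic SD of its mean.

    x_t = phi * x_{t-1} + eps_t with eps SD sqrt(1 - phi^2); the large-n
    standard error of the mean is sqrt((1 + phi) / ((1 - phi) * n)).
    """
    if not abs(phi) < 1:
        raise ValueError(f"AR(1) requires |phi| < 1, got {phi}")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    x0 = rng.normal()
    eps = rng.normal(0.0, np.sqrt(1.0 - phi * phi), n)
    x, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    analytic_ee = float(np.sqrt((1.0 + phi) / ((1.0 - phi) * n)))
    return x, analytic_ee


# ---------------------------------------------------------------------------
# presets


@dataclass(frozen=True)
class Preset:
    label: str
    tilt_deg: float
    contact_pairs: int
    n_runs: int


PRESETS: dict[str, Preset] = {
    "lps_glucer": Preset("+LPS +GluCer", 33.0, 337, 3),
    "nolps_glucer": Preset("-LPS +GluCer", 15.0, 165, 3),
    "lps_noglucer": Preset("+LPS -GluCer", 57.0, 322, 3),
    "nolps_noglucer": Preset("-LPS -GluCer", 19.0, 187, 1),
}


def preset_spec(name: str, n_frames: int = 200, noise_deg: float = 2.0,
                seed: int = 0) -> DimerFixtureSpec:
    """Fixture spec for one named scenario preset."""
    preset = PRESETS[name]
    return DimerFixtureSpec(
        n_frames=n_frames,
        schedule=[TiltSegment(0, n_frames, preset.tilt_deg)],
        noise_deg=noise_deg,
        contact_pairs=preset.contact_pairs,
        seed=seed,
    )
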
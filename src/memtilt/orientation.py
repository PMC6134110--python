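"""Orientation vectors and tilt decomposition of a membrane-protein dimer.

The extracellular-domain orientation is captured by three body-frame vectors:

* ``V1`` — the long axis, from the centroid of a membrane-proximal marker
  group to the centroid of a membrane-distal marker group;
* ``V2`` — the inter-monomer ("face") axis, the monomer-A → monomer-B centroid
  direction with its V1 component removed;
* ``V3 = V1 × V2`` — completing a right-handed frame.

The tilt of V1 relative to the membrane normal ``n`` (laboratory z by default)
is decomposed into three angles.  With ``u = V1`` expressed in an orthonormal
frame whose z axis is ``n`` and whose x axis is the *initial-frame* V2
projected into the membrane plane (fixed at the first frame of each run, so
that the reference does not co-rotate with the tilt it measures):

* ``overall = arccos(|u·n|)`` in [0, 90] degrees,
* ``lateral = atan2(u_x, u_z)`` signed, tilt within the dimer "face" plane,
* ``forward = atan2(u_y, u_z)`` signed, tilt out of the face plane.

These definitions force the identity
``tan^2(overall) = tan^2(lateral) + tan^2(forward)`` for every frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import AtomSelection, Frame, Trajectory

__all__ = [
    "TiltVectors",
    "TiltAngles",
    "TiltSeries",
    "AngleHistogram",
    "DegenerateGeometryError",
    "compute_tilt_vectors",
    "tilt_angles",
    "tilt_series",
    "angle_distribution",
]

_EPS = 1e-12


class DegenerateGeometryError(ValueError):
    """Coincident centroids make an orientation vector undefined."""


@dataclass(frozen=True)
class TiltVectors:
    """Unit body-frame vectors V1 (long axis), V2 (face axis), V3 = V1×V2."""

    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray


@dataclass(frozen=True)
class TiltAngles:
    """One frame's (overall, lateral, forward) tilt triple in degrees.

    ``saturated`` flags the degenerate case of the long axis lying exactly in
    the membrane plane, where lateral/forward are reported at their ±90 bound.
    """

    overall: float
    lateral: float
    forward: float
    saturated: bool = False


@dataclass
class TiltSeries:
    """Per-frame tilt angles for one run."""

    times: np.ndarray
    overall: np.ndarray
    lateral: np.ndarray
    forward: np.ndarray
    label: str = ""

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class AngleHistogram:
    """Normalized angle distribution (unit integral), optionally run-averaged."""

    edges: np.ndarray          # bin edges, degrees
    density: np.ndarray        # 1/degree
    window: float              # trailing fraction used
    n_runs: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    norm = float(np.linalg.norm(v))
    if norm < _EPS:
        raise DegenerateGeometryError(f"{what} has near-zero norm ({norm:g} nm)")
    return v / norm


def _centroid(frame: Frame, sel: AtomSelection) -> np.ndarray:
    if len(sel) == 0:
        raise ValueError(f"selection {sel.name!r} is empty")
    return frame.coords[sel.indices].mean(axis=0)


def compute_tilt_vectors(
    frame: Frame,
    proximal: AtomSelection,
    distal: AtomSelection,
    monomer_a: AtomSelection,
    monomer_b: AtomSelection,
) -> TiltVectors:
    """Build the V1–V3 body frame from centroid geometry of one frame."""
    v1 = _unit(
        _centroid(frame, distal) - _centroid(frame, proximal),
        "proximal->distal axis",
    )
    ab = _centroid(frame, monomer_b) - _centroid(frame, monomer_a)
    ab_perp = ab - np.dot(ab, v1) * v1
    v2 = _unit(ab_perp, "inter-monomer axis (after removing V1 component)")
    v3 = np.cross(v1, v2)
    v3 /= np.linalg.norm(v3)
    return TiltVectors(v1=v1, v2=v2, v3=v3)


def _plane_axes(normal: np.ndarray, lateral_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane x (lateral) and y (forward) axes from a reference direction."""
    x = lateral_ref - np.dot(lateral_ref, normal) * normal
    x = _unit(x, "lateral reference projected into the membrane plane")
    y = np.cross(normal, x)
    return x, y


def tilt_angles(
    vectors: TiltVectors,
    normal: np.ndarray = (0.0, 0.0, 1.0),
    lateral_ref: np.ndarray | None = None,
) -> TiltAngles:
    """Decompose V1's tilt relative to *normal* into (overall, lateral, forward).

    ``lateral_ref`` anchors the in-plane lateral direction; it defaults to this
    frame's own V2 (series analysis passes the first frame's V2 so the
    reference stays fixed per run).
    """
    n = _unit(np.asarray(normal, dtype=float), "membrane normal")
    if lateral_ref is None:
        lateral_ref = vectors.v2
    x, y = _plane_axes(n, np.asarray(lateral_ref, dtype=float))
    u = vectors.v1
    ux, uy, uz = float(np.dot(u, x)), float(np.dot(u, y)), float(np.dot(u, n))
    overall = float(np.degrees(np.arccos(min(abs(uz), 1.0))))
    if abs(uz) < _EPS:
        return TiltAngles(
            overall=90.0,
            lateral=float(np.sign(ux) or 1.0) * 90.0,
            forward=float(np.sign(uy) or 1.0) * 90.0,
            saturated=True,
        )
    lateral = float(np.degrees(np.arctan2(ux, uz)))
    forward = float(np.degrees(np.arctan2(uy, uz)))
    return TiltAngles(overall=overall, lateral=lateral, forward=forward)


def tilt_series(
    trajectory: Trajectory,
    proximal: AtomSelection,
    distal: AtomSelection,
    monomer_a: AtomSelection,
    monomer_b: AtomSelection,
    normal: np.ndarray = (0.0, 0.0, 1.0),
    label: str = "",
) -> TiltSeries:
    """Per-frame tilt decomposition over a trajectory.

    The lateral/forward reference frame is fixed from the first frame's V2.
    """
    if trajectory.n_frames == 0:
        raise ValueError("trajectory has no frames")
    first = compute_tilt_vectors(
        trajectory[0], proximal, distal, monomer_a, monomer_b
    )
    lateral_ref = first.v2
    overall = np.empty(trajectory.n_frames)
    lateral = np.empty(trajectory.n_frames)
    forward = np.empty(trajectory.n_frames)
    for i, frame in enumerate(trajectory):
        vec = compute_tilt_vectors(frame, proximal, distal, monomer_a, monomer_b)
        ang = tilt_angles(vec, normal=normal, lateral_ref=lateral_ref)
        overall[i], lateral[i], forward[i] = ang.overall, ang.lateral, ang.forward
    return TiltSeries(
        times=trajectory.times, overall=overall, lateral=lateral,
        forward=forward, label=label,
    )


def trailing_slice(n: int, window: float) -> slice:
    """Index slice selecting the trailing *window* fraction of *n* frames."""
    if not 0.0 < window <= 1.0:
        raise ValueError(f"window must be in (0, 1], got {window}")
    start = int(np.ceil((1.0 - window) * n))
    if start >= n:
        raise ValueError("trailing window contains no frames")
    return slice(start, n)


def angle_distribution(
    series: list[TiltSeries] | TiltSeries,
    component: str = "overall",
    window: float = 0.5,
    bin_width: float = 1.0,
) -> AngleHistogram:
    """Normalized histogram over the trailing window, averaged across runs.

    Each run's histogram is normalized to unit integral before bin-wise
    averaging, so the average also integrates to one and runs of different
    lengths carry equal weight.
    """
    if isinstance(series, TiltSeries):
        series = [series]
    if not series:
        raise ValueError("need at least one tilt series")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    windows = []
    for s in series:
        data = getattr(s, component)
        windows.append(np.asarray(data)[trailing_slice(len(s), window)])
    lo = min(w.min() for w in windows)
    hi = max(w.max() for w in windows)
    left = np.floor(lo / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((hi - left) / bin_width + 1e-9)))
    edges = left + bin_width * np.arange(n_bins + 1)
    dens = np.zeros(n_bins)
    for w in windows:
        h, _ = np.histogram(w, bins=edges, density=True)
        dens += h
    dens /= len(windows)
    return AngleHistogram(edges=edges, density=dens, window=window,
                         n_runs=len(windows))
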
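"""Lipid acyl-chain order parameters and bilayer thickness.

The order parameter of a vector v relative to the membrane normal n is
``S = <(3 cos^2 theta - 1)/2>`` with theta the angle between v and n, averaged
over lipids and frames; S ranges from -0.5 (perpendicular) through 0 (magic
angle / isotropic) to 1 (parallel).  Two modes:

* ``"cc"`` (default) — carbon-skeleton vectors C(i-1) -> C(i+1), usable when
  the topology lacks explicit hydrogens;
* ``"cd"`` — C–H bond vectors (the deuterium order parameter S_CD), requiring
  a hydrogen-partner map.

Bilayer thickness is the distance between the mean z of the upper- and
lower-leaflet phosphate planes, leaflets assigned per frame by the sign of z
relative to the selection's mean z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AtomSelection, Trajectory

__all__ = [
    "OrderProfile",
    "ThicknessSeries",
    "order_parameters",
    "order_parameter_of_vectors",
    "membrane_thickness",
]


@dataclass
class OrderProfile:
    """Order parameter per position index along the chain."""

    positions: np.ndarray      # carbon position index along the chain
    s: np.ndarray              # dimensionless, in [-0.5, 1.0]
    mode: str                  # "cc" or "cd"
    n_samples: np.ndarray      # vectors averaged per position


@dataclass
class ThicknessSeries:
    """Per-frame phosphate-plane separation (nm)."""

    times: np.ndarray
    thickness: np.ndarray
    n_flips: int = 0           # leaflet sign changes relative to frame 0

    def __len__(self) -> int:
        return len(self.times)


def order_parameter_of_vectors(vectors: np.ndarray,
                               normal: np.ndarray = (0.0, 0.0, 1.0)) -> float:
    """S = <(3 cos^2 theta - 1)/2> of a set of vectors against the normal."""
    v = np.asarray(vectors, dtype=float)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    norms = np.linalg.norm(v, axis=-1)
    if np.any(norms == 0):
        raise ValueError("zero-length vector in order-parameter input")
    cos = (v @ n) / norms
    return float(np.mean(1.5 * cos * cos - 0.5))


def _validate_chains(chains: list[np.ndarray], mode: str) -> list[np.ndarray]:
    out = []
    for chain in chains:
        arr = np.asarray(chain, dtype=np.int64)
        if arr.ndim != 1 or len(arr) < 3:
            raise ValueError("each chain needs >= 3 ordered atom indices")
        if len(np.unique(arr)) != len(arr):
            raise ValueError("duplicate atom index within a chain")
        out.append(arr)
    return out


def order_parameters(trajectory: Trajectory,
                     chains: list[np.ndarray],
                     normal: np.ndarray = (0.0, 0.0, 1.0),
                     mode: str = "cc",
                     h_partners: dict[int, list[int]] | None = None) -> OrderProfile:
    """Per-position order parameters averaged over lipids and frames.

    Parameters
    ----------
    chains:
        One ordered carbon-index list per lipid chain.  All chains contribute
        to the same positional profile; position ``i`` is the i-th carbon of
        the chain (0-based).  In "cc" mode positions 1..L-2 are defined.
    h_partners:
        Required in "cd" mode: map carbon index -> hydrogen atom indices.
    """
    if mode not in ("cc", "cd"):
        raise ValueError(f"mode must be 'cc' or 'cd', got {mode!r}")
    chains = _validate_chains(chains, mode)
    if mode == "cd" and not h_partners:
        raise ValueError("cd mode requires an h_partners map")
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    max_len = max(len(c) for c in chains)
    acc = np.zeros(max_len)
    cnt = np.zeros(max_len, dtype=np.int64)
    for frame in trajectory:
        x = frame.coords
        for chain in chains:
            if mode == "cc":
                vec = x[chain[2:]] - x[chain[:-2]]
                cos = (vec @ n) / np.linalg.norm(vec, axis=1)
                s = 1.5 * cos * cos - 0.5
                acc[1:len(chain) - 1] += s
                cnt[1:len(chain) - 1] += 1
            else:
                for pos, c in enumerate(chain):
                    partners = h_partners.get(int(c), [])
                    for h in partners:
                        vec = x[h] - x[c]
                        norm = np.linalg.norm(vec)
                        if norm == 0:
                            raise ValueError(f"zero-length C-H bond at atom {c}")
                        cosv = float(vec @ n) / norm
                        acc[pos] += 1.5 * cosv * cosv - 0.5
                        cnt[pos] += 1
    defined = cnt > 0
    s = np.full(max_len, np.nan)
    s[defined] = acc[defined] / cnt[defined]
    return OrderProfile(positions=np.flatnonzero(defined),
                        s=s[defined], mode=mode, n_samples=cnt[defined])


def membrane_thickness(trajectory: Trajectory,
                       phosphate_sel: AtomSelection) -> ThicknessSeries:
    """Phosphate-plane separation per frame.

    Leaflets are assigned by the sign of z relative to the selection's mean z
    each frame (mass-weighted when the topology carries masses).  Atoms whose
    leaflet sign differs from frame 0 are counted as flips and logged, not
    reassigned.
    """
    if len(phosphate_sel) == 0:
        raise ValueError("phosphate selection is empty")
    masses = trajectory.topology.masses
    w = None
    if masses is not None:
        w = masses[phosphate_sel.indices]
    thickness = np.empty(trajectory.n_frames)
    ref_sign = None
    n_flips = 0
    for i, frame in enumerate(trajectory):
        z = frame.coords[phosphate_sel.indices, 2]
        center = float(np.average(z, weights=w))
        upper = z > center
        lower = ~upper
        if not np.any(upper) or not np.any(lower):
            raise ValueError(
                "phosphate selection spans a single leaflet; need atoms on "
                "both sides of the membrane center"
            )
        if ref_sign is None:
            ref_sign = upper.copy()
        else:
            n_flips += int(np.count_nonzero(upper != ref_sign))
        thickness[i] = abs(float(z[upper].mean()) - float(z[lower].mean()))
    if n_flips:
        warnings.warn(f"{n_flips} leaflet sign changes relative to frame 0",
                      stacklevel=2)
    return ThicknessSeries(times=trajectory.times, thickness=thickness,
                           n_flips=n_flips)
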
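"""Complexation metrics on labeled coordinate frames.

Metrics mirror a coarse trajectory analysis of one siRNA duplex surrounded
by k triblock-copolymer chains: the duplex bending angle theta (180 deg =
rectilinear), donor/acceptor hydrogen-bond counts between segments, the
total buried surface (sum of isolated-partner SASAs minus complex SASA,
Shrake-Rupley), and the PLL-contact stoichiometry (a PLL residue counts as
complexed when its minimum heavy-atom distance to the siRNA is within
0.3 nm).  All coordinates are in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

SIRNA = "siRNA"
SEGMENTS = (SIRNA, "PEG", "PLL", "PLA")

#: van der Waals radii (nm) used when a PDB file carries no explicit radii
VDW_RADII_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
    "P": 0.180, "S": 0.180, "X": 0.185,
}

PROBE_RADIUS_NM = 0.14
HBOND_DIST_NM = 0.35  # donor--acceptor heavy-atom cutoff
HBOND_ANGLE_DEG = 150.0  # minimum donor-H-acceptor angle
PLL_CONTACT_NM = 0.30

__all__ = [
    "StructureFrame",
    "MetricResult",
    "theta_angle",
    "count_hbonds",
    "sasa",
    "buried_surface",
    "complexed_pll_count",
    "complexed_copolymer_count",
    "stoichiometry",
    "ensemble_metrics",
]


class FrameError(ValueError):
    """Structure frame missing atoms or labels a metric requires."""


@dataclass
class StructureFrame:
    """One labeled coordinate frame (nm).

    Arrays are parallel over atoms.  ``segment`` tags each atom as siRNA,
    PEG, PLL or PLA; ``h_parent`` points a hydrogen at its donor heavy atom
    (-1 for non-hydrogens), which is what the hydrogen-bond angle test
    needs.  Hydrogens are excluded from SASA and minimum-distance contacts.
    """

    coords: np.ndarray  # (n, 3) nm
    element: np.ndarray  # str
    resname: np.ndarray  # str
    resid: np.ndarray  # int; unique per residue within a chain
    chain: np.ndarray  # str
    segment: np.ndarray  # str in SEGMENTS
    radius: np.ndarray | None = None  # nm
    is_donor: np.ndarray | None = None
    is_acceptor: np.ndarray | None = None
    h_parent: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        n = len(self.coords)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise FrameError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise FrameError("coordinates must be finite")
        for name in ("element", "resname", "resid", "chain", "segment"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise FrameError(f"{name} length {len(arr)} != {n} atoms")
            setattr(self, name, arr)
        bad = set(np.unique(self.segment)) - set(SEGMENTS)
        if bad:
            raise FrameError(f"unknown segment tags: {sorted(bad)}")
        if self.radius is None:
            self.radius = np.array(
                [VDW_RADII_NM.get(e, VDW_RADII_NM["X"]) for e in self.element]
            )
        else:
            self.radius = np.asarray(self.radius, float)
            if np.any(self.radius[self.element != "H"] <= 0):
                raise FrameError("heavy-atom radii must be positive")
        for name in ("is_donor", "is_acceptor"):
            flags = getattr(self, name)
            setattr(
                self, name,
                np.zeros(n, bool) if flags is None else np.asarray(flags, bool),
            )
        if self.h_parent is None:
            self.h_parent = np.full(n, -1, int)
        else:
            self.h_parent = np.asarray(self.h_parent, int)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def heavy(self) -> np.ndarray:
        return self.element != "H"

    def select(self, mask: np.ndarray) -> "StructureFrame":
        """Sub-frame of the masked atoms (h_parent remapped; orphans dropped)."""
        idx = np.flatnonzero(mask)
        remap = np.full(self.n_atoms, -1, int)
        remap[idx] = np.arange(len(idx))
        hp = self.h_parent[idx].copy()
        keep = hp >= 0
        hp[keep] = remap[hp[keep]]
        return StructureFrame(
            coords=self.coords[idx], element=self.element[idx],
            resname=self.resname[idx], resid=self.resid[idx],
            chain=self.chain[idx], segment=self.segment[idx],
            radius=self.radius[idx], is_donor=self.is_donor[idx],
            is_acceptor=self.is_acceptor[idx], h_parent=hp,
        )

    def copolymer_chains(self) -> list[str]:
        """Chain ids carrying copolymer (non-siRNA) atoms, sorted."""
        return sorted(set(self.chain[self.segment != SIRNA]))


@dataclass
class MetricResult:
    """Per-frame metric bundle."""

    theta: float
    hbond_count: int
    buried_surface: float
    complexed_pll_residues: int
    complexed_copolymers: int
    copolymer_count: int


# ---------------------------------------------------------------------------
# theta bending angle
# ---------------------------------------------------------------------------

def _nucleotide_order(frame: StructureFrame, chain: str) -> np.ndarray:
    mask = (frame.chain == chain) & (frame.segment == SIRNA)
    return np.unique(frame.resid[mask])


def theta_angle(
    frame: StructureFrame, end_window: int = 2, mid_window: int = 2
) -> float:
    """Duplex bending angle in degrees; 180 means rectilinear.

    Vertex at the center of mass of the central ``mid_window`` base pairs,
    arms to the centers of mass of the ``end_window`` terminal nucleotides
    at each duplex end (both strands; the two strands are antiparallel, so
    the 5' end of one pairs with the 3' end of the other).
    """
    chains = sorted(set(frame.chain[frame.segment == SIRNA]))
    if not chains:
        raise FrameError("no siRNA atoms in frame")
    groups: dict[str, list[np.ndarray]] = {"end_a": [], "mid": [], "end_b": []}
    for ci, chain in enumerate(chains):
        resids = _nucleotide_order(frame, chain)
        if len(resids) < max(2 * end_window, mid_window):
            raise FrameError("too few nucleotides to resolve end/middle groups")
        # orient both strands along the same duplex direction (antiparallel:
        # strand 2's resid order runs opposite), so windows pair by position
        seq = resids if ci == 0 else resids[::-1]
        end_a, end_b = seq[:end_window], seq[-end_window:]
        c0 = len(seq) // 2
        mid = seq[c0 - mid_window // 2: c0 - mid_window // 2 + mid_window]
        sel = (frame.chain == chain) & (frame.segment == SIRNA) & frame.heavy
        for key, rset in (("end_a", end_a), ("mid", mid), ("end_b", end_b)):
            m = sel & np.isin(frame.resid, rset)
            groups[key].append(frame.coords[m])
    coms = {k: np.concatenate(v).mean(axis=0) for k, v in groups.items()}
    u = coms["end_a"] - coms["mid"]
    v = coms["end_b"] - coms["mid"]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise FrameError("degenerate geometry: coincident group centers")
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def count_hbonds(
    frame: StructureFrame,
    between: tuple[str, str] = (SIRNA, "PLL"),
    dist_cutoff: float = HBOND_DIST_NM,
    angle_cutoff: float = HBOND_ANGLE_DEG,
) -> int:
    """Hydrogen bonds between two segments (or segment groups).

    A donor-acceptor pair counts when the heavy-atom distance is within
    ``dist_cutoff`` and some hydrogen of the donor makes a donor-H-acceptor
    angle of at least ``angle_cutoff`` degrees.  Each element of ``between``
    may be a segment name or a tuple of names; the count is symmetric in
    the order of the two sides.
    """
    sides = []
    for seg in between:
        segs = (seg,) if isinstance(seg, str) else tuple(seg)
        sides.append(np.isin(frame.segment, segs))
    donors_any = frame.is_donor.any()
    acceptors_any = frame.is_acceptor.any()
    if not (donors_any and acceptors_any):
        warnings.warn("no donor/acceptor flags set; hydrogen-bond count is 0")
        return 0

    h_idx = np.flatnonzero(frame.h_parent >= 0)
    h_by_parent: dict[int, list[int]] = {}
    for h in h_idx:
        h_by_parent.setdefault(int(frame.h_parent[h]), []).append(int(h))

    passes = [(sides[0], sides[1])]
    if not np.array_equal(sides[0], sides[1]):
        passes.append((sides[1], sides[0]))
    count = 0
    for a_mask, b_mask in passes:
        don = np.flatnonzero(a_mask & frame.is_donor & frame.heavy)
        acc = np.flatnonzero(b_mask & frame.is_acceptor & frame.heavy)
        if len(don) == 0 or len(acc) == 0:
            continue
        tree = cKDTree(frame.coords[acc])
        for d in don:
            near = tree.query_ball_point(frame.coords[d], dist_cutoff)
            hs = h_by_parent.get(int(d), [])
            for j in near:
                a = acc[j]
                for h in hs:
                    dh = frame.coords[h] - frame.coords[d]
                    ha = frame.coords[a] - frame.coords[h]
                    # angle at H between D->H and H->A; 180 deg = linear
                    c = np.clip(
                        -dh @ ha / (np.linalg.norm(dh) * np.linalg.norm(ha)),
                        -1, 1,
                    )
                    if np.degrees(np.arccos(c)) >= angle_cutoff:
                        count += 1
                        break
    return count


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere point set."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    frame: StructureFrame,
    probe_radius: float = PROBE_RADIUS_NM,
    n_points: int = 960,
) -> float:
    """Solvent-accessible surface area (nm^2) of the heavy atoms.

    Shrake-Rupley sphere sampling with a fixed Fibonacci point set, so the
    result is deterministic for a given frame.
    """
    heavy = frame.heavy
    xyz = frame.coords[heavy]
    if len(xyz) == 0:
        raise FrameError("no heavy atoms for SASA")
    rad = frame.radius[heavy] + probe_radius
    pts = _fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    rmax = rad.max()
    total = 0.0
    for i in range(len(xyz)):
        surf = xyz[i] + rad[i] * pts
        nbr = [j for j in tree.query_ball_point(xyz[i], rad[i] + rmax) if j != i]
        if nbr:
            d = np.linalg.norm(surf[:, None, :] - xyz[nbr][None, :, :], axis=2)
            exposed = np.all(d >= rad[nbr][None, :], axis=1)
            n_exp = int(exposed.sum())
        else:
            n_exp = n_points
        total += 4.0 * np.pi * rad[i] ** 2 * n_exp / n_points
    return float(total)


def buried_surface(
    frame: StructureFrame,
    probe_radius: float = PROBE_RADIUS_NM,
    n_points: int = 960,
) -> float:
    """Total buried surface (nm^2) between the siRNA and every copolymer.

    SASA(siRNA alone) + sum_k SASA(copolymer k alone) - SASA(complex);
    each copolymer chain is isolated by its chain id.  Clipped at zero
    (sampling noise can give a tiny negative value for non-contacting
    partners).
    """
    if frame.radius is None:
        raise FrameError("radii required for SASA")
    parts = [frame.select(frame.segment == SIRNA)]
    for ch in frame.copolymer_chains():
        parts.append(frame.select((frame.chain == ch) & (frame.segment != SIRNA)))
    isolated = sum(sasa(p, probe_radius, n_points) for p in parts)
    together = sasa(frame, probe_radius, n_points)
    return max(isolated - together, 0.0)


# ---------------------------------------------------------------------------
# PLL contact stoichiometry
# ---------------------------------------------------------------------------

def _pll_contact_residues(
    frame: StructureFrame, cutoff: float
) -> set[tuple[str, int]]:
    sirna = frame.heavy & (frame.segment == SIRNA)
    pll = frame.heavy & (frame.segment == "PLL")
    if not pll.any():
        raise FrameError("no PLL atoms in frame")
    if not sirna.any():
        raise FrameError("no siRNA atoms in frame")
    tree = cKDTree(frame.coords[sirna])
    dmin, _ = tree.query(frame.coords[pll])
    idx = np.flatnonzero(pll)
    hit = idx[dmin <= cutoff]
    return {(c, int(r)) for c, r in zip(frame.chain[hit], frame.resid[hit])}


def complexed_pll_count(frame: StructureFrame, cutoff: float = PLL_CONTACT_NM) -> int:
    """PLL residues whose minimum heavy-atom distance to the siRNA is <= cutoff."""
    return len(_pll_contact_residues(frame, cutoff))


def complexed_copolymer_count(
    frame: StructureFrame, cutoff: float = PLL_CONTACT_NM
) -> int:
    """Copolymer chains with at least one complexed PLL residue.

    0 for a frame with no copolymer chains at all (nothing to complex).
    """
    if not frame.copolymer_chains():
        return 0
    return len({chain for chain, _ in _pll_contact_residues(frame, cutoff)})


def stoichiometry(
    frames: list[StructureFrame], cutoff: float = PLL_CONTACT_NM
) -> float:
    """Mean complexed copolymers per siRNA over an ensemble of frames."""
    if not frames:
        raise FrameError("empty ensemble")
    return float(np.mean([complexed_copolymer_count(f, cutoff) for f in frames]))


# ---------------------------------------------------------------------------
# ensemble table
# ---------------------------------------------------------------------------

def frame_metrics(frame: StructureFrame, **kwargs) -> MetricResult:
    """All complexation metrics of one frame."""
    has_cop = bool(frame.copolymer_chains())
    return MetricResult(
        theta=theta_angle(frame),
        hbond_count=count_hbonds(frame, **kwargs.get("hbond", {})) if has_cop else 0,
        buried_surface=buried_surface(frame),
        complexed_pll_residues=complexed_pll_count(frame) if has_cop else 0,
        complexed_copolymers=complexed_copolymer_count(frame),
        copolymer_count=len(frame.copolymer_chains()),
    )


def ensemble_metrics(frames: list[StructureFrame]) -> pd.DataFrame:
    """Per-frame metric table; report mean +/- SD over it as the ensemble value."""
    rows = []
    for i, f in enumerate(frames):
        m = frame_metrics(f)
        rows.append({
            "frame": i, "theta_deg": m.theta, "hbonds": m.hbond_count,
            "buried_nm2": m.buried_surface,
            "complexed_pll": m.complexed_pll_residues,
            "complexed_copolymers": m.complexed_copolymers,
            "copolymer_count": m.copolymer_count,
        })
    return pd.DataFrame(rows)
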
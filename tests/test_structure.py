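"""Trajectory complexation metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest

from micellekit import (
    StructureFrame,
    buried_surface,
    complexed_copolymer_count,
    complexed_pll_count,
    count_hbonds,
    ensemble_metrics,
    sasa,
    stoichiometry,
    theta_angle,
)
from micellekit.structure import SIRNA, FrameError, PLL_CONTACT_NM
from micellekit.synthetic import GeneratorConfig, gen_helix_complex


# ---------------------------------------------------------------------------
# helpers: tiny hand-built frames and oracles
# ---------------------------------------------------------------------------

def make_frame(coords, segment, element=None, donor=None, acceptor=None,
               h_parent=None, resid=None, chain=None, radius=None):
    n = len(coords)
    return StructureFrame(
        coords=np.asarray(coords, float),
        element=np.array(element if element is not None else ["C"] * n),
        resname=np.array(["X"] * n),
        resid=np.array(resid if resid is not None else np.arange(1, n + 1)),
        chain=np.array(chain if chain is not None else ["A"] * n),
        segment=np.array(segment),
        radius=radius,
        is_donor=donor, is_acceptor=acceptor, h_parent=h_parent,
    )


def triplet_frame(end_a, mid, end_b):
    """Minimal two-strand duplex whose three theta groups sit at given points."""
    coords, resids, chains = [], [], []
    for point in (end_a, end_a, mid, mid, end_b, end_b):
        coords.append(point)
    # strand A resids 1..6 ascending; strand B spans the same positions reversed
    return make_frame(
        coords + coords[::-1],
        segment=[SIRNA] * 12,
        resid=list(range(1, 7)) + list(range(1, 7)),
        chain=["A"] * 6 + ["B"] * 6,
    )


def brute_force_hbonds(frame, seg_a, seg_b, dmax=0.35, amin=150.0):
    count = 0
    pairs = [(seg_a, seg_b), (seg_b, seg_a)]
    for sa, sb in pairs:
        for d in range(frame.n_atoms):
            if frame.segment[d] != sa or not frame.is_donor[d]:
                continue
            hs = [h for h in range(frame.n_atoms) if frame.h_parent[h] == d]
            for a in range(frame.n_atoms):
                if frame.segment[a] != sb or not frame.is_acceptor[a]:
                    continue
                if frame.element[a] == "H" or frame.element[d] == "H":
                    continue
                if np.linalg.norm(frame.coords[d] - frame.coords[a]) > dmax:
                    continue
                for h in hs:
                    v1 = frame.coords[d] - frame.coords[h]
                    v2 = frame.coords[a] - frame.coords[h]
                    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(c, -1, 1)))
                    if ang >= amin:
                        count += 1
                        break
    return count


def brute_force_pll_contacts(frame, cutoff=PLL_CONTACT_NM):
    residues = set()
    for i in range(frame.n_atoms):
        if frame.segment[i] != "PLL" or frame.element[i] == "H":
            continue
        for j in range(frame.n_atoms):
            if frame.segment[j] != SIRNA or frame.element[j] == "H":
                continue
            if np.linalg.norm(frame.coords[i] - frame.coords[j]) <= cutoff:
                residues.add((frame.chain[i], int(frame.resid[i])))
                break
    return len(residues)


def two_sphere_sasa(r1, r2, d, probe):
    """Closed-form SASA of two partially overlapping spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * (R1**2 + R2**2)
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
    return 4 * np.pi * (R1**2 + R2**2) - 2 * np.pi * (R1 * h1 + R2 * h2)


def random_isometry(rng):
    q = rng.normal(size=(3, 3))
    rot, _ = np.linalg.qr(q)
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    shift = rng.normal(scale=5.0, size=3)
    return rot, shift


def transform(frame, rot, shift):
    out = frame.select(np.ones(frame.n_atoms, bool))
    out.coords = frame.coords @ rot.T + shift
    return out


# ---------------------------------------------------------------------------
# theta
# ---------------------------------------------------------------------------

class TestTheta:
    def test_collinear_centers_give_180(self):
        f = triplet_frame([0, 0, 2.0], [0, 0, 1.0], [0, 0, 0.0])
        assert theta_angle(f) == pytest.approx(180.0)

    def test_right_angle(self):
        f = triplet_frame([1.0, 0, 0], [0, 0, 0], [0, 1.0, 0])
        assert theta_angle(f) == pytest.approx(90.0)

    def test_coincident_centers_rejected(self):
        f = triplet_frame([0, 0, 0], [0, 0, 0], [0, 0, 1.0])
        with pytest.raises(FrameError):
            theta_angle(f)

    def test_straight_synthetic_helix(self):
        f = gen_helix_complex(k_copolymers=0)
        assert theta_angle(f) == pytest.approx(180.0, abs=2.0)

    @pytest.mark.parametrize("beta", [10.0, 30.0, 60.0])
    def test_prescribed_bend(self, beta):
        f = gen_helix_complex(k_copolymers=0, bend_deg=beta)
        assert theta_angle(f) == pytest.approx(180.0 - beta, abs=3.0)

    def test_requires_sirna_atoms(self):
        f = make_frame([[0, 0, 0]], segment=["PLL"])
        with pytest.raises(FrameError):
            theta_angle(f)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

class TestHbonds:
    def _dha_frame(self, angle_deg, da_dist=0.29):
        """Donor (siRNA) + its H + acceptor (PLL) at a set D-H-A angle."""
        d = np.array([0.0, 0.0, 0.0])
        h = np.array([0.10, 0.0, 0.0])
        # acceptor placed so that the D-H-A angle is as requested
        back = np.deg2rad(180.0 - angle_deg)
        ha = 0.19 if angle_deg > 120 else 0.15
        a = h + ha * np.array([np.cos(back), np.sin(back), 0.0])
        if angle_deg == 180.0:
            a = np.array([da_dist, 0.0, 0.0])
        return make_frame(
            [d, h, a],
            segment=[SIRNA, SIRNA, "PLL"],
            element=["N", "H", "O"],
            donor=[True, False, False],
            acceptor=[False, False, True],
            h_parent=[-1, 0, -1],
            chain=["A", "A", "C1"],
        )

    def test_linear_pair_counts_once(self):
        assert count_hbonds(self._dha_frame(180.0)) == 1

    def test_bent_pair_rejected(self):
        assert count_hbonds(self._dha_frame(90.0)) == 0

    def test_distance_cutoff(self):
        far = self._dha_frame(180.0, da_dist=0.40)
        assert count_hbonds(far) == 0

    def test_symmetric_in_segment_order(self):
        f = self._dha_frame(180.0)
        assert count_hbonds(f, (SIRNA, "PLL")) == count_hbonds(f, ("PLL", SIRNA))

    def test_no_flags_warns_and_returns_zero(self):
        f = make_frame([[0, 0, 0], [0.2, 0, 0]], segment=[SIRNA, "PLL"])
        with pytest.warns(UserWarning):
            assert count_hbonds(f) == 0

    def test_matches_brute_force_on_random_frames(self, rng):
        for _ in range(5):
            n = 50
            coords = rng.uniform(0, 1.2, size=(n, 3))
            segment = rng.choice([SIRNA, "PLL"], size=n)
            element = rng.choice(["N", "O", "C"], size=n)
            donor = (element == "N") & (rng.random(n) < 0.7)
            acceptor = np.isin(element, ["N", "O"])
            h_parent = np.full(n, -1)
            # hang an H off half the donors by stealing carbon atoms
            carbons = np.flatnonzero(element == "C")
            for d, c in zip(np.flatnonzero(donor), carbons):
                element[c] = "H"
                h_parent[c] = d
                coords[c] = coords[d] + rng.normal(scale=0.07, size=3)
                donor[c] = acceptor[c] = False
            f = make_frame(coords, segment=segment, element=element,
                           donor=donor, acceptor=acceptor, h_parent=h_parent)
            assert count_hbonds(f) == brute_force_hbonds(f, SIRNA, "PLL")


# ---------------------------------------------------------------------------
# SASA / buried surface
# ---------------------------------------------------------------------------

class TestSasa:
    def test_isolated_sphere_closed_form(self):
        f = make_frame([[0, 0, 0]], segment=[SIRNA], radius=[0.2])
        expected = 4 * np.pi * (0.2 + 0.14) ** 2
        assert sasa(f) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("d", [0.30, 0.45, 0.60])
    def test_two_sphere_overlap_closed_form(self, d):
        f = make_frame([[0, 0, 0], [d, 0, 0]], segment=[SIRNA] * 2,
                       radius=[0.2, 0.17])
        expected = two_sphere_sasa(0.2, 0.17, d, 0.14)
        assert sasa(f) == pytest.approx(expected, rel=0.01)

    def test_distant_partners_bury_nothing(self):
        f = gen_helix_complex(k_copolymers=2, wrap_fraction=0.0, n_complexed=0)
        assert buried_surface(f, n_points=240) == pytest.approx(0.0, abs=0.3)

    def test_monotone_approach(self):
        # translating one copolymer from far away into contact can only
        # increase the buried surface
        base = gen_helix_complex(k_copolymers=1, wrap_fraction=1.0)
        cop = base.segment != SIRNA
        areas = []
        for offset in (5.0, 1.0, 0.3, 0.0):
            f = base.select(np.ones(base.n_atoms, bool))
            f.coords = base.coords.copy()
            f.coords[cop] += np.array([offset, 0.0, 0.0])
            areas.append(buried_surface(f, n_points=240))
        assert areas == sorted(areas)
        assert areas[0] == pytest.approx(0.0, abs=0.3)
        assert areas[-1] > 3.0

    def test_agrees_with_independent_implementation(self, rng):
        # cross-check the kernel against biotite's Shrake-Rupley on a
        # random cluster (same radii, same probe; different point sets)
        import biotite.structure as struc

        n = 30
        coords = rng.uniform(0, 1.0, size=(n, 3))
        radii = rng.uniform(0.15, 0.2, size=n)
        f = make_frame(coords, segment=[SIRNA] * n, radius=radii)
        mine = sasa(f)
        atoms = struc.AtomArray(n)
        atoms.coord = coords * 10.0
        atoms.element = np.array(["C"] * n)
        ref = struc.sasa(atoms, probe_radius=1.4, vdw_radii=radii * 10.0,
                         point_number=960).sum() / 100.0  # A^2 -> nm^2
        assert mine == pytest.approx(ref, rel=0.01)

    def test_missing_radii_rejected(self):
        f = make_frame([[0, 0, 0]], segment=[SIRNA], radius=[0.2])
        f.radius = None
        with pytest.raises(FrameError):
            buried_surface(f)


# ---------------------------------------------------------------------------
# PLL contacts and stoichiometry
# ---------------------------------------------------------------------------

class TestPllContacts:
    def test_far_copolymers_not_complexed(self):
        f = gen_helix_complex(k_copolymers=3, wrap_fraction=0.0, n_complexed=0)
        assert complexed_pll_count(f) == 0
        assert complexed_copolymer_count(f) == 0

    def test_single_bead_within_cutoff(self):
        f = make_frame(
            [[0, 0, 0], [0.25, 0, 0]],
            segment=[SIRNA, "PLL"],
            element=["P", "N"],
            chain=["A", "C1"],
        )
        assert complexed_pll_count(f) == 1

    def test_fully_wrapped_copolymer(self):
        f = gen_helix_complex(k_copolymers=1, wrap_fraction=1.0)
        assert complexed_pll_count(f) == 10
        assert complexed_copolymer_count(f) == 1

    def test_matches_brute_force_on_random_frames(self, rng):
        for _ in range(5):
            n = 120
            coords = rng.uniform(0, 1.5, size=(n, 3))
            segment = rng.choice([SIRNA, "PLL", "PEG"], size=n)
            if not (segment == "PLL").any():
                segment[0] = "PLL"
            if not (segment == SIRNA).any():
                segment[1] = SIRNA
            resid = rng.integers(1, 20, size=n)
            chain = np.where(segment == SIRNA, "A", "C1")
            f = make_frame(coords, segment=segment, resid=resid, chain=chain)
            assert complexed_pll_count(f) == brute_force_pll_contacts(f)

    def test_no_pll_rejected(self):
        f = make_frame([[0, 0, 0]], segment=[SIRNA])
        with pytest.raises(FrameError):
            complexed_pll_count(f)

    def test_ensemble_stoichiometry(self):
        frames = [
            gen_helix_complex(k_copolymers=4, wrap_fraction=0.5,
                              n_complexed=nc, cfg=GeneratorConfig(seed=s))
            for s, nc in ((1, 4), (2, 3))
        ]
        assert stoichiometry(frames) == pytest.approx(3.5)


# ---------------------------------------------------------------------------
# rigid-motion invariance and the ensemble table
# ---------------------------------------------------------------------------

class TestInvariance:
    def test_metrics_invariant_under_isometry(self, rng):
        f = gen_helix_complex(k_copolymers=2, wrap_fraction=0.5,
                              cfg=GeneratorConfig(seed=7))
        rot, shift = random_isometry(rng)
        g = transform(f, rot, shift)
        # arccos is ill-conditioned near 180 deg: sqrt(eps)-level wobble
        assert theta_angle(g) == pytest.approx(theta_angle(f), rel=1e-6, abs=1e-5)
        assert count_hbonds(g) == count_hbonds(f)
        assert complexed_pll_count(g) == complexed_pll_count(f)
        # SASA sampling grid is not rotation-invariant: allow sampling noise
        assert buried_surface(g, n_points=240) == pytest.approx(
            buried_surface(f, n_points=240), rel=0.05, abs=0.3
        )


def test_ensemble_table_columns():
    frames = [gen_helix_complex(k_copolymers=1, wrap_fraction=1.0,
                                cfg=GeneratorConfig(seed=s)) for s in (0, 1)]
    df = ensemble_metrics(frames)
    assert list(df.columns) == ["frame", "theta_deg", "hbonds", "buried_nm2",
                                "complexed_pll", "complexed_copolymers",
                                "copolymer_count"]
    assert len(df) == 2
    assert (df["complexed_copolymers"] == 1).all()
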
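"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator returns its data object together with a machine-readable
ground-truth dict, so recovery tests read truth only from there.  The same
seed reproduces the same output bit-for-bit.

Generated worlds:

* ITC thermograms — Gaussian power pulses whose areas equal the one-site
  model heats for the micelle-into-siRNA schedule (cell 0.05 mM phosphate,
  syringe 3 mM amine), on a linearly drifting baseline with white noise.
* Idealized siRNA/copolymer frames — a straight B-form-like duplex (rise
  0.34 nm, twist 36 deg/bp) at one pseudo-atom-per-moiety resolution
  (phosphate, sugar, base), plus bead-chain copolymers (45 PEG + 10 PLL +
  25 PLA beads) wrapping a set fraction of their PLL beads onto the
  phosphate backbone; optional global bend of the duplex axis.
* Quadratic-trend metric series — truth polynomial plus iid Gaussian noise.
* Electropherograms — Gaussian siRNA peak at 260 nm with area proportional
  to concentration and an internal-standard peak at 210 nm, on a noisy
  baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cze import Electropherogram
from .itc import InjectionSchedule, Thermogram, one_site_heat_curve, J_PER_UCAL
from .saturation import MetricSeries
from .structure import SIRNA, StructureFrame

__all__ = [
    "GeneratorConfig",
    "gen_itc_thermogram",
    "gen_helix_complex",
    "gen_metric_series",
    "gen_electropherogram",
]

#: stoichiometry interpolation truth (value = a x^2 + b x + c)
STOICHIOMETRY_POLY = (-0.05, 1.07, 0.01)
#: enthalpy interpolation truth, kcal/mol
ENTHALPY_POLY = (-0.36, 10.0, -95.6)
#: copolymer counts at which trajectory metrics are evaluated
COPOLYMER_COUNTS = (1, 4, 6, 8)

#: one-site truth on the amine/phosphate charge basis: the per-siRNA
#: stoichiometry 5.71 divided by 40 phosphates / 10 amines per chain
ITC_TRUTH = {"n_sites": 5.71 / 4.0, "ka": 2.6e7, "dh": -16.5}


@dataclass(frozen=True)
class GeneratorConfig:
    """Noise levels and discretization of the synthetic world.

    ``itc_noise_fraction`` scales white power noise relative to the tallest
    injection pulse; ``series_sigma`` and ``cze_noise_mau`` are absolute.
    """

    seed: int = 0
    itc_noise_fraction: float = 0.02
    itc_drift: float = 2e-5  # ucal/s per s linear baseline drift
    itc_pulse_width: float = 8.0  # s (Gaussian sigma)
    itc_dt: float = 1.0  # s sampling step
    series_sigma: float = 0.2
    cze_noise_mau: float = 0.02
    cze_dt_min: float = 0.002

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

def gen_itc_thermogram(
    truth: dict | None = None,
    schedule: InjectionSchedule | None = None,
    cfg: GeneratorConfig | None = None,
) -> tuple[Thermogram, dict]:
    """Synthetic differential-power trace for a one-site titration.

    ``truth`` holds n_sites/ka/dh on the charge basis (defaults to the
    experimental micelle-siRNA parameters).  Returns the thermogram and a
    ground-truth dict carrying the parameters and the exact per-injection
    molar heats its pulses integrate to.
    """
    truth = dict(ITC_TRUTH if truth is None else truth)
    schedule = schedule or InjectionSchedule()
    cfg = cfg or GeneratorConfig()
    if cfg.itc_pulse_width * 10 >= schedule.spacing:
        raise ValueError("pulse width too large: injections would overlap")
    rng = cfg.rng()

    heats = one_site_heat_curve(
        truth["n_sites"], truth["ka"], truth["dh"], schedule
    )  # kJ/mol injectant
    moles = schedule.injection_volumes * schedule.syringe_ligand_conc
    areas_ucal = heats * moles * 1e3 / J_PER_UCAL

    t_end = schedule.injection_times[-1] + schedule.spacing
    time = np.arange(0.0, t_end + cfg.itc_dt, cfg.itc_dt)
    dp = np.zeros_like(time)
    w = cfg.itc_pulse_width
    for t_inj, area in zip(schedule.injection_times, areas_ucal):
        # 5 sigma clearance to both window edges keeps the cut tails
        # negligible against the integration tolerance
        center = t_inj + 5.0 * w
        in_win = (time >= t_inj) & (time < t_inj + schedule.spacing)
        pulse = np.exp(-0.5 * ((time[in_win] - center) / w) ** 2)
        discrete = np.trapezoid(pulse, time[in_win])
        dp[in_win] += pulse * (area / discrete)

    peak = np.max(np.abs(dp)) if np.any(dp) else 1.0
    dp = dp + cfg.itc_drift * time
    if cfg.itc_noise_fraction > 0:
        dp = dp + rng.normal(0.0, cfg.itc_noise_fraction * peak, size=len(dp))

    tg = Thermogram(time=time, dp=dp, schedule=schedule)
    truth_out = {**truth, "heats_kj_per_mol": heats.tolist(),
                 "areas_ucal": areas_ucal.tolist()}
    return tg, truth_out


# ---------------------------------------------------------------------------
# structure frames
# ---------------------------------------------------------------------------

_RISE = 0.34  # nm per bp
_TWIST = np.deg2rad(36.0)
_R_PHOS, _R_SUGAR, _R_BASE = 0.94, 0.70, 0.35  # nm from the helix axis
# strands placed diametrically opposite: every base-pair center of mass
# then lies exactly on the helix axis, so the generated duplex is globally
# straight by construction (a real B-form groove phase would leave a
# rotating lateral offset of a few degrees in the bending angle)
_STRAND2_PHASE = np.deg2rad(180.0)
_BEAD_SPACING = 0.36  # nm along a copolymer chain
_CONTACT_PLACEMENT = 0.25  # nm from a phosphate for a wrapped PLL bead


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


class _FrameBuilder:
    def __init__(self):
        self.rows: list[tuple] = []
        self.h_links: list[tuple[int, int]] = []

    def add(self, xyz, element, resname, resid, chain, segment,
            donor=False, acceptor=False) -> int:
        self.rows.append((np.asarray(xyz, float), element, resname,
                          int(resid), chain, segment, donor, acceptor))
        return len(self.rows) - 1

    def add_h(self, parent: int, xyz) -> None:
        row = self.rows[parent]
        i = self.add(xyz, "H", row[2], row[3], row[4], row[5])
        self.h_links.append((i, parent))

    def build(self) -> StructureFrame:
        n = len(self.rows)
        hp = np.full(n, -1, int)
        for h, p in self.h_links:
            hp[h] = p
        cols = list(zip(*self.rows))
        return StructureFrame(
            coords=np.array([c for c in cols[0]]),
            element=np.array(cols[1]), resname=np.array(cols[2]),
            resid=np.array(cols[3]), chain=np.array(cols[4]),
            segment=np.array(cols[5]),
            is_donor=np.array(cols[6], bool),
            is_acceptor=np.array(cols[7], bool),
            h_parent=hp,
        )


def _duplex(builder: _FrameBuilder, n_bp: int, bend_deg: float) -> np.ndarray:
    """Add an idealized duplex along z; returns phosphate coordinates."""
    phosphates = []
    z_mid = _RISE * (n_bp - 1) / 2.0
    rot = _rotation(np.array([1.0, 0.0, 0.0]), np.deg2rad(bend_deg))

    def place(p):
        # bend: rotate the upper arm about the duplex midpoint
        if bend_deg and p[2] > z_mid:
            return rot @ (p - np.array([0, 0, z_mid])) + np.array([0, 0, z_mid])
        return p

    for strand, (chain, phase) in enumerate(
        (("A", 0.0), ("B", _STRAND2_PHASE))
    ):
        for i in range(n_bp):
            ang = i * _TWIST + phase
            # antiparallel: chain B resids run opposite to z
            resid = i + 1 if strand == 0 else n_bp - i
            z = i * _RISE
            u = np.array([np.cos(ang), np.sin(ang), 0.0])
            p_pos = place(u * _R_PHOS + np.array([0, 0, z]))
            s_pos = place(u * _R_SUGAR + np.array([0, 0, z]))
            b_pos = place(u * _R_BASE + np.array([0, 0, z]))
            ip = builder.add(p_pos, "P", "RNA", resid, chain, SIRNA,
                             acceptor=True)
            builder.add(s_pos, "C", "RNA", resid, chain, SIRNA)
            ib = builder.add(b_pos, "N", "RNA", resid, chain, SIRNA,
                             donor=True, acceptor=True)
            builder.add_h(ib, place(u * (_R_BASE + 0.10) + np.array([0, 0, z])))
            phosphates.append(p_pos)
    return np.array(phosphates)


def _copolymer(
    builder: _FrameBuilder,
    chain_id: str,
    phosphates: np.ndarray,
    slots: list[int],
    n_wrapped: int,
    far_anchor: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Add one 45 PEG + 10 PLL + 25 PLA bead chain.

    The first ``n_wrapped`` PLL beads sit 0.25 nm outside assigned
    phosphate slots; the rest of the chain extends radially away from the
    duplex axis, safely outside the contact cutoff.
    """
    axis_xy = np.array([0.0, 0.0])
    positions: list[np.ndarray] = []
    pll = []
    for m in range(10):
        if m < n_wrapped:
            p = phosphates[slots[m]]
            radial = p.copy()
            radial[:2] -= axis_xy
            u = radial / np.linalg.norm(radial)
            pll.append(p + u * _CONTACT_PLACEMENT)
        else:
            start = pll[-1] if pll else far_anchor
            u = start.copy()
            u[2] = 0.0
            nrm = np.linalg.norm(u)
            u = u / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
            pll.append(start + u * _BEAD_SPACING * (m - n_wrapped + 1)
                       + np.array([0, 0, 0.05 * m]))
    positions.extend(pll)
    # PEG then PLA blocks walk further outward from the last PLL bead
    tip = positions[-1]
    u = tip.copy()
    u[2] = 0.0
    nrm = np.linalg.norm(u)
    u = u / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
    jitter = rng.normal(0.0, 0.02, size=(70, 3))
    for b in range(70):
        positions.append(tip + u * _BEAD_SPACING * (b + 1) + jitter[b])

    for m, pos in enumerate(positions):
        if m < 10:
            i = builder.add(pos, "N", "LYS", m + 1, chain_id, "PLL",
                            donor=True, acceptor=True)
            toward = phosphates[slots[m]] if m < n_wrapped else pos + u
            d = toward - pos
            nd = np.linalg.norm(d)
            hdir = d / nd if nd > 1e-9 else np.array([1.0, 0.0, 0.0])
            builder.add_h(i, pos + hdir * 0.10)
        elif m < 55:
            builder.add(pos, "O", "PEG", m + 1, chain_id, "PEG", acceptor=True)
        else:
            builder.add(pos, "C", "LAC", m + 1, chain_id, "PLA")


def gen_helix_complex(
    n_bp: int = 21,
    k_copolymers: int = 1,
    wrap_fraction: float = 0.5,
    bend_deg: float = 0.0,
    n_complexed: int | None = None,
    cfg: GeneratorConfig | None = None,
) -> StructureFrame:
    """Idealized duplex plus k bead-chain copolymers.

    ``wrap_fraction`` of each complexed copolymer's 10 PLL beads is placed
    within contact range (0.25 nm) of distinct backbone phosphates;
    ``n_complexed`` copolymers (default all k) touch the duplex, the rest
    start 3 nm away.  ``bend_deg`` kinks the duplex axis at its midpoint,
    so the bending angle reads 180 - bend_deg.
    """
    if n_bp < 4:
        raise ValueError("need at least 4 base pairs")
    if k_copolymers < 0 or not 0.0 <= wrap_fraction <= 1.0:
        raise ValueError("invalid copolymer count or wrap fraction")
    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    n_complexed = k_copolymers if n_complexed is None else n_complexed
    if n_complexed > k_copolymers:
        raise ValueError("n_complexed exceeds k_copolymers")

    builder = _FrameBuilder()
    phosphates = _duplex(builder, n_bp, bend_deg)
    n_wrapped = int(round(wrap_fraction * 10))
    n_slots = len(phosphates)
    if n_complexed * n_wrapped > n_slots:
        raise ValueError(
            f"cannot place {n_complexed * n_wrapped} wrapped PLL beads on "
            f"{n_slots} phosphates: reduce k or wrap_fraction"
        )
    slot_order = list(rng.permutation(n_slots))
    height = _RISE * (n_bp - 1)
    # single-letter chain ids (PDB column width); duplex strands are A/B
    chain_letters = "CDEFGHIJKLMNOPQRSTUVWXYZ"
    if k_copolymers > len(chain_letters):
        raise ValueError("too many copolymer chains for distinct chain ids")
    for j in range(k_copolymers):
        chain_id = chain_letters[j]
        if j < n_complexed:
            slots = slot_order[j * n_wrapped: (j + 1) * n_wrapped]
            # pad so indexing is safe when n_wrapped == 0
            slots = slots + [0] * (10 - len(slots))
            far = np.array([3.0, 0.0, height * (j + 0.5) / max(k_copolymers, 1)])
            _copolymer(builder, chain_id, phosphates, slots, n_wrapped, far, rng)
        else:
            ang = 2 * np.pi * j / max(k_copolymers, 1)
            far = np.array([3.0 * np.cos(ang), 3.0 * np.sin(ang),
                            height * (j + 0.5) / max(k_copolymers, 1)])
            _copolymer(builder, chain_id, phosphates, [0] * 10, 0, far, rng)
    return builder.build()


# ---------------------------------------------------------------------------
# metric series and electropherograms
# ---------------------------------------------------------------------------

def gen_metric_series(
    truth_poly: tuple[float, float, float] = STOICHIOMETRY_POLY,
    counts=COPOLYMER_COUNTS,
    sigma: float | None = None,
    cfg: GeneratorConfig | None = None,
) -> tuple[MetricSeries, dict]:
    """Metric series sampled from a truth quadratic plus Gaussian noise."""
    cfg = cfg or GeneratorConfig()
    sigma = cfg.series_sigma if sigma is None else sigma
    rng = cfg.rng()
    x = np.asarray(counts, float)
    if len(x) == 0:
        raise ValueError("counts must be nonempty")
    a, b, c = truth_poly
    y = a * x**2 + b * x + c
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=len(x))
    series = MetricSeries(counts=x, values=y, sd=np.full(len(x), sigma))
    return series, {"a": a, "b": b, "c": c, "sigma": sigma}


#: instrument response factors of the synthetic CZE world (arbitrary but fixed)
_CZE_RESPONSE_260 = 0.90  # mAU*min per uM siRNA
_CZE_RESPONSE_IS = 0.12  # mAU*min per ug/mL internal standard
_CZE_T_SIRNA = 3.2  # min apex
_CZE_T_IS = 1.8  # min apex
_CZE_PEAK_SIGMA = 0.05  # min


def gen_electropherogram(
    conc_uM: float = 2.0,
    is_conc_ug_ml: float = 4.0,
    cfg: GeneratorConfig | None = None,
) -> tuple[Electropherogram, dict]:
    """Dual-wavelength trace with known peak areas.

    The siRNA peak (260 nm) area is proportional to the concentration; the
    internal-standard peak sits on the 210 nm channel.  Ground truth holds
    the exact areas and apex times.
    """
    if conc_uM < 0 or is_conc_ug_ml < 0:
        raise ValueError("concentrations must be nonnegative")
    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    t = np.arange(0.0, 5.0 + cfg.cze_dt_min, cfg.cze_dt_min)

    def peak(center, area):
        return area / (_CZE_PEAK_SIGMA * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((t - center) / _CZE_PEAK_SIGMA) ** 2
        )

    a_sirna = _CZE_RESPONSE_260 * conc_uM
    a_is = _CZE_RESPONSE_IS * is_conc_ug_ml
    au260 = 0.5 + peak(_CZE_T_SIRNA, a_sirna)
    au210 = 0.8 + peak(_CZE_T_IS, a_is) + peak(_CZE_T_SIRNA, 0.3 * a_sirna)
    if cfg.cze_noise_mau > 0:
        au260 = au260 + rng.normal(0.0, cfg.cze_noise_mau, len(t))
        au210 = au210 + rng.normal(0.0, cfg.cze_noise_mau, len(t))
    eg = Electropherogram(time_min=t, au260=au260, au210=au210)
    truth = {
        "conc_uM": conc_uM, "is_conc_ug_ml": is_conc_ug_ml,
        "area_260": a_sirna, "area_is_210": a_is,
        "t_sirna": _CZE_T_SIRNA, "t_is": _CZE_T_IS,
    }
    return eg, truth
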
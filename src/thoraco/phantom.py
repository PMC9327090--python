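"""Synthetic breathing-torso phantom with analytic ground truth.

The phantom emulates a seated acquisition: quiet breathing followed by a
maximal capacity maneuver (full inspiration to TLC, forced full expiration
to RV). Geometry is a stack of elliptic rings at the marker-row heights
with linear-in-z interpolation between rings; breathing scales the ring
half-axes by a compartment-dependent fraction of a common waveform, so
the enclosed volume has an exact closed form at every instant.

Breathing waveform s(t)
-----------------------
* quiet phase: ``s = sin(2 pi f t)``, so s(0)=0 (end-expiration start) and
  the first quarter-period reaches peak inspiration (+1); the quiet
  trough (s = -1) is the functional residual capacity level;
* maneuver: piecewise-linear ramp from the quiet end value to
  ``+tlc_excursion``, down to ``-rv_excursion``, then back to 0 --
  continuous everywhere. Excursions are expressed in units of the quiet
  half-amplitude, so tlc_excursion > 1 puts TLC above every quiet peak
  and rv_excursion > 1 puts RV below every quiet trough.

Radial gain
-----------
A marker at row r, azimuth theta moves with
``u = 1 + eps_r * s(t) * g(theta)`` where ``g`` is a smooth left/right
gain, ``g = ((1+asym) + (1-asym) cos(theta)) / 2`` (g=1 at the right
lateral, g=asym at the left). Paradox-flagged compartments flip the sign
of eps, producing inward motion during inspiration (Hoover-sign-like
behaviour). With the gain applied to both half-axes the cross-section
area is ``pi a b (alpha^2 + beta^2/2)`` with ``alpha = 1 + eps s (1+asym)/2``
and ``beta = eps s (1-asym)/2``; with the gain on a single axis it is
``pi a b alpha``. Both are exact, so the ground-truth volume integral is
a polynomial of degree <= 4 in z per segment and is integrated exactly by
3-point Gauss quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import MarkerLayout, default_layout
from .marker_io import MarkerTrajectorySet

MM3_TO_L = 1e-6

_GAUSS_X = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GAUSS_W = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


class PhantomConfigError(ValueError):
    pass


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic subject.

    Defaults describe a healthy adult torso: ~22 L chest-wall volume,
    quiet breathing at 15 breaths/min for 3 minutes, tidal volume ~0.5 L,
    then a capacity maneuver giving IC ~2.5 L and VC ~3.6 L, sampled at
    60 Hz with 0.3 mm isotropic marker jitter (typical optical tracking
    noise).
    """

    height_mm: float = 500.0
    a0_mm: tuple[float, ...] = (125.0, 133.0, 138.0, 140.0, 138.0, 135.0, 132.0)
    b0_mm: tuple[float, ...] = (92.0, 102.0, 108.0, 108.0, 106.0, 108.0, 112.0)
    eps: dict[str, float] = field(
        default_factory=lambda: {"RCp": 0.006, "RCa": 0.005, "AB": 0.007}
    )
    freq_hz: float = 0.25
    quiet_duration_s: float = 180.0
    tlc_excursion: float = 8.6
    rv_excursion: float = 5.0
    insp_s: float = 3.0
    exp_s: float = 4.0
    recover_s: float = 2.0
    paradox_flags: frozenset[str] = frozenset()
    asymmetry: float = 1.0
    scale_axes: str = "both"  # "a" | "b" | "both"
    jitter_sd_mm: float = 0.3
    sample_rate: float = 60.0
    seed: int = 0
    layout: MarkerLayout | None = None

    def __post_init__(self) -> None:
        if self.layout is None:
            self.layout = default_layout()
        if isinstance(self.paradox_flags, (set, list, tuple)):
            self.paradox_flags = frozenset(self.paradox_flags)
        rows = self.layout.rows
        if len(self.a0_mm) != rows or len(self.b0_mm) != rows:
            raise PhantomConfigError(
                f"a0_mm/b0_mm must have one entry per row ({rows})"
            )
        if min(self.a0_mm) <= 0 or min(self.b0_mm) <= 0:
            raise PhantomConfigError("half-axes must be strictly positive")
        if any(e < 0 for e in self.eps.values()):
            raise PhantomConfigError("compartment amplitudes eps must be >= 0")
        if self.scale_axes not in ("a", "b", "both"):
            raise PhantomConfigError("scale_axes must be 'a', 'b' or 'both'")
        if not self.tlc_excursion > 1.0:
            raise PhantomConfigError("TLC excursion must exceed the tidal excursion")
        if not self.rv_excursion > 1.0:
            raise PhantomConfigError("RV excursion must fall below quiet end-expiration")
        if not 0.0 <= self.asymmetry:
            raise PhantomConfigError("asymmetry ratio must be >= 0")
        gmax = max(1.0, self.asymmetry)
        worst = max(self.tlc_excursion, self.rv_excursion) * gmax
        if any(e * worst >= 1.0 for e in self.eps.values()):
            raise PhantomConfigError(
                "amplitudes produce non-positive half-axes during the maneuver"
            )

    # -- timeline -------------------------------------------------------
    @property
    def duration_s(self) -> float:
        return self.quiet_duration_s + self.insp_s + self.exp_s + self.recover_s

    def times(self) -> np.ndarray:
        n = int(round(self.duration_s * self.sample_rate)) + 1
        return np.arange(n) / self.sample_rate

    # -- per-row geometry ----------------------------------------------
    def row_heights(self) -> np.ndarray:
        rows = self.layout.rows
        return self.height_mm * (rows - np.arange(1, rows + 1)) / (rows - 1)

    def signed_eps(self) -> dict[str, float]:
        return {
            c: (-e if c in self.paradox_flags else e) for c, e in self.eps.items()
        }

    def row_eps(self) -> np.ndarray:
        """Per-row amplitude: mean of the (signed) amplitudes of the
        compartments containing the row (boundary rows are shared)."""
        signed = self.signed_eps()
        out = np.empty(self.layout.rows)
        for r in range(1, self.layout.rows + 1):
            vals = [
                signed[c]
                for c, (lo, hi) in self.layout.compartment_rows.items()
                if lo <= r <= hi
            ]
            out[r - 1] = float(np.mean(vals))
        return out


# ---------------------------------------------------------------------------
# Waveform
# ---------------------------------------------------------------------------

def breathing_waveform(t, config: PhantomConfig):
    """Normalized breathing drive s(t); array-in, array-out, total function."""
    t = np.asarray(t, dtype=float)
    c = config
    t1 = c.quiet_duration_s
    t2 = t1 + c.insp_s
    t3 = t2 + c.exp_s
    t4 = t3 + c.recover_s
    s0 = np.sin(2 * np.pi * c.freq_hz * t1)  # continuity at maneuver start

    quiet = np.sin(2 * np.pi * c.freq_hz * t)
    up = s0 + (c.tlc_excursion - s0) * (t - t1) / c.insp_s
    down = c.tlc_excursion - (c.tlc_excursion + c.rv_excursion) * (t - t2) / c.exp_s
    rec = -c.rv_excursion * (1.0 - (t - t3) / c.recover_s)

    s = np.where(t < t1, quiet, np.where(t < t2, up, np.where(t < t3, down, rec)))
    s = np.where(t >= t4, 0.0, s)
    return s if s.ndim else float(s)


# ---------------------------------------------------------------------------
# Analytic volume
# ---------------------------------------------------------------------------

def _gauss_nodes(config: PhantomConfig):
    """Quadrature nodes/weights per inter-row segment plus node values of
    a, b (mm) and eps, all linearly interpolated in z."""
    z = config.row_heights()  # decreasing
    a = np.asarray(config.a0_mm, float)
    b = np.asarray(config.b0_mm, float)
    e = config.row_eps()
    z_hi, z_lo = z[:-1], z[1:]
    half = (z_hi - z_lo) / 2.0
    mid = (z_hi + z_lo) / 2.0
    zq = (mid[:, None] + half[:, None] * _GAUSS_X[None, :]).ravel()
    wq = (half[:, None] * _GAUSS_W[None, :]).ravel()
    seg = np.repeat(np.arange(len(z) - 1), len(_GAUSS_X))
    frac = (z[seg] - zq) / (z[seg] - z[seg + 1])  # 0 at upper row, 1 at lower
    aq = a[seg] * (1 - frac) + a[seg + 1] * frac
    bq = b[seg] * (1 - frac) + b[seg + 1] * frac
    eq = e[seg] * (1 - frac) + e[seg + 1] * frac
    return zq, wq, aq, bq, eq


def _section_area_mm2(a, b, eps, s, config: PhantomConfig):
    """Exact cross-section area for half-axes a, b and gain 1 + eps*s*g(theta)."""
    c0 = (1.0 + config.asymmetry) / 2.0
    c1 = (1.0 - config.asymmetry) / 2.0
    alpha = 1.0 + eps * s * c0
    beta = eps * s * c1
    if config.scale_axes == "both":
        return np.pi * a * b * (alpha**2 + beta**2 / 2.0)
    return np.pi * a * b * alpha


def _volume_from_s(config: PhantomConfig, s, z_range=None):
    """Volume (L) as a function of the drive value(s) s; exact integral."""
    zq, wq, aq, bq, eq = _gauss_nodes(config)
    if z_range is not None:
        lo, hi = z_range
        keep = (zq > lo) & (zq < hi)
        zq, wq, aq, bq, eq = zq[keep], wq[keep], aq[keep], bq[keep], eq[keep]
    s = np.asarray(s, dtype=float)
    scalar = s.ndim == 0
    area = _section_area_mm2(
        aq[:, None], bq[:, None], eq[:, None], np.atleast_1d(s)[None, :], config
    )
    vol = (wq[:, None] * area).sum(axis=0) * MM3_TO_L
    return float(vol[0]) if scalar else vol


def analytic_chest_volume(config: PhantomConfig, t) -> np.ndarray | float:
    """Analytic chest-wall volume V(t) in liters."""
    s = breathing_waveform(t, config)
    return _volume_from_s(config, s)


def _compartment_z_ranges(config: PhantomConfig) -> dict[str, tuple[float, float]]:
    z = config.row_heights()
    out = {}
    for name, (lo_row, hi_row) in config.layout.compartment_rows.items():
        out[name] = (float(z[hi_row - 1]), float(z[lo_row - 1]))
    return out


@dataclass
class GroundTruth:
    """Noise-free analytic truth for a generated phantom session."""

    t: np.ndarray
    volume_l: np.ndarray
    compartments: dict[str, np.ndarray]
    vt_l: float
    ic_l: float
    vc_l: float
    rr_bpm: float
    frc_l: float
    frcvt_l: float
    tlc_l: float
    rv_l: float
    phase_frames: dict[str, int]


# ---------------------------------------------------------------------------
# Marker generation
# ---------------------------------------------------------------------------

def generate_phantom(config: PhantomConfig) -> tuple[MarkerTrajectorySet, GroundTruth]:
    """Sample the phantom surface at the layout's marker stations.

    Returns the (possibly jittered) marker trajectories and the noise-free
    analytic ground truth. Deterministic for a fixed config/seed.
    """
    layout = config.layout
    t = config.times()
    s = breathing_waveform(t, config)

    z_rows = config.row_heights()
    e_rows = config.row_eps()
    a_rows = np.asarray(config.a0_mm, float)
    b_rows = np.asarray(config.b0_mm, float)

    theta = np.array([np.deg2rad(st.azimuth_deg) for st in layout.stations])
    rows = np.array([st.row - 1 for st in layout.stations])
    g = ((1.0 + config.asymmetry) + (1.0 - config.asymmetry) * np.cos(theta)) / 2.0

    u = 1.0 + e_rows[rows][None, :] * s[:, None] * g[None, :]  # (T, M)
    ux = u if config.scale_axes in ("a", "both") else np.ones_like(u)
    uy = u if config.scale_axes in ("b", "both") else np.ones_like(u)

    pos = np.empty((len(t), len(theta), 3))
    pos[:, :, 0] = a_rows[rows][None, :] * np.cos(theta)[None, :] * ux
    pos[:, :, 1] = b_rows[rows][None, :] * np.sin(theta)[None, :] * uy
    pos[:, :, 2] = z_rows[rows][None, :]

    if config.jitter_sd_mm > 0:
        rng = np.random.default_rng(config.seed)
        pos = pos + rng.normal(0.0, config.jitter_sd_mm, pos.shape)

    trajs = MarkerTrajectorySet(pos, config.sample_rate, layout.marker_labels, layout)

    volume = _volume_from_s(config, s)
    comps = {
        name: _volume_from_s(config, s, z_range=zr)
        for name, zr in _compartment_z_ranges(config).items()
    }

    v_of = lambda sv: float(_volume_from_s(config, np.array([sv]))[0])
    frc = v_of(-1.0)
    frcvt = v_of(1.0)
    tlc = v_of(config.tlc_excursion)
    rv = v_of(-config.rv_excursion)

    quiet = t < config.quiet_duration_s
    qidx = np.flatnonzero(quiet)
    phase_frames = {
        "FRC": int(qidx[np.argmin(s[quiet])]),
        "FRCVT": int(qidx[np.argmax(s[quiet])]),
        "TLC": int(np.argmax(s)),
        "RV": int(np.argmin(s)),
    }

    truth = GroundTruth(
        t=t,
        volume_l=volume,
        compartments=comps,
        vt_l=frcvt - frc,
        ic_l=tlc - frc,
        vc_l=tlc - rv,
        rr_bpm=60.0 * config.freq_hz,
        frc_l=frc,
        frcvt_l=frcvt,
        tlc_l=tlc,
        rv_l=rv,
        phase_frames=phase_frames,
    )
    return trajs, truth
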
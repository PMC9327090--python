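"""Respiratory phase detection and ventilatory pattern.

The chest-wall volume trace of a session (quiet breathing followed by a
maximal capacity maneuver) contains four static phases:

* FRC    functional residual capacity, end-expiratory level of quiet breathing;
* FRCVT  end-inspiratory (end-of-tidal-volume) level;
* TLC    total lung capacity, the global maximum of the trace;
* RV     residual volume, the global minimum after forced expiration.

FRC and FRCVT are medians over the quiet-breathing trough/peak values, a
robust choice against drift; peaks and troughs are found by prominence-
based extremum detection on a 0.25 s moving-mean smoothed copy of the
trace (raw values are reported at the detected indices). From the phases
the ventilatory pattern follows: VT = FRCVT - FRC, IC = TLC - FRC,
VC = TLC - RV, RR = 60 / mean quiet breath period and MV = VT * RR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .layout import COMPARTMENTS

SMOOTH_WINDOW_S = 0.25
PROMINENCE_FRACTION = 0.25


class BreathingError(ValueError):
    pass


@dataclass
class VolumeTrace:
    t: np.ndarray
    volume_l: np.ndarray
    sample_rate: float
    compartments: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.volume_l = np.asarray(self.volume_l, dtype=float)
        if self.t.shape != self.volume_l.shape:
            raise BreathingError("t and volume must have the same length")
        if not np.all(np.isfinite(self.volume_l)):
            raise BreathingError("volume trace contains non-finite values")


@dataclass
class PhaseVolumes:
    """The four static phase volumes (L) with representative frame indices."""

    rv_l: float
    frc_l: float
    frcvt_l: float
    tlc_l: float
    frames: dict[str, int]
    breath_boundaries: np.ndarray  # end-expiration indices in the quiet window

    def __post_init__(self) -> None:
        if not (self.rv_l <= self.frc_l < self.frcvt_l <= self.tlc_l):
            raise BreathingError(
                "phase ordering violated: need RV <= FRC < FRCVT <= TLC, got "
                f"RV={self.rv_l:.3f} FRC={self.frc_l:.3f} "
                f"FRCVT={self.frcvt_l:.3f} TLC={self.tlc_l:.3f}"
            )


@dataclass
class VentilatoryPattern:
    vt_l: float
    ic_l: float
    vc_l: float
    rr_bpm: float
    mv_l_min: float
    compartment_deltas_l: dict[str, dict[str, float]] = field(default_factory=dict)
    compartment_percent: dict[str, dict[str, float]] = field(default_factory=dict)


def _moving_mean(x: np.ndarray, sample_rate: float,
                 window_s: float = SMOOTH_WINDOW_S) -> np.ndarray:
    w = max(1, int(round(window_s * sample_rate)))
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def detect_phases(trace: VolumeTrace, quiet_window_s: float) -> PhaseVolumes:
    """Locate RV, FRC, FRCVT and TLC on the chest-wall volume trace.

    ``quiet_window_s`` is the duration of the quiet-breathing part at the
    start of the session; the capacity maneuver is expected afterwards.
    """
    v = trace.volume_l
    sm = _moving_mean(v, trace.sample_rate)
    nq = int(round(quiet_window_s * trace.sample_rate))
    nq = min(nq, len(v))
    quiet = sm[:nq]
    if np.ptp(quiet) == 0:
        raise BreathingError("flat trace: no breaths detected")

    # two passes: a permissive one estimates the quiet-breath excursion,
    # the second applies the 25%-of-excursion prominence rule
    rough = 0.1 * np.ptp(quiet)
    pk, _ = find_peaks(quiet, prominence=rough)
    tr, _ = find_peaks(-quiet, prominence=rough)
    if len(pk) < 3 or len(tr) < 3:
        raise BreathingError(
            f"fewer than 3 quiet breaths detected ({len(pk)} peaks, {len(tr)} troughs)"
        )
    excursion = np.median(quiet[pk]) - np.median(quiet[tr])
    prom = PROMINENCE_FRACTION * excursion
    pk, _ = find_peaks(quiet, prominence=prom)
    tr, _ = find_peaks(-quiet, prominence=prom)
    if len(pk) < 3 or len(tr) < 3:
        raise BreathingError("fewer than 3 quiet breaths after prominence filtering")

    frc = float(np.median(v[tr]))
    frcvt = float(np.median(v[pk]))
    i_tlc = int(np.argmax(v))
    i_rv = int(np.argmin(v))
    tlc = float(v[i_tlc])
    rv = float(v[i_rv])
    if i_tlc < nq:
        warnings.warn(
            "global maximum (TLC) falls inside the quiet window; "
            "maneuver may be missing", stacklevel=2
        )

    i_frc = int(tr[np.argmin(np.abs(v[tr] - frc))])
    i_frcvt = int(pk[np.argmin(np.abs(v[pk] - frcvt))])
    return PhaseVolumes(
        rv_l=rv, frc_l=frc, frcvt_l=frcvt, tlc_l=tlc,
        frames={"RV": i_rv, "FRC": i_frc, "FRCVT": i_frcvt, "TLC": i_tlc},
        breath_boundaries=tr.astype(int),
    )


def ventilatory_pattern(phases: PhaseVolumes, trace: VolumeTrace) -> VentilatoryPattern:
    """Ventilatory pattern from the detected phases.

    If the trace carries compartment volumes, per-compartment VT/IC/VC are
    the compartment volume differences at the global phase instants, with
    signed percentage contributions (negative = paradoxical motion).
    """
    if len(phases.breath_boundaries) < 2:
        raise BreathingError("need at least 2 breath boundaries for the rate")
    period = float(np.mean(np.diff(phases.breath_boundaries))) / trace.sample_rate
    rr = 60.0 / period
    vt = phases.frcvt_l - phases.frc_l
    ic = phases.tlc_l - phases.frc_l
    vc = phases.tlc_l - phases.rv_l
    pattern = VentilatoryPattern(
        vt_l=vt, ic_l=ic, vc_l=vc, rr_bpm=rr, mv_l_min=vt * rr
    )
    if trace.compartments:
        pairs = {
            "VT": ("FRC", "FRCVT"),
            "IC": ("FRC", "TLC"),
            "VC": ("RV", "TLC"),
        }
        for which, (p0, p1) in pairs.items():
            i0, i1 = phases.frames[p0], phases.frames[p1]
            deltas = {
                c: float(trace.compartments[c][i1] - trace.compartments[c][i0])
                for c in COMPARTMENTS
                if c in trace.compartments
            }
            pattern.compartment_deltas_l[which] = deltas
            pattern.compartment_percent[which] = compartmental_contributions(deltas)
    return pattern


def compartmental_contributions(deltas_l: dict[str, float]) -> dict[str, float]:
    """Signed percentage contribution of each compartment to the total
    chest-wall volume change (ratio of each delta to the sum of deltas).
    Negative values flag paradoxical (inward) motion."""
    total = sum(deltas_l.values())
    if total == 0:
        raise BreathingError("zero total volume change; percentages undefined")
    return {c: 100.0 * d / total for c, d in deltas_l.items()}
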
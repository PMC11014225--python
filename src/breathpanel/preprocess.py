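"""Chromatogram pre-processing and technical-adequacy quality control.

De-noising is Savitzky-Golay (moving least-squares polynomial) smoothing;
baseline estimation is asymmetric least squares (a Whittaker smoother whose
weights are small above the current baseline estimate and large below, so
peaks are ignored while the slow drift is tracked).  Quality control flags
breath runs that are technically inadequate: collapsed total signal,
detector saturation, or missing landmark (anchor) peaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .chromatogram import Chromatogram, Stage
from .peaks import _pick, _vote_shift, estimate_anchor_rts

__all__ = [
    "QCReport",
    "denoise",
    "baseline_correct",
    "qc_assess",
    "qc_cohort",
    "filter_inadequate",
]

log = logging.getLogger("breathpanel.preprocess")

DEFAULT_WINDOW = 21
DEFAULT_POLYORDER = 3
DEFAULT_SMOOTHNESS = 1e9
DEFAULT_ASYMMETRY = 0.01
DEFAULT_MAX_ITER = 10

DEFAULT_N_ANCHORS = 6
#: Minimum anchors for adequacy.  With a per-compound detection probability
#: around 0.9 a sample can legitimately lack several of the six landmark
#: compounds; requiring two keeps the false-flag rate negligible while
#: anchor-stripped traces still count zero.
DEFAULT_MIN_ANCHORS = 2
DEFAULT_FLOOR_FRACTION = 0.01
DEFAULT_MAX_SATURATION = 0.05
ANCHOR_SEARCH_WINDOW = 3.0  # seconds, around the shift-corrected position
#: Largest injection-timing shift the anchor check will compensate; kept
#: tight so a trace whose landmark peaks were lost cannot re-match
#: neighbouring compounds by inventing a large shift.
QC_MAX_SHIFT = 4.0


def denoise(
    chrom: Chromatogram,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
) -> Chromatogram:
    """Savitzky-Golay smoothing; grid and length are untouched.

    The filter reproduces any signal that is locally a polynomial of degree
    <= ``polyorder`` exactly, so well-resolved peaks keep their apex and area
    while white noise power drops.
    """
    if chrom.stage is not Stage.RAW:
        raise ValueError(f"denoise expects a raw trace, got stage={chrom.stage.value!r}")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not 0 < polyorder < window:
        raise ValueError("need 0 < polyorder < window")
    if window > len(chrom):
        raise ValueError("window longer than trace")
    smoothed = savgol_filter(chrom.intensities, window, polyorder, mode="interp")
    return chrom.with_intensities(smoothed, Stage.DENOISED)


def _second_difference_penalty(n: int) -> np.ndarray:
    """Upper banded form (3, n) of D2' D2 for the Whittaker smoother."""
    d2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    a = (d2.T @ d2).todia()
    ab = np.zeros((3, n))
    for off, data in zip(a.offsets, a.data):
        if off == 0:
            ab[2] = data
        elif off == 1:
            ab[1] = data
        elif off == 2:
            ab[0] = data
    return ab


def baseline_correct(
    chrom: Chromatogram,
    smoothness: float = DEFAULT_SMOOTHNESS,
    asymmetry: float = DEFAULT_ASYMMETRY,
    max_iter: int = DEFAULT_MAX_ITER,
) -> Chromatogram:
    """Estimate and subtract an asymmetric-least-squares baseline.

    Solves ``(W + smoothness * D2'D2) z = W y`` iteratively, with weight
    ``asymmetry`` for points above the current baseline and
    ``1 - asymmetry`` below, so the baseline hugs the peak-free floor.
    Negative residuals are kept (not clipped) to leave integration unbiased.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if not 0 < asymmetry < 0.5:
        raise ValueError("asymmetry must be in (0, 0.5)")
    if chrom.stage is Stage.RAW:
        warnings.warn("baseline_correct applied to a raw (un-denoised) trace", stacklevel=2)
    elif chrom.stage is Stage.BASELINE_CORRECTED:
        warnings.warn("baseline_correct re-applied to a corrected trace", stacklevel=2)

    y = chrom.intensities
    n = y.size
    penalty = smoothness * _second_difference_penalty(n)
    w = np.ones(n)
    z = y.copy()
    converged = False
    for _ in range(max_iter):
        ab = penalty.copy()
        ab[2] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            converged = True
            break
        w = w_new
    if not converged:
        warnings.warn(
            f"ALS baseline did not converge in {max_iter} iterations; using last iterate",
            stacklevel=2,
        )
    return chrom.with_intensities(y - z, Stage.BASELINE_CORRECTED)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Adequacy assessment of one breath run."""

    sample_id: str
    total_signal: float
    saturation_fraction: float
    anchor_peaks_found: int
    adequate: bool
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "total_signal": self.total_signal,
            "saturation_fraction": self.saturation_fraction,
            "anchor_peaks_found": self.anchor_peaks_found,
            "adequate": self.adequate,
            "reasons": list(self.reasons),
        }


def qc_assess(
    chrom: Chromatogram,
    floor: float,
    ceiling: float | None = None,
    anchor_rts: np.ndarray | None = None,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_saturation: float = DEFAULT_MAX_SATURATION,
) -> QCReport:
    """Assess one trace against the three inadequacy modes.

    ``floor`` is the minimum acceptable total (positive-part) signal in
    detector*seconds; ``ceiling`` the saturation level in detector units
    (default: 99.9% of the trace maximum, which catches flat-topped clipping
    without an absolute calibration); anchors are landmark RTs that must show
    a detectable local maximum within +/-3 s.
    """
    x, t = chrom.intensities, chrom.times
    total = chrom.total_signal()
    ceil_val = ceiling if ceiling is not None else 0.999 * float(np.max(x))
    saturation = float(np.mean(x >= ceil_val))

    found = 0
    if anchor_rts is not None and len(anchor_rts):
        idx, _ = _pick(x, t, None, DEFAULT_MIN_SNR_QC)
        apex = t[idx]
        shift = 0.0
        if apex.size:
            est = _vote_shift(
                apex, np.asarray(anchor_rts), ANCHOR_SEARCH_WINDOW, max_shift=QC_MAX_SHIFT
            )
            if est is not None:
                shift = est
        for rt in anchor_rts:
            if apex.size and np.min(np.abs(apex - (rt + shift))) <= ANCHOR_SEARCH_WINDOW:
                found += 1

    reasons = []
    if total < floor:
        reasons.append("low_signal")
    if saturation > max_saturation:
        reasons.append("saturated")
    if anchor_rts is not None and len(anchor_rts) and found < min_anchors:
        reasons.append("missing_anchors")
    return QCReport(
        sample_id=chrom.sample_id,
        total_signal=total,
        saturation_fraction=saturation,
        anchor_peaks_found=found,
        adequate=not reasons,
        reasons=reasons,
    )


DEFAULT_MIN_SNR_QC = 5.0


def qc_cohort(
    samples: list[Chromatogram],
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
    ceiling: float | None = None,
    anchor_rts: np.ndarray | None = None,
    anchor_candidates: np.ndarray | None = None,
    n_anchors: int = DEFAULT_N_ANCHORS,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_saturation: float = DEFAULT_MAX_SATURATION,
) -> list[QCReport]:
    """Cohort-level QC: the signal floor is ``floor_fraction`` of the cohort
    median total signal, and anchors default to the cohort's own landmark
    peaks (robust medians, so a minority of corrupted runs cannot move
    them), selected among ``anchor_candidates`` (e.g. library RTs) when
    given.
    """
    totals = [c.total_signal() for c in samples]
    floor = floor_fraction * float(np.median(totals)) if samples else 0.0
    if anchor_rts is None:
        anchor_rts = estimate_anchor_rts(
            samples, candidate_rts=anchor_candidates, n_anchors=n_anchors
        )
    return [
        qc_assess(
            c,
            floor=floor,
            ceiling=ceiling,
            anchor_rts=anchor_rts,
            min_anchors=min_anchors,
            max_saturation=max_saturation,
        )
        for c in samples
    ]


def filter_inadequate(
    samples: list[Chromatogram], reports: list[QCReport]
) -> list[Chromatogram]:
    """Keep adequate samples, preserving order; log each exclusion."""
    if len(samples) != len(reports):
        raise ValueError("one QC report per sample required")
    for chrom, rep in zip(samples, reports):
        if chrom.sample_id != rep.sample_id:
            raise ValueError(
                f"report/sample mismatch: {rep.sample_id!r} vs {chrom.sample_id!r}"
            )
    kept = []
    for chrom, rep in zip(samples, reports):
        if rep.adequate:
            kept.append(chrom)
        else:
            log.info("excluding %s: %s", chrom.sample_id, ",".join(rep.reasons))
    return kept
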
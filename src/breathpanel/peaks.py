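"""Peak detection, integration, cross-sample alignment and annotation.

Turns a set of baseline-corrected chromatograms into the samples x VOC
feature matrix the biomarker search operates on: local-maximum peak picking
with prominence and signal-to-noise gates, trapezoidal integration between
prominence bases, anchor-based retention-time shift correction, pooled
single-linkage clustering into consensus features, nearest-neighbour library
annotation, and a log10 + train-only-standardization feature transform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .chromatogram import Chromatogram, Stage
from .library import CompoundLibrary

__all__ = [
    "Peak",
    "FeatureMatrix",
    "Alignment",
    "detect_peaks",
    "integrate_peak",
    "align_samples",
    "match_library",
    "build_feature_matrix",
    "estimate_anchor_rts",
    "estimate_noise_sd",
]

DEFAULT_MIN_SNR = 5.0
DEFAULT_TOLERANCE = 3.0
DEFAULT_MIN_PRESENCE = 0.5
#: Window (in samples) over which prominences and bases are evaluated; caps
#: how far an isolated tall peak's base can wander along the trace.
PROMINENCE_WLEN = 501
#: Fraction of apex height at which integration bounds are cut.
BOUND_HEIGHT_FRACTION = 0.01
#: Minimum peak width in samples (at half prominence).  Real chromatographic
#: peaks span tens of samples at 10 Hz; baseline-flex ripples are narrower.
MIN_WIDTH_SAMPLES = 5


@dataclass(frozen=True)
class Peak:
    """One detected chromatographic peak.

    ``pedestal`` is the local valley level the integration is referenced to
    (zero on a clean baseline); the recorded ``area`` is pedestal-corrected.
    """

    apex_time: float
    apex_height: float
    area: float
    left: float
    right: float
    prominence: float
    pedestal: float = 0.0

    def __post_init__(self) -> None:
        if not self.left < self.apex_time < self.right:
            raise ValueError("peak bounds must bracket the apex")


def estimate_noise_sd(intensities: np.ndarray) -> float:
    """Robust white-noise level from second differences.

    Second differencing annihilates both the baseline and the peak slopes
    (first differences would see the slopes of a crowded trace and inflate
    the estimate); for white noise the second difference has variance six
    times the noise variance, hence the 1.4826/sqrt(6) scaling of the median
    absolute deviation.
    """
    d = np.diff(np.asarray(intensities, float), n=2)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(6.0))


def _pick(
    x: np.ndarray,
    t: np.ndarray,
    min_prominence: float | None,
    min_snr: float,
) -> tuple[np.ndarray, dict]:
    """Shared find_peaks call with noise-scaled gates (works on raw traces)."""
    noise = estimate_noise_sd(x)
    prom = min_prominence if min_prominence is not None else 3.0 * noise
    prom = max(prom, 1e-12 * max(float(np.max(np.abs(x), initial=0.0)), 1.0))
    height = min_snr * noise if noise > 0 else None
    idx, props = find_peaks(
        x,
        height=height,
        prominence=prom,
        wlen=PROMINENCE_WLEN,
        width=MIN_WIDTH_SAMPLES,
        rel_height=0.5,
    )
    props["noise"] = noise
    return idx, props


def detect_peaks(
    chrom: Chromatogram,
    min_prominence: float | None = None,
    min_snr: float = DEFAULT_MIN_SNR,
) -> list[Peak]:
    """Detect peaks on a baseline-corrected trace.

    Local maxima with prominence >= ``min_prominence`` (default three times
    the robust noise level) and apex height >= ``min_snr`` times the noise
    level; integration bounds are the prominence bases.  Peaks are returned
    sorted by apex time.
    """
    if chrom.stage is not Stage.BASELINE_CORRECTED:
        raise ValueError(
            f"detect_peaks requires a baseline-corrected trace, got stage={chrom.stage.value!r}"
        )
    x, t = chrom.intensities, chrom.times
    idx, props = _pick(x, t, min_prominence, min_snr)
    noise = props["noise"]
    peaks = []
    for k, i in enumerate(idx):
        lo, hi = int(props["left_bases"][k]), int(props["right_bases"][k])
        # valley-referenced integration: the run-level baseline cannot track
        # the co-elution continuum under every peak, so each peak is
        # integrated above its own local pedestal (median trace level just
        # inside the prominence bases), with bounds tightened to where the
        # pedestal-referenced trace falls below a small height threshold
        ped = 0.5 * (
            float(np.median(x[max(lo - 5, 0) : lo + 6]))
            + float(np.median(x[hi - 5 : hi + 6]))
        )
        ped = min(ped, float(x[i]))  # degenerate flat traces
        thr = ped + max(BOUND_HEIGHT_FRACTION * (x[i] - ped), 2.0 * noise)
        below_l = np.flatnonzero(x[lo:i] < thr)
        if below_l.size:
            lo = lo + int(below_l[-1])
        below_r = np.flatnonzero(x[i + 1 : hi + 1] < thr)
        if below_r.size:
            hi = i + 1 + int(below_r[0])
        peaks.append(
            Peak(
                apex_time=float(t[i]),
                apex_height=float(x[i]),
                area=integrate_peak(chrom, (float(t[lo]), float(t[hi])), pedestal=ped),
                left=float(t[lo]),
                right=float(t[hi]),
                prominence=float(props["prominences"][k]),
                pedestal=ped,
            )
        )
    return peaks


def integrate_peak(
    chrom: Chromatogram,
    peak: "Peak | tuple[float, float]",
    pedestal: float | None = None,
) -> float:
    """Trapezoidal integral of the trace between peak bounds.

    The integral is referenced to the peak's local pedestal (taken from a
    :class:`Peak`, or passed explicitly; zero for plain bounds).  Negative
    integrals (possible after baseline subtraction in noise) are floored at
    zero with a warning.
    """
    if isinstance(peak, Peak):
        left, right = peak.left, peak.right
        if pedestal is None:
            pedestal = peak.pedestal
    else:
        left, right = peak
    if pedestal is None:
        pedestal = 0.0
    t = chrom.times
    if left < t[0] - 1e-9 or right > t[-1] + 1e-9 or right <= left:
        raise ValueError(f"peak bounds [{left}, {right}] outside trace grid")
    lo, hi = np.searchsorted(t, [left, right])
    hi = min(hi, t.size - 1)
    area = float(
        np.trapezoid(chrom.intensities[lo : hi + 1] - pedestal, t[lo : hi + 1])
    )
    if area < 0:
        warnings.warn(f"negative peak area {area:.3g} floored at 0", stacklevel=2)
        return 0.0
    return area


# ---------------------------------------------------------------------------
# anchors and alignment
# ---------------------------------------------------------------------------


def _cluster_1d(values: np.ndarray, gap: float) -> np.ndarray:
    """Single-linkage clustering of sorted 1-D values: split where the gap
    between neighbours exceeds ``gap``.  Returns cluster labels in the order
    of the (sorted) input."""
    if values.size == 0:
        return np.zeros(0, dtype=int)
    labels = np.zeros(values.size, dtype=int)
    labels[1:] = np.cumsum(np.diff(values) > gap)
    return labels


#: Candidate anchors closer together than this are ambiguous for nearest-apex
#: matching under retention-time jitter and are skipped.
ANCHOR_MIN_ISOLATION = 10.0


def estimate_anchor_rts(
    samples: list[Chromatogram],
    candidate_rts: np.ndarray | None = None,
    n_anchors: int = 6,
    tolerance: float = DEFAULT_TOLERANCE,
    min_snr: float = DEFAULT_MIN_SNR,
) -> np.ndarray:
    """Landmark retention times: abundant, consistently present, isolated peaks.

    ``candidate_rts`` are known compound locations (typically the library
    RTs).  Candidates with a neighbouring candidate closer than the
    isolation distance are discarded — a landmark that can be confused with
    its neighbour under retention-time jitter is useless for shift
    estimation.  Each surviving candidate is scored by the median (over
    samples) height of the nearest detected apex within +/-``tolerance``
    (zero when absent, so inconsistently present compounds rank low); the
    ``n_anchors`` best candidate RTs are returned sorted.  Raw traces are
    fine: the peak gates are prominence-based.

    Without candidates the tallest well-isolated detected peaks of the
    first sample serve as (shift-contaminated) candidate locations.
    """
    per_sample: list[tuple[np.ndarray, np.ndarray]] = []
    for chrom in samples:
        idx, _ = _pick(chrom.intensities, chrom.times, None, min_snr)
        per_sample.append((chrom.times[idx], chrom.intensities[idx]))

    if candidate_rts is None:
        if not per_sample or per_sample[0][0].size == 0:
            return np.zeros(0)
        apx, hts = per_sample[0]
        order = np.argsort(hts)[::-1]
        cands: list[float] = []
        for j in order:
            if all(abs(apx[j] - c) >= ANCHOR_MIN_ISOLATION for c in cands):
                cands.append(float(apx[j]))
            if len(cands) >= 4 * n_anchors:
                break
        candidate_rts = np.sort(cands)
    candidate_rts = np.sort(np.asarray(candidate_rts, dtype=float))

    isolated = []
    for i, rt in enumerate(candidate_rts):
        gaps = np.abs(np.delete(candidate_rts, i) - rt)
        if gaps.size == 0 or gaps.min() >= ANCHOR_MIN_ISOLATION:
            isolated.append(rt)

    scored = []
    for rt in isolated:
        heights = []
        for apx, hts in per_sample:
            if apx.size == 0:
                heights.append(0.0)
                continue
            j = int(np.argmin(np.abs(apx - rt)))
            heights.append(float(hts[j]) if abs(apx[j] - rt) <= tolerance else 0.0)
        scored.append((float(np.median(heights)), rt))
    scored.sort(key=lambda r: -r[0])
    return np.sort(np.asarray([rt for _, rt in scored[:n_anchors]]))


#: Largest global retention-time shift the aligner will consider (seconds).
MAX_GLOBAL_SHIFT = 8.0
#: Agreement window of the shift vote; generous against per-peak jitter but
#: narrower than typical compound spacing.
SHIFT_VOTE_WINDOW = 1.2


def _vote_shift(
    apx: np.ndarray,
    anchor_rts: np.ndarray,
    tolerance: float,
    max_shift: float = MAX_GLOBAL_SHIFT,
) -> float | None:
    """Global shift by consensus voting over candidate anchor offsets.

    A nearest-match median is easily poisoned when a strongly shifted
    sample's anchors sit closer to a *neighbouring* compound than to their
    own nominal position.  Voting fixes this: every apex-to-anchor offset
    within the shift range is a candidate, the offset grid value consistent
    with the most anchors wins (ties: smallest magnitude), and the final
    shift is the median of the winning matches.
    """
    offsets_per_anchor = []
    for rt in anchor_rts:
        d = apx - rt
        offsets_per_anchor.append(d[np.abs(d) <= max_shift])
    if not any(len(o) for o in offsets_per_anchor):
        return None
    grid = np.arange(-max_shift, max_shift + 1e-9, 0.1)
    votes = np.zeros(grid.size, dtype=int)
    for offs in offsets_per_anchor:
        if len(offs):
            votes += (np.min(np.abs(grid[:, None] - offs[None, :]), axis=1) <= SHIFT_VOTE_WINDOW)
    best = votes.max()
    winners = grid[votes == best]
    s0 = float(winners[np.argmin(np.abs(winners))])
    matched = []
    for offs in offsets_per_anchor:
        if len(offs):
            j = int(np.argmin(np.abs(offs - s0)))
            if abs(offs[j] - s0) <= max(SHIFT_VOTE_WINDOW, tolerance / 2.0):
                matched.append(offs[j])
    return float(np.median(matched)) if matched else s0


@dataclass
class Alignment:
    """Cross-sample feature grid produced by :func:`align_samples`."""

    features: pd.DataFrame  # feature_id, consensus_rt, n_present
    areas: pd.DataFrame  # samples x features, NaN where absent
    apex_times: pd.DataFrame  # samples x features, NaN where absent
    shifts: pd.Series  # per-sample global RT shift (seconds)


def align_samples(
    peaklists: dict[str, list[Peak]],
    tolerance: float = DEFAULT_TOLERANCE,
    min_presence: float = DEFAULT_MIN_PRESENCE,
    anchor_rts: np.ndarray | None = None,
) -> Alignment:
    """Align per-sample peak lists into consensus features.

    Three steps: (1) each sample's global RT shift is the median offset of
    its peaks nearest to the anchor RTs (zero if no anchors supplied or none
    matched, with a warning in the latter case); (2) shifted apexes are
    pooled and single-linkage clustered, splitting where the gap exceeds
    ``tolerance``; (3) clusters present in >= ``min_presence`` of samples
    become features, and each sample contributes its nearest unassigned apex
    within ``tolerance``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not 0 < min_presence <= 1:
        raise ValueError("min_presence must be in (0, 1]")
    sample_ids = list(peaklists)
    n = len(sample_ids)

    shifts = {}
    for sid in sample_ids:
        apx = np.asarray([p.apex_time for p in peaklists[sid]])
        shift = 0.0
        if anchor_rts is not None and len(anchor_rts) and apx.size:
            shift = _vote_shift(apx, np.asarray(anchor_rts), tolerance)
            if shift is None:
                warnings.warn(f"sample {sid}: no anchors matched, using zero shift", stacklevel=2)
                shift = 0.0
        shifts[sid] = shift

    pooled_t, pooled_owner, pooled_idx = [], [], []
    for si, sid in enumerate(sample_ids):
        for pi, p in enumerate(peaklists[sid]):
            pooled_t.append(p.apex_time - shifts[sid])
            pooled_owner.append(si)
            pooled_idx.append(pi)
    pooled_t = np.asarray(pooled_t)
    pooled_owner = np.asarray(pooled_owner, dtype=int)
    pooled_idx = np.asarray(pooled_idx, dtype=int)
    order = np.argsort(pooled_t)
    pooled_t, pooled_owner, pooled_idx = pooled_t[order], pooled_owner[order], pooled_idx[order]
    labels = _cluster_1d(pooled_t, tolerance)

    consensus = []
    for lab in np.unique(labels):
        m = labels == lab
        if np.unique(pooled_owner[m]).size >= min_presence * n:
            consensus.append((float(np.median(pooled_t[m])), int(np.unique(pooled_owner[m]).size)))
    consensus.sort()
    feature_ids = [f"rt{rt:06.1f}" for rt, _ in consensus]
    features = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "consensus_rt": [rt for rt, _ in consensus],
            "n_present": [c for _, c in consensus],
        }
    )

    areas = pd.DataFrame(np.nan, index=sample_ids, columns=feature_ids)
    apex_times = pd.DataFrame(np.nan, index=sample_ids, columns=feature_ids)
    for sid in sample_ids:
        plist = peaklists[sid]
        if not plist:
            continue
        apx = np.asarray([p.apex_time for p in plist]) - shifts[sid]
        used = np.zeros(len(plist), dtype=bool)
        for fid, (rt, _) in zip(feature_ids, consensus):
            cand = np.flatnonzero(~used & (np.abs(apx - rt) <= tolerance))
            if cand.size:
                j = cand[np.argmin(np.abs(apx[cand] - rt))]
                used[j] = True
                areas.loc[sid, fid] = plist[j].area
                apex_times.loc[sid, fid] = plist[j].apex_time
    return Alignment(
        features=features,
        areas=areas,
        apex_times=apex_times,
        shifts=pd.Series(shifts, name="rt_shift"),
    )


def match_library(consensus_rts: np.ndarray, library: CompoundLibrary) -> pd.DataFrame:
    """Annotate consensus features with nearest library compounds.

    One-to-one: a library record annotates at most one feature; conflicts are
    resolved closest-first, ties in favour of the smaller library RT.
    Returns a DataFrame with ``annotation`` (None when unmatched) and the
    matched ``library_rt``.
    """
    consensus_rts = np.asarray(consensus_rts, dtype=float)
    names = library.qualified_names()
    pairs = []
    for fi, rt in enumerate(consensus_rts):
        for li, lrt in enumerate(library.rts):
            d = abs(rt - lrt)
            if d <= library.tolerance:
                pairs.append((d, lrt, fi, li))
    pairs.sort()
    annotation: list[str | None] = [None] * consensus_rts.size
    library_rt = np.full(consensus_rts.size, np.nan)
    used_f = set()
    used_l = set()
    for d, lrt, fi, li in pairs:
        if fi in used_f or li in used_l:
            continue
        used_f.add(fi)
        used_l.add(li)
        annotation[fi] = names[li]
        library_rt[fi] = lrt
    return pd.DataFrame({"annotation": annotation, "library_rt": library_rt})


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Samples x features abundance table in transformed units.

    Values are ``log10(area + eps)`` (``eps`` = 1% of the smallest positive
    area, which also imputes absent peaks) centered and scaled per feature on
    the training rows only.  The transform descriptor records every fitted
    quantity so the matrix is reproducible and leak-checkable.
    """

    values: pd.DataFrame
    features: pd.DataFrame  # feature_id, consensus_rt, annotation, library_rt
    transform: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def panel_columns(self, panel: list[str]) -> np.ndarray:
        return self.values[list(panel)].to_numpy(dtype=float)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(directory / "feature_matrix.csv", index_label="sample_id")
        self.features.to_csv(directory / "features_meta.csv", index=False)
        with open(directory / "transform.json", "w", encoding="utf-8") as fh:
            json.dump(self.transform, fh, indent=2, sort_keys=True)


def build_feature_matrix(
    alignment: Alignment,
    train_ids: list[str],
    annotations: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Log-transform, impute and train-only standardize aligned areas.

    Features with zero variance on the training rows are dropped with a
    warning (they carry no discriminative information and would break the
    scaling).
    """
    areas = alignment.areas
    missing = [sid for sid in train_ids if sid not in areas.index]
    if missing:
        raise ValueError(f"training ids not in alignment: {missing}")
    positive = areas.to_numpy(dtype=float)
    positive = positive[np.isfinite(positive) & (positive > 0)]
    eps = 0.01 * float(positive.min()) if positive.size else 1e-12
    logged = np.log10(areas.fillna(0.0).to_numpy(dtype=float) + eps)
    values = pd.DataFrame(logged, index=areas.index, columns=areas.columns)

    train = values.loc[list(train_ids)]
    center = train.mean(axis=0)
    scale = train.std(axis=0, ddof=1)
    dead = scale[(scale == 0) | ~np.isfinite(scale)].index
    if len(dead):
        warnings.warn(f"dropping {len(dead)} zero-variance features: {list(dead)}", stacklevel=2)
        values = values.drop(columns=dead)
        center = center.drop(index=dead)
        scale = scale.drop(index=dead)
    values = (values - center) / scale

    features = (
        alignment.features.set_index("feature_id")
        .loc[values.columns]
        .rename_axis("feature_id")
        .reset_index()
    )
    if annotations is not None:
        ann = annotations.copy()
        ann.index = alignment.features["feature_id"]
        features = features.merge(
            ann.loc[values.columns].reset_index(names="feature_id"), on="feature_id", how="left"
        )
    transform = {
        "epsilon": eps,
        "center": {k: float(v) for k, v in center.items()},
        "scale": {k: float(v) for k, v in scale.items()},
        "train_ids": list(train_ids),
    }
    return FeatureMatrix(values=values, features=features, transform=transform)
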
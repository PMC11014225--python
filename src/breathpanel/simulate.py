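"""Synthetic micro-GC breath chromatogram generator.

Generates cohorts of case/control breath chromatograms with the statistical
structure the downstream analysis assumes, together with full ground truth
(per-compound areas and apex times, the planted biomarker panel, and the ids
of deliberately corrupted samples), so that every pipeline stage can be
tested without access to raw clinical data.

Generative model
----------------
Each detectable compound elutes as an exponentially modified Gaussian (EMG):
a Gaussian whose width grows linearly with retention time, convolved with an
exponential tail (detector/column tailing).  Peak areas are log-normal per
compound per sample; in cancer samples the three planted biomarker compounds
have their mean log-amplitude shifted upward by ``effect_size`` standard
deviations of the log-amplitude law.  On top of the peaks sit a slow baseline
drift and white detector noise.  Retention times jitter globally per sample
(injection-timing shift) and independently per peak.

Besides the library compounds, the generator places ``n_unknown`` additional
unannotated compounds at cohort-fixed random retention times: the platform
detects roughly 100 VOCs per breath sample of which only 61 carry a library
identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erfc

from .chromatogram import Chromatogram, Stage
from .library import CompoundLibrary, load_default_library, load_library

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_chromatogram",
    "simulate_cohort",
    "inject_inadequate",
    "assign_roles",
    "simulate_feature_matrix",
    "emg",
]

CRC, HC = "CRC", "HC"

#: Minimum separation (s) enforced when placing unannotated compounds; the
#: RT-dependent term keeps late-eluting unknowns chromatographically
#: resolvable despite the width growth along the run.
UNKNOWN_MIN_SEPARATION = 7.0
UNKNOWN_SEPARATION_SIGMA = 2.5
#: Extra clearance from identified (library) compounds: keeps every unknown
#: resolvable from the annotated peaks it would otherwise shoulder.
UNKNOWN_LIBRARY_SEPARATION = 7.0
#: Clearance around the planted biomarker compounds: the study's discriminant
#: peaks are well-resolved in the real traces, so no unknown may shoulder
#: them in the simulation either.
UNKNOWN_BIOMARKER_SEPARATION = 7.0


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def emg(t: np.ndarray, mu: float, sigma: float, tau: float, area: float = 1.0) -> np.ndarray:
    """Exponentially modified Gaussian profile with unit-normalized area.

    ``mu``/``sigma`` are the location/width of the Gaussian component and
    ``tau`` the exponential tail constant, all in seconds.  The integral over
    the whole line equals ``area``.
    """
    t = np.asarray(t, dtype=float)
    z = (sigma / tau - (t - mu) / sigma) / np.sqrt(2.0)
    log_pref = sigma**2 / (2.0 * tau**2) - (t - mu) / tau
    # erfc underflows before the exponential overflows in the relevant range;
    # clip defensively for far-left evaluation points.
    return area / (2.0 * tau) * np.exp(np.minimum(log_pref, 700.0)) * erfc(z)


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic breath cohort.

    Defaults reproduce the clinical collection this generator emulates:
    36 cancer and 32 control samples, three elevated biomarker compounds
    (2,4-dimethylhexane at 197 s, 2,5-dimethylheptane at 341 s and
    2,2,5,5-tetramethylhexane at 470 s), a 10 Hz detector over a 0-800 s
    separation, and an 18+18 / 18+14 train/test split.
    """

    n_crc: int = 36
    n_hc: int = 32
    library_path: str | None = None  # None -> packaged 61-compound library
    biomarker_rts: tuple[float, ...] = (197.0, 341.0, 470.0)
    effect_size: float = 1.5  # CRC shift of biomarker mean log-amplitude, in amp_log_sd units
    amp_log_mean: float = 0.0
    amp_log_sd: float = 0.5
    baseline_amplitude: float | None = None  # None -> 5% of median peak height
    noise_sd: float | None = None  # None -> 2% of median peak height
    rt_global_jitter_sd: float = 1.0
    rt_peak_jitter_sd: float = 0.5
    peak_width_base_sd: float = 0.8
    peak_width_slope: float = 0.0015  # seconds of sigma per second of RT
    tailing_tau: float = 1.5
    sampling_rate: float = 10.0  # Hz
    duration: float = 800.0  # seconds
    detection_probability: float = 0.9  # per compound per sample; biomarkers always 1.0
    n_unknown: int = 60  # requested unannotated compounds; placement is co-elution-limited
    inadequate_fraction: float = 0.0
    n_train_crc: int = 18
    n_train_hc: int = 18
    random_split: bool = False
    seed: int = 0

    # -- derived ---------------------------------------------------------

    def library(self) -> CompoundLibrary:
        if self.library_path is None:
            return load_default_library()
        return load_library(self.library_path)

    def validate(self) -> None:
        if self.n_crc <= 0 or self.n_hc <= 0:
            raise ConfigurationError("n_crc and n_hc must be positive")
        if not 0.0 <= self.detection_probability <= 1.0:
            raise ConfigurationError("detection_probability must be in [0, 1]")
        if not 0.0 <= self.inadequate_fraction < 1.0:
            raise ConfigurationError("inadequate_fraction must be in [0, 1)")
        n_steps = self.duration * self.sampling_rate
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigurationError(
                "duration * sampling_rate must be an integer number of grid steps"
            )
        lib = self.library()
        for rt in self.biomarker_rts:
            if np.min(np.abs(lib.rts - rt)) > lib.tolerance:
                raise ConfigurationError(
                    f"biomarker RT {rt} s has no library record within "
                    f"{lib.tolerance} s"
                )

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration * self.sampling_rate)) + 1
        return np.arange(n) / self.sampling_rate

    def sigma_at(self, rt: np.ndarray | float) -> np.ndarray | float:
        """Gaussian width of a peak eluting at ``rt`` (widths grow with RT)."""
        return self.peak_width_base_sd + self.peak_width_slope * np.asarray(rt, float)

    def reference_height(self) -> float:
        """Apex height of a median-amplitude peak at mid-run; scale anchor
        for the baseline-drift and noise defaults."""
        sigma = float(self.sigma_at(self.duration / 2.0))
        mu = 5.0 * sigma
        t = np.arange(0.0, mu + 5.0 * sigma + 10.0 * self.tailing_tau, 0.01)
        profile = emg(t, mu, sigma, self.tailing_tau, np.exp(self.amp_log_mean))
        return float(profile.max())

    def resolved_baseline_amplitude(self) -> float:
        if self.baseline_amplitude is not None:
            return self.baseline_amplitude
        return 0.05 * self.reference_height()

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return 0.02 * self.reference_height()


@dataclass
class GroundTruth:
    """Oracle record of a simulated cohort.

    ``peaks``: one row per emitted peak (sample, compound, true apex, true
    area, per-sample global RT shift).  ``panel``: the planted biomarker
    compounds.  ``qc``: ids of samples deliberately corrupted to be
    technically inadequate.
    """

    peaks: pd.DataFrame
    panel: pd.DataFrame
    qc: list[str] = field(default_factory=list)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.peaks.to_csv(directory / "truth_peaks.csv", index=False)
        self.panel.to_csv(directory / "truth_panel.csv", index=False)
        pd.DataFrame({"sample_id": self.qc}).to_csv(directory / "truth_qc.csv", index=False)


# ---------------------------------------------------------------------------
# compound table assembly
# ---------------------------------------------------------------------------


def _place_unknown_rts(config: SimulationConfig, occupied: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Cohort-fixed RTs for unannotated compounds.

    The free stretches of the retention axis are scanned into candidate
    slots, each separated from every neighbour (library compound or other
    slot) by a resolution-aware minimum distance that grows with the local
    peak width; slots get a small random offset, and ``n_unknown`` of them
    are chosen at random.  On a crowded column fewer than ``n_unknown`` may
    fit, which is accepted silently (real traces are co-elution limited
    too).
    """

    def sep(rt: float) -> float:
        return max(
            UNKNOWN_MIN_SEPARATION,
            UNKNOWN_SEPARATION_SIGMA * float(config.sigma_at(rt)),
        )

    def sep_lib(rt) -> np.ndarray | float:
        return np.maximum(
            UNKNOWN_LIBRARY_SEPARATION,
            UNKNOWN_SEPARATION_SIGMA * config.sigma_at(np.asarray(rt, float)),
        )

    occupied = np.sort(np.asarray(occupied, dtype=float))
    lo, hi = 16.0, config.duration - 5.0
    slots: list[float] = []
    t = lo
    while t < hi:
        # conflict if an earlier compound is closer than its own separation,
        # or a later one closer than the candidate's; the jump lands exactly
        # at conflict + sep_lib(conflict), which cannot re-conflict, so the
        # scan always advances.
        left = occupied[(occupied <= t) & (t - occupied < sep_lib(occupied))]
        right = occupied[(occupied > t) & (occupied - t < float(sep_lib(t)))]
        if left.size or right.size:
            blocker = float(max(left.max() if left.size else -np.inf,
                                right.max() if right.size else -np.inf))
            t = blocker + float(sep_lib(blocker)) + 1e-6
            continue
        slots.append(t)
        t += sep(t)
    if not slots:
        return np.zeros(0)
    jitter = rng.uniform(-1.0, 1.0, size=len(slots))
    chosen = rng.permutation(len(slots))[: config.n_unknown]
    rts = np.sort(np.asarray(slots)[chosen] + jitter[chosen])
    clear = np.ones(rts.size, dtype=bool)
    for brt in config.biomarker_rts:
        clear &= np.abs(rts - brt) >= UNKNOWN_BIOMARKER_SEPARATION
    return rts[clear]


def _compound_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """All compounds a cohort can emit: library rows plus placed unknowns.

    Columns: rt, name, is_biomarker, sigma, apex_offset (EMG mode minus the
    Gaussian location, precomputed per compound).
    """
    lib = config.library()
    rts = list(lib.rts)
    names = lib.qualified_names()
    unknown = _place_unknown_rts(config, lib.rts, rng)
    rts.extend(unknown)
    names.extend(f"unknown_{i + 1:03d}" for i in range(len(unknown)))
    df = pd.DataFrame({"rt": rts, "name": names}).sort_values("rt").reset_index(drop=True)

    is_bio = np.zeros(len(df), dtype=bool)
    for brt in config.biomarker_rts:
        j = int(np.argmin(np.abs(lib.rts - brt)))
        target = lib.rts[j]
        is_bio |= np.isclose(df["rt"].to_numpy(), target)
    df["is_biomarker"] = is_bio

    sigma = config.sigma_at(df["rt"].to_numpy())
    df["sigma"] = sigma
    df["apex_offset"] = [
        _emg_mode_offset(s, config.tailing_tau) for s in np.asarray(sigma, float)
    ]
    return df


def _emg_mode_offset(sigma: float, tau: float) -> float:
    """Apex position of a unit EMG relative to its Gaussian location."""
    t = np.arange(-2.0 * sigma, 2.0 * sigma + 5.0 * tau, 0.005)
    return float(t[np.argmax(emg(t, 0.0, sigma, tau))])


# ---------------------------------------------------------------------------
# chromatogram synthesis
# ---------------------------------------------------------------------------


def _baseline_drift(t: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Slow positive drift: two incommensurate low-frequency components."""
    phi1, phi2 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    wave = 1.0 + 0.6 * np.sin(2.0 * np.pi * t / (0.77 * span) + phi1) + 0.3 * np.sin(
        2.0 * np.pi * t / (0.29 * span) + phi2
    )
    return amplitude * wave / 1.9


def simulate_chromatogram(
    config: SimulationConfig,
    group: str,
    rng: np.random.Generator,
    sample_id: str = "sample",
    compounds: pd.DataFrame | None = None,
) -> tuple[Chromatogram, pd.DataFrame]:
    """Simulate one breath chromatogram and its per-compound truth table.

    Parameters
    ----------
    group : {"CRC", "HC"}
        Class label; cancer samples get the biomarker mean-shift.
    compounds : DataFrame, optional
        Precomputed compound table (shared across a cohort so that
        unannotated compounds sit at cohort-fixed RTs).  When omitted, a
        table is drawn from ``rng``.
    """
    config.validate()
    if group not in (CRC, HC):
        raise ValueError(f"group must be {CRC!r} or {HC!r}")
    if compounds is None:
        compounds = _compound_table(config, rng)

    t = config.time_grid()
    n_comp = len(compounds)
    baseline_amp = config.resolved_baseline_amplitude()
    noise_sd = config.resolved_noise_sd()

    # Fixed draw order keeps cohorts reproducible and comparable across
    # configurations that differ only in effect size.
    global_shift = rng.normal(0.0, config.rt_global_jitter_sd)
    detect_u = rng.uniform(size=n_comp)
    jitter = rng.normal(0.0, config.rt_peak_jitter_sd, size=n_comp)
    log_amp = rng.normal(config.amp_log_mean, config.amp_log_sd, size=n_comp)

    is_bio = compounds["is_biomarker"].to_numpy()
    if group == CRC:
        log_amp = log_amp + config.effect_size * config.amp_log_sd * is_bio
    included = (detect_u < config.detection_probability) | is_bio

    signal = _baseline_drift(t, baseline_amp, rng)
    noise = rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else 0.0

    rows = []
    rt = compounds["rt"].to_numpy()
    sigma = compounds["sigma"].to_numpy()
    offset = compounds["apex_offset"].to_numpy()
    names = compounds["name"].to_numpy()
    tau = config.tailing_tau
    dt = 1.0 / config.sampling_rate
    for i in np.flatnonzero(included):
        mu = rt[i] + global_shift + jitter[i]
        area = float(np.exp(log_amp[i]))
        lo = max(0, int((mu - 6.0 * sigma[i]) / dt))
        hi = min(t.size, int((mu + 6.0 * sigma[i] + 10.0 * tau) / dt) + 1)
        if hi <= lo:
            continue
        signal_window = emg(t[lo:hi], mu, sigma[i], tau, area)
        signal[lo:hi] += signal_window
        rows.append(
            {
                "sample_id": sample_id,
                "group": group,
                "compound": names[i],
                "rt_library": rt[i],
                "apex_time": mu + offset[i],
                "area": area,
                "rt_shift": global_shift,
            }
        )

    chrom = Chromatogram(
        sample_id=sample_id,
        times=t,
        intensities=signal + noise,
        stage=Stage.RAW,
        meta={"group": group},
    )
    truth = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "compound", "rt_library", "apex_time", "area", "rt_shift"],
    )
    return chrom, truth


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def assign_roles(
    manifest: pd.DataFrame,
    n_train_crc: int = 18,
    n_train_hc: int = 18,
    random_split: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign train/test roles per group.

    Canonical rule: the first ``n_train_*`` samples of each group in manifest
    order form the training set.  If a group is too small for the requested
    training count, half of it (rounded down) is used instead.  With
    ``random_split`` the within-group order is permuted first.
    """
    manifest = manifest.copy().reset_index(drop=True)
    roles = pd.Series("test", index=manifest.index)
    for grp, n_train in ((CRC, n_train_crc), (HC, n_train_hc)):
        idx = manifest.index[manifest["group"] == grp].to_numpy()
        if len(idx) == 0:
            continue
        n_tr = n_train if n_train < len(idx) else len(idx) // 2
        if random_split:
            if rng is None:
                raise ValueError("random_split requires an rng")
            idx = rng.permutation(idx)
        roles.iloc[idx[:n_tr]] = "train"
    manifest["role"] = roles
    return manifest


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[Chromatogram], pd.DataFrame, GroundTruth]:
    """Simulate a full cohort: traces, manifest and ground truth.

    Reproducible to the byte from ``config.seed``.  If
    ``config.inadequate_fraction`` is positive, the corresponding number of
    samples is corrupted in place and listed in ``GroundTruth.qc``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    compounds = _compound_table(config, rng)

    ids = [f"CRC{i + 1:03d}" for i in range(config.n_crc)] + [
        f"HC{i + 1:03d}" for i in range(config.n_hc)
    ]
    groups = [CRC] * config.n_crc + [HC] * config.n_hc

    chroms: list[Chromatogram] = []
    truth_parts: list[pd.DataFrame] = []
    for sid, grp in zip(ids, groups):
        chrom, truth = simulate_chromatogram(config, grp, rng, sample_id=sid, compounds=compounds)
        chroms.append(chrom)
        truth_parts.append(truth)

    manifest = assign_roles(
        pd.DataFrame({"sample_id": ids, "group": groups}),
        n_train_crc=config.n_train_crc,
        n_train_hc=config.n_train_hc,
        random_split=config.random_split,
        rng=rng,
    )

    panel = compounds.loc[compounds["is_biomarker"], ["rt", "name"]].reset_index(drop=True)
    truth = GroundTruth(peaks=pd.concat(truth_parts, ignore_index=True), panel=panel)

    if config.inadequate_fraction > 0:
        chroms, corrupted = inject_inadequate(
            chroms, config.inadequate_fraction, rng, anchor_candidates=config.library().rts
        )
        truth.qc = corrupted
    return chroms, manifest, truth


# ---------------------------------------------------------------------------
# corruption of technically inadequate samples
# ---------------------------------------------------------------------------


def inject_inadequate(
    samples: list[Chromatogram],
    fraction: float,
    rng: np.random.Generator,
    n_strip: int | None = None,
    anchor_candidates: np.ndarray | None = None,
) -> tuple[list[Chromatogram], list[str]]:
    """Corrupt ``floor(fraction * n)`` samples to be technically inadequate.

    Three corruption modes, chosen at random per victim: (a) global intensity
    scaled far below any plausible QC signal floor, (b) detector saturation
    (clipping at the sample's own 90th intensity percentile, flattening ~10%
    of points), (c) removal of the landmark (anchor) peaks by linear
    interpolation across their elution windows.  Mode (c) strips the top
    ``n_strip`` landmark compounds (default: four more than the QC stage's
    anchor count) so the independently re-estimated QC anchors are covered
    even when corruption itself perturbs the landmark ranking; the removal
    window is wide enough that no edge artifact of the interpolation can be
    mistaken for the landmark under the QC stage's shift compensation.

    Returns the (partially replaced) sample list and the corrupted ids.
    """
    from .peaks import estimate_anchor_rts  # late import: peaks builds on chromatogram only

    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    n = len(samples)
    m = int(fraction * n + 1e-9)
    if m == 0:
        return list(samples), []
    if n_strip is None:
        from .preprocess import DEFAULT_N_ANCHORS

        n_strip = DEFAULT_N_ANCHORS + 4

    victims = sorted(rng.choice(n, size=m, replace=False).tolist())
    anchor_rts = estimate_anchor_rts(
        samples, candidate_rts=anchor_candidates, n_anchors=n_strip
    )
    out = list(samples)
    corrupted: list[str] = []
    for idx in victims:
        chrom = samples[idx]
        mode = int(rng.integers(0, 3))
        x = chrom.intensities.copy()
        if mode == 0:  # (a) signal collapse
            x *= 1e-3
        elif mode == 1:  # (b) saturation clipping
            ceiling = float(np.quantile(x, 0.90))
            x = np.minimum(x, ceiling)
        else:  # (c) anchor-peak removal
            t = chrom.times
            for rt in anchor_rts:
                lo, hi = np.searchsorted(t, [rt - 8.0, rt + 8.0])
                hi = min(hi, t.size - 1)
                lo = max(lo, 0)
                if hi > lo:
                    x[lo : hi + 1] = np.linspace(x[lo], x[hi], hi - lo + 1)
        out[idx] = chrom.with_intensities(x, chrom.stage)
        corrupted.append(chrom.sample_id)
    return out, corrupted


# ---------------------------------------------------------------------------
# amplitude-level shortcut for selection-stage Monte Carlo
# ---------------------------------------------------------------------------


def simulate_feature_matrix(
    n_crc: int,
    n_hc: int,
    n_features: int,
    planted: tuple[int, ...],
    effect_size: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a standardized feature matrix straight from the amplitude law.

    Skips trace rendering and peak recovery: features are the standardized
    log-amplitudes themselves (unit variance, planted columns mean-shifted by
    ``effect_size`` in CRC rows), which is exactly the asymptotic content of
    the chromatogram pipeline's feature matrix.  Used for fast Monte-Carlo
    studies of the selection stage.

    Returns ``(X, y)`` with ``y`` boolean (True = CRC); rows are the CRC
    samples followed by the HC samples.
    """
    n = n_crc + n_hc
    X = rng.normal(size=(n, n_features))
    y = np.zeros(n, dtype=bool)
    y[:n_crc] = True
    for j in planted:
        X[y, j] += effect_size
    return X, y
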
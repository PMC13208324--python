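"""Per-spectrum quality-control metrics and joint flagging.

Four complementary metrics are computed per spectrum and interpreted
together rather than through any single cutoff:

* **Amide I SNR** — maximum rubber-band-corrected signal in the amide I
  window over the SD of linearly detrended residuals in a signal-free
  noise window (with a fallback window when the primary is degenerate).
* **Spike burden** — count of narrow spike events in the fingerprint
  region, found by MAD-based z-scoring of the first difference
  (|z| > 6), with runs of adjacent flagged differences merged into one
  event.
* **Spectral coherence** — cosine similarity to the cohort median
  spectrum within the fingerprint window after vector normalization.
* **Baseline fraction** — area(rubber-band baseline)/area(raw) in the
  fingerprint window, in percent: a compact index of baseline dominance.

Flags are report-only; no sample is ever auto-excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import rubberband_baseline
from .spectra import SpectrumSet, WindowSet

MAD_SCALE = 1.4826  # Gaussian-consistency factor


@dataclass
class QCConfig:
    signal_window: tuple[float, float] = (1600.0, 1700.0)
    noise_window: tuple[float, float] = (1800.0, 1900.0)
    fallback_noise_window: tuple[float, float] = (2000.0, 2200.0)
    spike_window: tuple[float, float] = (900.0, 1800.0)
    fingerprint_window: tuple[float, float] = (900.0, 1800.0)
    z_threshold: float = 6.0
    cosine_flag_threshold: float = 0.99
    metric_outlier_z: float = 3.5  # robust z across samples, per metric

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        for name in (
            "signal_window", "noise_window", "fallback_noise_window",
            "spike_window", "fingerprint_window",
        ):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy lo < hi")


@dataclass
class QCReport:
    """Per-sample QC metric values plus named flags."""

    sample_ids: list[str]
    snr: np.ndarray
    spike_count: np.ndarray
    cosine_to_median: np.ndarray
    baseline_fraction_pct: np.ndarray
    flags: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "snr": self.snr,
                "spike_count": self.spike_count,
                "cosine_to_median": self.cosine_to_median,
                "baseline_fraction_pct": self.baseline_fraction_pct,
            }
        )
        df["flags"] = [";".join(self.flags.get(s, [])) for s in self.sample_ids]
        return df

    @property
    def n_flagged(self) -> int:
        return sum(1 for v in self.flags.values() if v)


def _window_values(spectrum, grid, window):
    mask = (grid >= window[0]) & (grid <= window[1])
    return spectrum[mask], grid[mask]


def _detrended_sd(values: np.ndarray, grid: np.ndarray) -> float:
    """SD of residuals after removing a least-squares linear trend."""
    if values.size < 3:
        return 0.0
    coef = np.polyfit(grid, values, 1)
    resid = values - np.polyval(coef, grid)
    return float(resid.std(ddof=1))


def amide_snr(
    spectrum: np.ndarray, grid: np.ndarray, cfg: QCConfig | None = None
) -> tuple[float, list[str]]:
    """Amide I signal-to-noise ratio; returns (ratio, flags).

    Numerator: max of the rubber-band-corrected spectrum inside the signal
    window.  Denominator: detrended residual SD in the noise window,
    falling back to the fallback window when degenerate (< 1e-12).  If
    both are degenerate the ratio is +inf with a ``degenerate-snr`` flag.
    """
    cfg = cfg or QCConfig()
    spectrum = np.asarray(spectrum, dtype=float)
    grid = np.asarray(grid, dtype=float)
    sig, sig_grid = _window_values(spectrum, grid, cfg.signal_window)
    if sig.size == 0:
        raise ValueError(f"signal window {cfg.signal_window} empty on grid")
    _, corrected = rubberband_baseline(sig, sig_grid)
    numerator = float(corrected.max())
    flags: list[str] = []
    noise, ngrid = _window_values(spectrum, grid, cfg.noise_window)
    sd = _detrended_sd(noise, ngrid)
    if sd < 1e-12:
        noise, ngrid = _window_values(spectrum, grid, cfg.fallback_noise_window)
        sd = _detrended_sd(noise, ngrid)
        flags.append("noise-fallback")
    if sd < 1e-12:
        return float("inf"), flags + ["degenerate-snr"]
    return numerator / sd, flags


def spike_event_count(
    spectrum: np.ndarray, grid: np.ndarray, cfg: QCConfig | None = None
) -> tuple[int, list[str]]:
    """Count narrow spike events in the spike window; returns (count, flags).

    z-scores the first difference of in-window values with the scaled MAD;
    indices with |z| > threshold are flagged and runs of consecutive
    flagged differences merge into one event (a single-point spike makes
    two adjacent large differences and counts once).  Zero MAD (perfectly
    smooth signal) yields 0 events with a ``degenerate-mad`` flag.
    """
    cfg = cfg or QCConfig()
    vals, _ = _window_values(
        np.asarray(spectrum, float), np.asarray(grid, float), cfg.spike_window
    )
    if vals.size < 3:
        raise ValueError("spike window must contain >= 3 grid points")
    d = np.diff(vals)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0:
        return 0, ["degenerate-mad"]
    z = (d - med) / (MAD_SCALE * mad)
    flagged = np.abs(z) > cfg.z_threshold
    # count runs of consecutive True
    events = int(np.sum(flagged[1:] & ~flagged[:-1]) + (1 if flagged[0] else 0))
    return events, []


def cosine_similarity_profile(
    sset: SpectrumSet, cfg: QCConfig | None = None
) -> np.ndarray:
    """Cosine similarity of each spectrum to the cohort median profile.

    Spectra are restricted to the fingerprint window and unit-normalized
    *first*; the reference is the pointwise median of the normalized
    spectra.  Normalizing before the median makes the metric exactly
    invariant to positive per-spectrum scaling (film-thickness effects).
    Values are bounded in [-1, 1].
    """
    cfg = cfg or QCConfig()
    if sset.n_samples < 2:
        raise ValueError("cosine profile needs >= 2 samples (median reference)")
    mask = (sset.wavenumbers >= cfg.fingerprint_window[0]) & (
        sset.wavenumbers <= cfg.fingerprint_window[1]
    )
    sub = sset.intensities[:, mask]
    norms = np.linalg.norm(sub, axis=1)
    bad = np.nonzero(norms == 0)[0]
    if bad.size:
        raise ValueError(
            f"zero-norm spectrum in fingerprint window: {sset.sample_ids[bad[0]]}"
        )
    unit = sub / norms[:, None]
    ref = np.median(unit, axis=0)
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0:
        raise ValueError("median reference has zero norm in fingerprint window")
    sims = unit @ (ref / ref_norm)
    return np.clip(sims, -1.0, 1.0)


def baseline_area_fraction(
    spectrum: np.ndarray, grid: np.ndarray, cfg: QCConfig | None = None
) -> float:
    """Percent of in-window raw area attributable to the rubber-band baseline.

    Areas by trapezoidal integration over the fingerprint window.  Raises
    for nonpositive raw area (shift absorbance nonnegative first).
    """
    cfg = cfg or QCConfig()
    vals, g = _window_values(
        np.asarray(spectrum, float), np.asarray(grid, float), cfg.fingerprint_window
    )
    if vals.size < 3:
        raise ValueError("fingerprint window must contain >= 3 grid points")
    raw_area = float(np.trapezoid(vals, g))
    if raw_area <= 0:
        raise ValueError(
            "nonpositive raw area in fingerprint window; "
            "shift the spectrum nonnegative before computing baseline fraction"
        )
    baseline, _ = rubberband_baseline(vals, g)
    base_area = float(np.trapezoid(baseline, g))
    return 100.0 * base_area / raw_area


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.zeros_like(values)
    return (values - med) / (MAD_SCALE * mad)


def build_qc_report(sset: SpectrumSet, cfg: QCConfig | None = None) -> QCReport:
    """Compute all four metrics per sample and raise joint flags.

    Flags: low cosine similarity, degenerate SNR, and cross-sample robust-z
    outliers (|z| > cfg.metric_outlier_z) on any metric.  Flags are
    informational only — no sample is dropped.
    """
    cfg = cfg or QCConfig()
    grid = sset.wavenumbers
    flags: dict[str, list[str]] = {s: [] for s in sset.sample_ids}
    snr = np.empty(sset.n_samples)
    spikes = np.empty(sset.n_samples, dtype=int)
    basefrac = np.empty(sset.n_samples)
    for i, sid in enumerate(sset.sample_ids):
        row = sset.intensities[i]
        snr[i], fl = amide_snr(row, grid, cfg)
        flags[sid] += [f"snr:{f}" for f in fl if f != "noise-fallback"]
        spikes[i], fl = spike_event_count(row, grid, cfg)
        flags[sid] += [f"spikes:{f}" for f in fl]
        basefrac[i] = baseline_area_fraction(row, grid, cfg)
    cosine = cosine_similarity_profile(sset, cfg)
    for i, sid in enumerate(sset.sample_ids):
        if cosine[i] < cfg.cosine_flag_threshold:
            flags[sid].append("low-cosine")
    finite_snr = np.where(np.isfinite(snr), snr, np.nan)
    metric_cols = {
        "snr": np.nan_to_num(finite_snr, nan=np.nanmedian(finite_snr)),
        "spike_count": spikes.astype(float),
        "cosine": cosine,
        "baseline_fraction": basefrac,
    }
    for name, vals in metric_cols.items():
        z = _robust_z(vals)
        for i, sid in enumerate(sset.sample_ids):
            if abs(z[i]) > cfg.metric_outlier_z:
                flags[sid].append(f"outlier-{name}")
    return QCReport(
        sample_ids=list(sset.sample_ids),
        snr=snr,
        spike_count=spikes,
        cosine_to_median=cosine,
        baseline_fraction_pct=basefrac,
        flags=flags,
    )
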
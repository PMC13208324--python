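"""Synthetic dried-serum FTIR cohort generator with ground-truth sidecars.

Emulates a balanced two-class transplant cohort (default 12 Start&Stop vs
12 No-Stop) measured on a 400-4000 cm^-1 grid at 2 cm^-1 spacing.  Clean
spectra are sums of Gaussian bands mimicking the dominant serum absorptions
(amide I/II protein bands, fingerprint carbohydrate region, C-H stretch
lipid bands); the class effect is an additive amplitude shift planted on
bands inside the discriminant regions reported for this assay
(~946-1161, ~1300 and ~2865-3163 cm^-1).  Corruption layers reproduce the
artifact classes the QC stage is designed to catch: convex polynomial
baseline drift, multiplicative film-thickness gain, white noise, and
sparse single-point spikes.

Every stochastic draw is recorded in a sidecar so any cohort is exactly
reproducible from (seed, parameters) alone.  The RNG is numpy's PCG64,
named in the sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .spectra import SpectrumSet


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``class_delta`` is the additive amplitude difference applied for
    class 1 (Start&Stop) samples; zero means the band carries no class
    information.
    """

    center: float          # cm^-1
    width: float           # Gaussian sigma, cm^-1
    amplitude: float       # absorbance units
    class_delta: float = 0.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")


# Background serum-like bands: amide A/I/II/III, carbohydrate C-O,
# phosphate/glycosidic, CH2/CH3 stretches.  Amplitudes are relative
# absorbance with amide I ~ 1.
DEFAULT_BACKGROUND_BANDS = (
    BandSpec(3290.0, 80.0, 0.50),   # amide A (N-H stretch)
    BandSpec(2960.0, 12.0, 0.18),   # CH3 asym stretch
    BandSpec(2930.0, 18.0, 0.30),   # CH2 asym stretch
    BandSpec(2850.0, 14.0, 0.20),   # CH2 sym stretch
    BandSpec(1650.0, 25.0, 1.00),   # amide I
    BandSpec(1545.0, 25.0, 0.70),   # amide II
    BandSpec(1400.0, 25.0, 0.22),   # COO- sym stretch
    BandSpec(1240.0, 30.0, 0.18),   # amide III / PO2-
    BandSpec(1080.0, 40.0, 0.28),   # carbohydrate C-O / PO2- sym
    BandSpec(700.0, 60.0, 0.10),    # low-fingerprint envelope
)

# Class-effect bands planted inside the discriminant regions
# (carbohydrate 946-1161, amide III ~1300, C-H/N-H stretch 2865-3163).
DEFAULT_EFFECT_BANDS = (
    BandSpec(1045.0, 18.0, 0.10, class_delta=0.030),
    BandSpec(1300.0, 16.0, 0.08, class_delta=0.025),
    BandSpec(2880.0, 14.0, 0.08, class_delta=0.025),
    BandSpec(3100.0, 25.0, 0.08, class_delta=0.030),
)

#: Wavenumber regions in which class effects are planted by default;
#: used by recovery tests as ground truth.
DEFAULT_EFFECT_REGIONS = ((946.0, 1161.0), (1270.0, 1330.0), (2865.0, 3163.0))


@dataclass
class SyntheticTruth:
    """Full generative configuration for one cohort (the 'truth' sidecar).

    ``effect_scale`` multiplies every band's ``class_delta``, so a single
    knob sweeps the cohort from pure-noise (0.0) to strongly separated.
    """

    seed: int
    n_per_class: int = 12
    grid_min: float = 400.0
    grid_max: float = 4000.0
    grid_step: float = 2.0
    bands: tuple[BandSpec, ...] = DEFAULT_BACKGROUND_BANDS + DEFAULT_EFFECT_BANDS
    effect_scale: float = 1.0
    # Convex baseline: a0 + a1*t + a2*t^2 on t in [0,1] with a2 >= 0.
    baseline_offset_range: tuple[float, float] = (0.00, 0.10)
    baseline_slope_range: tuple[float, float] = (-0.05, 0.05)
    baseline_curvature_range: tuple[float, float] = (0.00, 0.08)
    gain_range: tuple[float, float] = (0.85, 1.15)
    noise_sd: float = 0.004
    spike_rate: float = 2.0          # expected spikes per spectrum (Poisson)
    spike_amplitude_range: tuple[float, float] = (0.05, 0.5)
    rng_algorithm: str = "numpy.PCG64"

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if not (0 < self.gain_range[0] <= self.gain_range[1]):
            raise ValueError("gain_range must be positive and ordered")
        if self.baseline_curvature_range[0] < 0:
            raise ValueError("baseline curvature must be nonnegative (convex)")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)

    def scaled_bands(self) -> tuple[BandSpec, ...]:
        return tuple(
            BandSpec(b.center, b.width, b.amplitude, b.class_delta * self.effect_scale)
            for b in self.bands
        )


def band_profile(
    grid: np.ndarray, bands, class_label: int = 0
) -> np.ndarray:
    """Clean spectrum: sum of Gaussian bands on *grid*.

    Class 1 adds each band's ``class_delta`` to its amplitude (floored at
    zero so absorbance stays nonnegative).  An empty band list yields the
    zero vector.
    """
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for b in bands:
        amp = b.amplitude + (b.class_delta if class_label == 1 else 0.0)
        amp = max(amp, 0.0)
        out += amp * np.exp(-0.5 * ((grid - b.center) / b.width) ** 2)
    return out


def corrupt_spectrum(
    clean: np.ndarray,
    truth: SyntheticTruth,
    rng: np.random.Generator,
    n_spikes: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Apply gain, convex baseline, white noise and sparse spikes.

    Returns ``(corrupted, artifacts)`` where *artifacts* records every
    drawn parameter (gain, baseline coefficients, spike indices and
    amplitudes, noise seed state is implicit in call order).  ``n_spikes``
    forces an exact spike count (otherwise Poisson with mean
    ``truth.spike_rate``).
    """
    clean = np.asarray(clean, dtype=float)
    n = clean.size
    gain = rng.uniform(*truth.gain_range)
    a0 = rng.uniform(*truth.baseline_offset_range)
    a1 = rng.uniform(*truth.baseline_slope_range)
    a2 = rng.uniform(*truth.baseline_curvature_range)
    t = np.linspace(0.0, 1.0, n)
    baseline = a0 + a1 * t + a2 * t**2
    baseline -= min(baseline.min(), 0.0)  # keep absorbance nonnegative
    out = gain * clean + baseline
    if truth.noise_sd > 0:
        out = out + rng.normal(0.0, truth.noise_sd, size=n)
    if n_spikes is None:
        n_spikes = int(rng.poisson(truth.spike_rate)) if truth.spike_rate > 0 else 0
    spike_idx = (
        np.sort(rng.choice(n, size=min(n_spikes, n), replace=False))
        if n_spikes > 0
        else np.array([], dtype=int)
    )
    spike_amp = rng.uniform(*truth.spike_amplitude_range, size=spike_idx.size)
    spike_sign = rng.choice([-1.0, 1.0], size=spike_idx.size)
    out[spike_idx] += spike_sign * spike_amp
    artifacts = {
        "gain": float(gain),
        "baseline_coeffs": [float(a0), float(a1), float(a2)],
        "spike_indices": spike_idx.tolist(),
        "spike_amplitudes": (spike_sign * spike_amp).tolist(),
    }
    return out, artifacts


def generate_cohort(truth: SyntheticTruth) -> tuple[SpectrumSet, dict]:
    """Generate a balanced labeled cohort plus its ground-truth sidecar.

    Deterministic under ``truth.seed``: the same truth object always
    produces bit-identical matrices.  The sidecar stores the full truth
    configuration and every per-sample artifact draw.
    """
    rng = np.random.default_rng(truth.seed)
    grid = truth.grid()
    bands = truth.scaled_bands()
    labels = np.array([0] * truth.n_per_class + [1] * truth.n_per_class)
    clean = {c: band_profile(grid, bands, c) for c in (0, 1)}
    rows, per_sample = [], []
    for i, lab in enumerate(labels):
        spec, artifacts = corrupt_spectrum(clean[lab], truth, rng)
        rows.append(spec)
        artifacts["label"] = int(lab)
        per_sample.append(artifacts)
    ids = [f"S{i:03d}" for i in range(labels.size)]
    sset = SpectrumSet(
        grid,
        np.vstack(rows),
        ids,
        labels,
        meta={"source": "synthetic", "seed": truth.seed},
    )
    sidecar = {
        "truth": _truth_dict(truth),
        "effect_regions": [list(r) for r in DEFAULT_EFFECT_REGIONS],
        "samples": {sid: art for sid, art in zip(ids, per_sample)},
    }
    return sset, sidecar


def _truth_dict(truth: SyntheticTruth) -> dict:
    d = asdict(truth)
    d["bands"] = [asdict(b) for b in truth.bands]
    return d
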
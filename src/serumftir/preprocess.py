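"""Composable, order-explicit spectral preprocessing.

Implements the variant grid evaluated for this assay: rubber-band
baseline correction (lower convex hull), unit vector normalization,
Savitzky-Golay derivatives (polynomial order 2, 15-point window),
atmospheric-region masking, and window restriction — each a pure function
on a SpectrumSet, composed in declared order by
:func:`apply_preprocess_pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectrumSet, WindowSet, FULL_WINDOWS, restrict_to_windows

# Atmospheric interference regions replaced by linear interpolation:
# CO2 asymmetric stretch and the water-vapor rotational band edge.
CO2_REGION = (2300.0, 2400.0)
WATER_VAPOR_REGION = (1790.0, 1960.0)


def rubberband_baseline(
    spectrum: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rubber-band baseline: lower convex hull of (grid, value) points.

    Returns ``(baseline, corrected)``.  The baseline is the hull linearly
    interpolated between vertices, so ``baseline <= spectrum`` pointwise,
    ``corrected = spectrum - baseline >= 0`` and corrected is exactly 0 at
    hull vertices (including both endpoints).
    """
    y = np.asarray(spectrum, dtype=float)
    x = np.asarray(grid, dtype=float)
    n = y.size
    if n < 2:
        return y.copy(), np.zeros_like(y)
    # Andrew monotone chain, lower hull only (x strictly ascending).
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # cross product of (k-j) x (i-j); <= 0 means k is not below chord
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    baseline = np.interp(x, x[hull], y[hull])
    corrected = y - baseline
    corrected[corrected < 0] = 0.0  # clamp float dust at hull vertices
    return baseline, corrected


def vector_normalize(matrix: np.ndarray, sample_ids=None) -> np.ndarray:
    """Scale each row to unit Euclidean norm.

    Raises on a zero-norm row, naming the sample if IDs are given.
    """
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    norms = np.linalg.norm(m, axis=1)
    bad = np.nonzero(norms == 0)[0]
    if bad.size:
        name = sample_ids[bad[0]] if sample_ids is not None else f"row {bad[0]}"
        raise ValueError(f"cannot vector-normalize zero-norm spectrum: {name}")
    return m / norms[:, None]


def _contiguous_segments(grid: np.ndarray, rtol: float = 1e-6) -> list[slice]:
    """Split a grid into uniformly spaced contiguous runs.

    A spacing jump beyond 1.5x the smallest spacing starts a new segment
    (window restriction leaves such gaps); within a segment, spacing must
    be uniform to relative tolerance *rtol*.
    """
    if grid.size < 2:
        return [slice(0, grid.size)]
    d = np.diff(grid)
    step = d.min()
    breaks = np.nonzero(d > 1.5 * step)[0]
    edges = [0, *(b + 1 for b in breaks), grid.size]
    segs = [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]
    for s in segs:
        dd = np.diff(grid[s])
        if dd.size and not np.allclose(dd, dd[0], rtol=rtol, atol=0):
            raise ValueError(
                "non-uniform wavenumber spacing within a contiguous segment; "
                "restrict to uniformly sampled windows first"
            )
    return segs


def savgol_derivative(
    matrix: np.ndarray,
    grid: np.ndarray,
    order: int = 2,
    window_pts: int = 15,
    deriv: int = 0,
) -> np.ndarray:
    """Savitzky-Golay smoothing/derivative per contiguous grid segment.

    The derivative is scaled by the grid spacing (units of absorbance per
    (cm^-1)^deriv).  Edges keep the polynomial fit of the terminal window
    (scipy mode="interp"), so output length equals input length.  When
    window restriction has created gaps, the filter is applied per
    contiguous segment and never across a gap.
    """
    if window_pts % 2 == 0 or window_pts <= order:
        raise ValueError("window_pts must be odd and > polynomial order")
    if deriv not in (0, 1, 2):
        raise ValueError("deriv must be 0, 1 or 2")
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    grid = np.asarray(grid, dtype=float)
    out = np.empty_like(m)
    for seg in _contiguous_segments(grid):
        g = grid[seg]
        if g.size < window_pts:
            raise ValueError(
                f"segment of {g.size} points shorter than the "
                f"{window_pts}-point filter window"
            )
        delta = g[1] - g[0] if g.size > 1 else 1.0
        out[:, seg] = savgol_filter(
            m[:, seg], window_pts, order, deriv=deriv, delta=delta,
            axis=1, mode="interp",
        )
    return out


def atmospheric_mask(spectrum: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Replace CO2 (2300-2400) and water-vapor (1790-1960 cm^-1) regions
    by linear interpolation between the region-edge values.

    Regions with no grid points are skipped; all other points untouched.
    """
    y = np.asarray(spectrum, dtype=float).copy()
    x = np.asarray(grid, dtype=float)
    for lo, hi in (WATER_VAPOR_REGION, CO2_REGION):
        inside = (x >= lo) & (x <= hi)
        if not inside.any():
            continue
        outside = ~inside
        if outside.sum() < 2:
            continue
        y[inside] = np.interp(x[inside], x[outside], y[outside])
    return y


@dataclass
class PreprocessConfig:
    """Ordered preprocessing recipe.

    ``steps`` entries are ``"rubberband"``, ``"vector_normalize"``,
    ``"atmospheric_mask"`` or ``("savgol", order, window_pts, deriv)``
    (the bare string ``"savgol"`` uses the 2/15-point defaults with
    deriv=2).  ``window_stage`` says whether window restriction happens
    before or after the steps.
    """

    steps: list = field(default_factory=list)
    windows: WindowSet = field(default_factory=lambda: FULL_WINDOWS)
    window_stage: str = "before"  # "before" | "after"

    def __post_init__(self):
        if self.window_stage not in ("before", "after"):
            raise ValueError("window_stage must be 'before' or 'after'")
        self.steps = [_canonical_step(s) for s in self.steps]

    def provenance(self) -> str:
        parts = [_step_name(s) for s in self.steps]
        return (
            f"windows={self.windows.intervals}@{self.window_stage};"
            f"steps=[{','.join(parts)}]"
        )


def _canonical_step(step):
    if isinstance(step, str):
        if step == "savgol":
            return ("savgol", 2, 15, 2)
        if step in ("rubberband", "vector_normalize", "atmospheric_mask"):
            return step
        raise ValueError(f"unknown preprocessing step {step!r}")
    name, *args = step
    if name != "savgol":
        raise ValueError(f"unknown parametric step {name!r}")
    order, window_pts, deriv = (list(args) + [2, 15, 2])[:3]
    return ("savgol", int(order), int(window_pts), int(deriv))


def _step_name(step) -> str:
    if isinstance(step, tuple):
        return f"savgol(o={step[1]},w={step[2]},d={step[3]})"
    return step


def apply_preprocess_pipeline(
    sset: SpectrumSet, cfg: PreprocessConfig
) -> SpectrumSet:
    """Apply the configured steps, in order, identically to every sample.

    Window restriction happens at the configured stage; derivatives are
    computed per contiguous window segment.  A provenance string is
    recorded in the output metadata.
    """
    out = sset
    if cfg.window_stage == "before":
        out = restrict_to_windows(out, cfg.windows)
    matrix = out.intensities
    grid = out.wavenumbers
    for step in cfg.steps:
        if step == "rubberband":
            matrix = np.vstack(
                [rubberband_baseline(row, grid)[1] for row in matrix]
            )
        elif step == "vector_normalize":
            matrix = vector_normalize(matrix, out.sample_ids)
        elif step == "atmospheric_mask":
            matrix = np.vstack([atmospheric_mask(row, grid) for row in matrix])
        else:
            _, order, window_pts, deriv = step
            matrix = savgol_derivative(matrix, grid, order, window_pts, deriv)
    meta = dict(sset.meta)
    meta["preprocess"] = cfg.provenance()
    result = SpectrumSet(grid, matrix, sset.sample_ids, sset.labels, meta)
    if cfg.window_stage == "after":
        result = restrict_to_windows(result, cfg.windows)
    return result


# ---------------------------------------------------------------------------
# Named variants: the published sensitivity grid (main x secondary
# preprocessing), plus "raw" as the no-op reference.

VARIANTS: dict[str, PreprocessConfig] = {}


def _register_variants():
    sg = lambda d: ("savgol", 2, 15, d)  # noqa: E731
    defs = {
        "raw": [],
        "2nd_derivative": [sg(2)],
        "2nd_derivative+vector_norm": [sg(2), "vector_normalize"],
        "atmospheric": ["atmospheric_mask"],
        "vector_norm": ["vector_normalize"],
        "1st_derivative": [sg(1)],
        "1st_derivative+vector_norm": [sg(1), "vector_normalize"],
        "rubberband": ["rubberband"],
        "rubberband+vector_norm": ["rubberband", "vector_normalize"],
    }
    for name, steps in defs.items():
        # atmospheric masking must see the full grid, so windows come after
        stage = "after" if "atmospheric_mask" in steps else "before"
        VARIANTS[name] = PreprocessConfig(
            steps=steps, windows=FULL_WINDOWS, window_stage=stage
        )


_register_variants()

#: Default analysis recipe: SG 2nd derivative + vector normalization on
#: the fingerprint/amide + C-H stretch windows.
DEFAULT_PIPELINE = VARIANTS["2nd_derivative+vector_norm"]


def get_variant(name: str) -> PreprocessConfig:
    try:
        return VARIANTS[name]
    except KeyError:
        raise ValueError(
            f"unknown variant {name!r}; valid names: {sorted(VARIANTS)}"
        ) from None
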
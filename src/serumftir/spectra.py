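"""Spectral containers and delimited-text / JCAMP-DX I/O.

The pipeline currency is :class:`SpectrumSet`: a strictly ascending
wavenumber grid (cm^-1) plus a samples-by-wavenumbers absorbance matrix,
optional binary class labels and free per-sample metadata.  Wide CSV/TSV
(samples as rows, numeric wavenumber columns) is the canonical exchange
format; JCAMP-DX import is a single-spectrum convenience.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical class names.  Class 1 ("Start&Stop", transient graft
#: dysfunction with recovery) is the positive class everywhere.
NEGATIVE_CLASS = "No-Stop"
POSITIVE_CLASS = "Start&Stop"
CLASS_NAMES = (NEGATIVE_CLASS, POSITIVE_CLASS)


class SpectraFormatError(ValueError):
    """Raised for malformed spectral tables or JCAMP-DX files."""


def normalize_label(label) -> int:
    """Map a class label to the internal {0, 1} encoding.

    Accepts the canonical names, 0/1 integers and their string forms.
    """
    s = str(label).strip()
    if s in (NEGATIVE_CLASS, "0", "no", "No", "NO"):
        return 0
    if s in (POSITIVE_CLASS, "1", "yes", "Yes", "YES"):
        return 1
    raise SpectraFormatError(
        f"unrecognized class label {label!r}; expected one of {CLASS_NAMES}"
    )


@dataclass
class SpectrumSet:
    """Wavenumber grid + intensity matrix + sample identity.

    Parameters
    ----------
    wavenumbers
        Strictly ascending vector in cm^-1, length ``n_points``.
    intensities
        Absorbance matrix, shape ``(n_samples, n_points)``.
    sample_ids
        Unique per-sample identifier strings.
    labels
        Optional binary class vector (0 = No-Stop, 1 = Start&Stop).
    meta
        Free key/value metadata (e.g. preprocessing provenance).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float).ravel()
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise SpectraFormatError("wavenumber grid must be strictly ascending")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraFormatError("intensities contain NaN/Inf")
        if self.intensities.shape != (len(self.sample_ids), self.wavenumbers.size):
            raise SpectraFormatError(
                f"shape mismatch: {self.intensities.shape} vs "
                f"{len(self.sample_ids)} samples x {self.wavenumbers.size} points"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SpectraFormatError("duplicate sample IDs")
        if self.labels is not None:
            self.labels = np.asarray(
                [normalize_label(v) for v in np.asarray(self.labels).ravel()],
                dtype=int,
            )
            if self.labels.size != len(self.sample_ids):
                raise SpectraFormatError("labels length != number of samples")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    def label_names(self) -> list[str] | None:
        if self.labels is None:
            return None
        return [CLASS_NAMES[v] for v in self.labels]

    def without_labels(self) -> "SpectrumSet":
        """Label-free view for stages that must not see class membership."""
        return SpectrumSet(
            self.wavenumbers, self.intensities, self.sample_ids, None, dict(self.meta)
        )

    def subset(self, mask) -> "SpectrumSet":
        """Row subset by boolean mask or index array."""
        idx = np.arange(self.n_samples)[np.asarray(mask)]
        return SpectrumSet(
            self.wavenumbers,
            self.intensities[idx],
            [self.sample_ids[i] for i in idx],
            None if self.labels is None else self.labels[idx],
            dict(self.meta),
        )


@dataclass
class WindowSet:
    """Ordered list of closed wavenumber intervals [lo, hi] in cm^-1.

    Intervals are sorted and overlapping/touching ones merged on
    construction, so the union is canonical.
    """

    intervals: list[tuple[float, float]]

    def __post_init__(self):
        ivals = [(float(lo), float(hi)) for lo, hi in self.intervals]
        for lo, hi in ivals:
            if not lo < hi:
                raise ValueError(f"window interval ({lo}, {hi}) must have lo < hi")
        ivals.sort()
        merged: list[tuple[float, float]] = []
        for lo, hi in ivals:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        self.intervals = merged

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Boolean membership of grid points in the closed-interval union."""
        w = np.asarray(wavenumbers, dtype=float)
        m = np.zeros(w.shape, dtype=bool)
        for lo, hi in self.intervals:
            m |= (w >= lo) & (w <= hi)
        return m


#: Window configuration (i): fingerprint/amide + C-H stretch.
FULL_WINDOWS = WindowSet([(600.0, 1900.0), (2800.0, 3400.0)])
#: Window configuration (ii): reduced fingerprint + C-H stretch.
REDUCED_WINDOWS = WindowSet([(600.0, 900.0), (2800.0, 3400.0)])


# ---------------------------------------------------------------------------
# Wide-table I/O

_ID_COLUMNS = ("sample_id", "id", "sample")


def read_spectra_table(
    path,
    label_column: str | None = "label",
    delimiter: str | None = None,
) -> SpectrumSet:
    """Read a wide spectral matrix (rows = samples, columns = wavenumbers).

    The header must hold numeric wavenumbers (any order) plus optional
    ID/label columns.  The grid is sorted ascending with intensity columns
    permuted accordingly; duplicate wavenumber columns are rejected.
    """
    sep = delimiter
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    # check the raw header before pandas mangles duplicate column names
    with open(path, encoding="utf-8") as fh:
        raw_header = fh.readline().rstrip("\n").split(sep)
    if len(set(raw_header)) != len(raw_header):
        dupes = sorted({c for c in raw_header if raw_header.count(c) > 1})
        raise SpectraFormatError(f"duplicate wavenumber columns: {dupes}")
    df = pd.read_csv(path, sep=sep, dtype=str)
    meta_cols, wn_cols = [], []
    for col in df.columns:
        if col == label_column or col.lower() in _ID_COLUMNS:
            meta_cols.append(col)
            continue
        try:
            wn_cols.append((float(col), col))
        except ValueError:
            raise SpectraFormatError(
                f"non-numeric header cell {col!r} outside declared metadata columns"
            ) from None
    if not wn_cols:
        raise SpectraFormatError("no numeric wavenumber columns found")
    values = [w for w, _ in wn_cols]
    if len(set(values)) != len(values):
        dupes = sorted({v for v in values if values.count(v) > 1})
        raise SpectraFormatError(f"duplicate wavenumber columns: {dupes}")
    wn_cols.sort(key=lambda t: t[0])
    grid = np.array([w for w, _ in wn_cols])
    matrix = df[[c for _, c in wn_cols]].to_numpy(dtype=float)

    id_col = next((c for c in df.columns if c.lower() in _ID_COLUMNS), None)
    ids = (
        df[id_col].tolist()
        if id_col is not None
        else [f"S{i:03d}" for i in range(len(df))]
    )
    labels = None
    if label_column is not None and label_column in df.columns:
        labels = df[label_column].tolist()
    return SpectrumSet(grid, matrix, ids, labels)


def write_spectra_table(sset: SpectrumSet, path, delimiter: str = ",") -> None:
    """Write a SpectrumSet as a wide table re-readable by read_spectra_table.

    Floats are formatted at 17 significant digits so the round trip is exact
    to float-text precision.
    """
    cols = {"sample_id": sset.sample_ids}
    if sset.labels is not None:
        cols["label"] = sset.label_names()
    for j, w in enumerate(sset.wavenumbers):
        cols[np.format_float_positional(w, trim="-")] = sset.intensities[:, j]
    df = pd.DataFrame(cols)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# JCAMP-DX (minimal subset: XYDATA=(X++(Y..Y)) and XYPOINTS)


def _jcamp_records(text: str) -> tuple[dict, list[str]]:
    """Split label-data records; return header dict and data-block lines."""
    header: dict[str, str] = {}
    data_lines: list[str] = []
    current: str | None = None
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line:
            continue
        if line.startswith("##"):
            name, _, value = line[2:].partition("=")
            key = name.strip().upper().replace(" ", "")
            if key in ("XYDATA", "XYPOINTS"):
                current = key
                header[key] = value.strip()
            else:
                current = None
                header[key] = value.strip()
        elif current is not None:
            data_lines.append(line)
    if data_lines and "XYPOINTS" in header and "XYDATA" not in header:
        header["_MODE"] = "XYPOINTS"
    elif "XYDATA" in header:
        header["_MODE"] = "XYDATA"
    return header, data_lines


def read_jcampdx(path) -> SpectrumSet:
    """Read a single-spectrum JCAMP-DX file.

    Supports ``##XYDATA=(X++(Y..Y))`` (first number per line is the
    uncompressed X start, remaining numbers are Y values at FIRSTX/LASTX
    spacing) and ``##XYPOINTS=(XY..XY)``.  XFACTOR/YFACTOR scaling is
    applied; a descending abscissa is flipped to ascending.
    """
    with open(path, encoding="utf-8", errors="replace") as fh:
        header, data_lines = _jcamp_records(fh.read())
    if "TITLE" not in header:
        raise SpectraFormatError("JCAMP-DX: missing ##TITLE record")
    mode = header.get("_MODE")
    if mode is None or not data_lines:
        raise SpectraFormatError("JCAMP-DX: no XYDATA/XYPOINTS block found")
    xfac = float(header.get("XFACTOR", 1.0))
    yfac = float(header.get("YFACTOR", 1.0))

    if mode == "XYPOINTS":
        xs, ys = [], []
        for line in data_lines:
            for pair in line.replace(";", " ").split():
                x_s, _, y_s = pair.partition(",")
                if not y_s:
                    raise SpectraFormatError(f"JCAMP-DX: bad XY pair {pair!r}")
                xs.append(float(x_s))
                ys.append(float(y_s))
        x = np.array(xs) * xfac
        y = np.array(ys) * yfac
    else:
        for req in ("FIRSTX", "LASTX", "NPOINTS"):
            if req not in header:
                raise SpectraFormatError(f"JCAMP-DX: missing ##{req} record")
        npts = int(float(header["NPOINTS"]))
        firstx = float(header["FIRSTX"])
        lastx = float(header["LASTX"])
        ys = []
        for line in data_lines:
            nums = line.replace(",", " ").split()
            ys.extend(float(v) for v in nums[1:])  # first token is line X start
        if len(ys) != npts:
            raise SpectraFormatError(
                f"JCAMP-DX: NPOINTS={npts} but {len(ys)} Y values read"
            )
        x = np.linspace(firstx, lastx, npts) * xfac
        y = np.array(ys) * yfac

    order = np.argsort(x)
    title = header.get("TITLE") or "jcamp"
    return SpectrumSet(x[order], y[order][None, :], [title])


# ---------------------------------------------------------------------------


def restrict_to_windows(sset: SpectrumSet, windows: WindowSet) -> SpectrumSet:
    """Keep only grid points inside the closed-interval union of *windows*.

    Point order is preserved; labels and metadata pass through untouched.
    Raises if the intersection with the grid is empty.
    """
    mask = windows.mask(sset.wavenumbers)
    if not mask.any():
        raise ValueError(
            f"no grid points fall inside windows {windows.intervals}"
        )
    return SpectrumSet(
        sset.wavenumbers[mask],
        # contiguous copy so downstream reductions are layout-independent
        np.ascontiguousarray(sset.intensities[:, mask]),
        sset.sample_ids,
        sset.labels,
        dict(sset.meta),
    )
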
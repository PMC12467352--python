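"""Spectral power features of voxel time series.

Each voxel's BOLD time series is reduced to eight band powers: the series is
linearly detrended, a one-sided periodogram is computed on the raw DFT grid,
and the periodogram ordinates falling into each of eight frequency bins are
summed.  The default bins are 0.08 Hz wide and centred at 0.04, 0.12, 0.20,
0.28, 0.36, 0.44, 0.52, and 0.60 Hz, spanning 0-0.64 Hz contiguously.

A voxel's feature vector stacks its own 8 band powers with those of its six
face-adjacent neighbours (56 spectral features) and appends the gray-matter
occupancy fraction as a 57th feature.  In ``original`` mode the occupancy
column is kept but set to 0 for every voxel, mirroring the uncorrected
predictor; in ``pva_corrected`` mode it carries the tissue fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .volumes import Volume3D, Volume4D, check_aligned

__all__ = [
    "BandSchema",
    "FeatureMatrix",
    "band_powers",
    "periodogram_power",
    "extract_features",
    "prepare_occupancy",
    "NEIGHBOR_OFFSETS",
]

#: Fixed neighbour order for feature stacking: x-, x+, y-, y+, z-, z+.
NEIGHBOR_OFFSETS = (
    (-1, 0, 0), (1, 0, 0),
    (0, -1, 0), (0, 1, 0),
    (0, 0, -1), (0, 0, 1),
)

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass(frozen=True)
class BandSchema:
    """Frequency-bin schema: bin k covers [midpoint_k - w/2, midpoint_k + w/2)."""

    midpoints_hz: tuple[float, ...] = (0.04, 0.12, 0.20, 0.28, 0.36, 0.44, 0.52, 0.60)
    bin_width_hz: float = 0.08

    def __post_init__(self):
        mids = np.asarray(self.midpoints_hz, dtype=float)
        if mids.size == 0 or np.any(np.diff(mids) <= 0):
            raise ValueError("midpoints must be strictly increasing")
        edges = self.edges
        if edges[0][0] < -1e-12:
            raise ValueError("lowest bin edge is negative")
        for (lo1, hi1), (lo2, _) in zip(edges, edges[1:]):
            if lo2 < hi1 - 1e-12:
                raise ValueError("bins overlap")
        if self.bin_width_hz <= 0:
            raise ValueError("bin_width_hz must be positive")

    @property
    def n_bands(self) -> int:
        return len(self.midpoints_hz)

    @property
    def edges(self) -> list[tuple[float, float]]:
        w = self.bin_width_hz / 2.0
        return [(m - w, m + w) for m in self.midpoints_hz]

    @property
    def highest_edge_hz(self) -> float:
        return self.midpoints_hz[-1] + self.bin_width_hz / 2.0


def periodogram_power(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of linearly detrended series (last axis = time).

    Returns ``(freq_fraction, power)`` where ``freq_fraction`` is the DFT
    frequency in cycles/sample and ``power[k] = c_k |X_k|^2 / T`` with
    ``c_k = 2`` except at DC and (for even T) Nyquist.  With this scaling the
    powers sum to ``sum(x_detrended**2)`` (Parseval), i.e. detrended variance
    times T.
    """
    x = np.asarray(series, dtype=np.float64)
    T = x.shape[-1]
    x = signal.detrend(x, axis=-1, type="linear")
    X = np.fft.rfft(x, axis=-1)
    power = (X.real ** 2 + X.imag ** 2) / T
    scale = np.full(power.shape[-1], 2.0)
    scale[0] = 1.0
    if T % 2 == 0:
        scale[-1] = 1.0
    power = power * scale
    freq = np.fft.rfftfreq(T)  # cycles per sample
    return freq, power


def _bin_ordinates(freq_hz: np.ndarray, schema: BandSchema, nyquist: float,
                   allow_partial: bool) -> list[np.ndarray]:
    """Index arrays of DFT ordinates per bin; 0 Hz is always excluded."""
    sels = []
    for lo, hi in schema.edges:
        sel = np.nonzero((freq_hz >= lo) & (freq_hz < hi) & (freq_hz > 0))[0]
        if sel.size == 0 and lo < nyquist:
            raise ValueError(
                f"no DFT ordinate falls in bin [{lo:.3f}, {hi:.3f}) Hz; "
                "the series is too short for this schema")
        sels.append(sel)
    return sels


def band_powers(series, tr_seconds: float, schema: BandSchema | None = None,
                allow_partial: bool = False, average: bool = False) -> np.ndarray:
    """Band powers of one series (or a stack of series on the last axis).

    Parameters
    ----------
    series
        Length-T sequence, or array whose last axis is time (T >= 16).
    tr_seconds
        Sampling interval; the Nyquist frequency 1/(2*tr) must reach the
        schema's highest bin edge unless ``allow_partial`` is set, in which
        case bins lying fully above Nyquist are returned as 0.
    average
        If True, return the mean periodogram ordinate per bin instead of the
        sum (a per-bin monotone rescaling; the sum is the default).

    Returns
    -------
    ndarray with shape ``series.shape[:-1] + (n_bands,)`` of nonnegative powers.
    """
    schema = schema or BandSchema()
    x = np.asarray(series, dtype=np.float64)
    T = x.shape[-1]
    if T < 16:
        raise ValueError(f"need at least 16 time points, got {T}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if nyquist < schema.highest_edge_hz - 1e-12 and not allow_partial:
        raise ValueError(
            f"Nyquist frequency {nyquist:.3f} Hz is below the highest bin edge "
            f"{schema.highest_edge_hz:.3f} Hz; the sampling rate is inadequate "
            "(pass allow_partial=True to zero-fill the unreachable bins)")
    freq_frac, power = periodogram_power(x)
    freq_hz = freq_frac / tr_seconds
    sels = _bin_ordinates(freq_hz, schema, nyquist, allow_partial)
    out = np.zeros(x.shape[:-1] + (schema.n_bands,))
    for k, sel in enumerate(sels):
        if sel.size:
            bp = power[..., sel].sum(axis=-1)
            out[..., k] = bp / sel.size if average else bp
    return out


@dataclass
class FeatureMatrix:
    """Per-voxel feature rows keyed back to voxel coordinates.

    ``rows`` has 57 columns: 8 centre-voxel band powers, then the 6
    face-adjacent neighbours' 8-vectors in the fixed order x-, x+, y-, y+,
    z-, z+, then the occupancy fraction.  ``voxel_index`` maps each row to
    its (x, y, z) voxel.
    """

    rows: np.ndarray
    voxel_index: np.ndarray  # (n, 3) int
    mode: str
    schema: BandSchema
    grid_shape: tuple[int, int, int]
    subject_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("original", "pva_corrected"):
            raise ValueError(f"mode must be 'original' or 'pva_corrected', got {self.mode!r}")
        n_spec = 7 * self.schema.n_bands
        if self.rows.shape[1] != n_spec + 1:
            raise ValueError(
                f"expected {n_spec + 1} feature columns, got {self.rows.shape[1]}")
        if np.any(self.rows[:, :n_spec] < 0):
            raise ValueError("spectral features must be nonnegative")
        occ = self.rows[:, -1]
        if np.any((occ < 0) | (occ > 1)):
            raise ValueError("occupancy column must lie in [0, 1]")
        if self.mode == "original" and np.any(occ != 0):
            raise ValueError("original mode requires a zeroed occupancy column")

    @property
    def n_voxels(self) -> int:
        return self.rows.shape[0]

    def as_original(self) -> "FeatureMatrix":
        """The same matrix with the occupancy column zeroed (original mode).

        The uncorrected predictor keeps the 57th column and sets it to 0 for
        every voxel, so the two modes differ only in that column.
        """
        rows = self.rows.copy()
        rows[:, -1] = 0.0
        return FeatureMatrix(rows, self.voxel_index, "original", self.schema,
                             self.grid_shape, subject_id=self.subject_id,
                             meta=dict(self.meta))

    @property
    def n_features(self) -> int:
        return self.rows.shape[1]

    def values_to_volume(self, values: np.ndarray, template: Volume3D,
                         background: float = 0.0) -> Volume3D:
        """Scatter one value per row back into a 3D map on this grid."""
        out = np.full(self.grid_shape, background, dtype=np.float64)
        ix = self.voxel_index
        out[ix[:, 0], ix[:, 1], ix[:, 2]] = values
        return template.with_data(out)


def extract_features(bold: Volume4D, mask: Volume3D, occupancy: Volume3D,
                     mode: str = "pva_corrected", schema: BandSchema | None = None,
                     neighbor_policy: str = "replicate", allow_partial: bool = False,
                     subject_id: str | None = None) -> FeatureMatrix:
    """Build the 57-column feature matrix for all in-mask voxels.

    Neighbours outside the mask (or the grid) follow ``neighbor_policy``:
    ``"replicate"`` copies the centre voxel's band powers (default, avoids a
    spurious power deficit at mask borders), ``"zero"`` fills zeros.
    """
    schema = schema or BandSchema()
    check_aligned(bold, mask, occupancy)
    if neighbor_policy not in ("replicate", "zero"):
        raise ValueError(f"unknown neighbor_policy {neighbor_policy!r}")
    mask_arr = mask.data.astype(bool)
    if not mask_arr.any():
        raise ValueError("mask is empty")
    occ = occupancy.data
    if np.any((occ < -1e-9) | (occ > 1 + 1e-9)):
        raise ValueError("occupancy values must lie in [0, 1]")
    occ = np.clip(occ, 0.0, 1.0)

    coords = np.argwhere(mask_arr)
    series = bold.data[mask_arr]  # (n, T)
    if not np.all(np.isfinite(series)):
        raise ValueError("in-mask voxel time series contain non-finite values")
    bp = band_powers(series, bold.tr_seconds, schema, allow_partial=allow_partial)

    # row lookup per voxel for neighbour gathering
    row_of = np.full(mask_arr.shape, -1, dtype=np.int64)
    row_of[mask_arr] = np.arange(coords.shape[0])

    n, B = bp.shape
    rows = np.empty((n, 7 * B + 1))
    rows[:, :B] = bp
    shape = mask_arr.shape
    for j, off in enumerate(NEIGHBOR_OFFSETS):
        nbr = coords + np.asarray(off)
        inside = np.all((nbr >= 0) & (nbr < np.asarray(shape)), axis=1)
        nbr_rows = np.full(n, -1, dtype=np.int64)
        nbr_rows[inside] = row_of[nbr[inside, 0], nbr[inside, 1], nbr[inside, 2]]
        valid = nbr_rows >= 0
        block = np.empty((n, B))
        block[valid] = bp[nbr_rows[valid]]
        if neighbor_policy == "replicate":
            block[~valid] = bp[~valid]
        else:
            block[~valid] = 0.0
        rows[:, (1 + j) * B:(2 + j) * B] = block

    rows[:, -1] = 0.0 if mode == "original" else occ[mask_arr]
    nyquist = 1.0 / (2.0 * bold.tr_seconds)
    zeroed = [k for k, (lo, _) in enumerate(schema.edges) if lo >= nyquist]
    meta = {"neighbor_policy": neighbor_policy, "estimator": "periodogram",
            "tr_seconds": bold.tr_seconds}
    if zeroed:
        meta["bands_above_nyquist"] = zeroed
    return FeatureMatrix(rows, coords, mode, schema, shape,
                         subject_id=subject_id, meta=meta)


def prepare_occupancy(occ_native: Volume3D, fwhm_mm: float = 5.0,
                      target_mm: float = 2.0) -> Volume3D:
    """Smooth a native-resolution GM occupancy map and resample it.

    The map is clipped to [0, 1], smoothed with a Gaussian of the given FWHM
    (sigma = FWHM / 2.3548 mm, converted to voxels per axis, reflective
    boundaries), then resampled to ``target_mm`` isotropic resolution —
    block-averaged when the target is an integer multiple of every axis's
    voxel size, linearly interpolated otherwise.  The output is clipped to
    [0, 1] again.
    """
    data = np.asarray(occ_native.data, dtype=np.float64)
    if np.any(data < -1e-3) or np.any(data > 1 + 1e-3):
        raise ValueError("occupancy values must lie in [0, 1] (up to rounding)")
    data = np.clip(data, 0.0, 1.0)
    vox = np.asarray(occ_native.voxel_size_mm, dtype=float)
    sigma_vox = (fwhm_mm / _FWHM_TO_SIGMA) / vox
    smoothed = ndimage.gaussian_filter(data, sigma=sigma_vox, mode="reflect")

    factors = target_mm / vox
    extent = np.asarray(data.shape) * vox
    if np.any(target_mm > extent):
        raise ValueError("target resolution is coarser than the grid extent")

    int_factors = np.round(factors).astype(int)
    if np.allclose(factors, int_factors) and np.all(int_factors >= 1):
        f = int_factors
        trimmed = smoothed[: data.shape[0] // f[0] * f[0],
                           : data.shape[1] // f[1] * f[1],
                           : data.shape[2] // f[2] * f[2]]
        out = trimmed.reshape(trimmed.shape[0] // f[0], f[0],
                              trimmed.shape[1] // f[1], f[1],
                              trimmed.shape[2] // f[2], f[2]).mean(axis=(1, 3, 5))
    else:
        out = ndimage.zoom(smoothed, 1.0 / factors, order=1, mode="nearest")
    out = np.clip(out, 0.0, 1.0)

    aff = occ_native.affine.copy()
    aff[:3, :3] = aff[:3, :3] @ np.diag(factors)
    return Volume3D(out, (target_mm, target_mm, target_mm), aff)
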
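"""Synthetic phantoms and cohorts with the structure the method assumes.

The generator builds a cortical-ribbon phantom (an ellipsoidal shell whose
GM occupancy peaks mid-ribbon and decays to zero at its edges, carved into
bilateral parcels), then simulates subjects under an explicit forward model:

* a smooth latent band-power field per voxel, linearly coupled to the
  voxel's true gray-matter CBF (``true_gm_cbf = a0 + a . powers``, exactly);
* a BOLD-like time series per voxel synthesized as a sum of band-limited
  noise components carrying those powers, plus a broadband floor;
* partial-volume mixing of the measurement:
  ``measured_cbf = occupancy * true_gm_cbf + (1 - occupancy) * wm_cbf + noise``,
  which is the artifact the PVA-corrected predictor exists to undo — thinner
  cortex (lower occupancy) drags measured CBF toward the white-matter value
  while true GM CBF is unchanged;
* between-subject variation in regional CBF and in regional "thickness"
  (an occupancy multiplier), and an optional case-control effect map in
  Cohen's d units applied to the case group's regional CBF.

All randomness flows from per-subject seeds derived from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .spectral import BandSchema
from .volumes import LabelAtlas, Volume3D, Volume4D

__all__ = [
    "PhantomSpec",
    "Phantom",
    "GenerativeParams",
    "SyntheticSubject",
    "make_phantom",
    "simulate_subject",
    "simulate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the ribbon phantom."""

    shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    ribbon_thickness_voxels: float = 2.0
    n_parcels: int = 8  # bilateral pairs
    occupancy_peak: float = 0.95
    mask_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.shape) < 2 * self.ribbon_thickness_voxels + 2:
            raise ValueError("grid too small for the requested ribbon thickness")
        if self.n_parcels < 1:
            raise ValueError("need at least one parcel")


@dataclass
class Phantom:
    mask: Volume3D       # boolean analysis mask (occupancy above threshold)
    occupancy: Volume3D  # GM fraction in [0, 1]
    atlas: LabelAtlas    # bilateral parcels partitioning the ribbon
    spec: PhantomSpec


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Ellipsoidal-shell ribbon with bilateral angular parcels.

    Occupancy is a Gaussian bump of the (approximate) radial distance to the
    shell mid-surface, peaking at ``occupancy_peak`` mid-ribbon.  Parcels
    split each hemisphere (x below/above centre) into equal angular sectors
    around the x-axis; every voxel with non-negligible occupancy is labelled,
    and the analysis mask is ``occupancy > mask_threshold``.
    """
    spec = spec or PhantomSpec()
    shape = np.asarray(spec.shape)
    center = (shape - 1) / 2.0
    semi_axes = 0.40 * shape  # voxels
    xi, yi, zi = np.meshgrid(*[np.arange(s) for s in spec.shape], indexing="ij")
    rel = np.stack([(xi - center[0]) / semi_axes[0],
                    (yi - center[1]) / semi_axes[1],
                    (zi - center[2]) / semi_axes[2]])
    u = np.sqrt((rel ** 2).sum(axis=0))
    radial_voxels = (u - 1.0) * float(np.mean(semi_axes))
    half_thickness = spec.ribbon_thickness_voxels / 2.0
    occ = spec.occupancy_peak * np.exp(-0.5 * (radial_voxels / half_thickness) ** 2)

    mask = occ > spec.mask_threshold
    if not mask.any():
        raise ValueError("phantom ribbon is empty; check the spec")

    # bilateral angular parcellation of everything with visible occupancy
    labelled_zone = occ > 0.01
    phi = np.arctan2(zi - center[2], yi - center[1])  # angle around the x-axis
    sector = np.clip(((phi + np.pi) / (2 * np.pi) * spec.n_parcels).astype(int),
                     0, spec.n_parcels - 1)
    left = xi < center[0]
    labels = np.zeros(spec.shape, dtype=np.int64)
    labels[labelled_zone] = (2 * sector[labelled_zone] + 1
                             + (~left[labelled_zone]).astype(int))
    lut = {}
    for k in range(spec.n_parcels):
        name = f"parcel_{k + 1:02d}"
        lut[2 * k + 1] = (name, "L")
        lut[2 * k + 2] = (name, "R")

    occ_vol = Volume3D.from_array(occ, spec.voxel_size_mm)
    mask_vol = occ_vol.with_data(mask.astype(np.uint8))
    atlas = LabelAtlas(labels, lut, occ_vol.voxel_size_mm, occ_vol.affine,
                       occ_vol.space_id)
    return Phantom(mask_vol, occ_vol, atlas, spec)


@dataclass(frozen=True)
class GenerativeParams:
    """Forward-model parameters coupling band powers, CBF, and measurement.

    ``band_weights`` is the linear link a from the 8 latent band powers to
    GM CBF; ``wm_cbf`` (mL/100g/min) is the white-matter flow mixed in by
    partial-volume averaging; ``noise_sd_frac`` scales the measurement noise
    to the spatial SD of true GM CBF (default 20%); ``effect_map`` holds the
    case-vs-control shift per region in Cohen's d units (negative = case
    hypoperfusion), applied on the between-subject regional SD.
    """

    band_weights: tuple[float, ...] = (1.0, 0.85, 0.7, 0.55, 0.45, 0.35, 0.25, 0.15)
    intercept: float = 0.0          # a0, mL/100g/min
    gm_cbf_mean: float = 60.0       # population mean cortical CBF
    regional_pattern_sd: float = 6.0   # fixed across subjects
    between_subject_sd: float = 5.0    # per-region subject fluctuation
    voxel_sd: float = 4.0              # smooth within-region variation
    band_jitter_sd: float = 0.10       # log-scale per-band field jitter
    broadband_frac: float = 0.05       # broadband floor power / band power
    wm_cbf: float = 20.0
    noise_sd_frac: float = 0.20
    thickness_subject_sd: float = 0.10  # per-region occupancy multiplier SD
    effect_map: dict = field(default_factory=dict)
    tr_seconds: float = 0.8
    n_timepoints: int = 240
    smooth_voxels: float = 3.0
    pattern_seed: int = 1234  # fixed regional base pattern, shared by subjects
    schema: BandSchema = field(default_factory=BandSchema)

    def __post_init__(self):
        if len(self.band_weights) != self.schema.n_bands:
            raise ValueError("band_weights length must match the schema")
        if any(w <= 0 for w in self.band_weights):
            raise ValueError("band_weights must be positive")
        if self.noise_sd_frac < 0 or self.thickness_subject_sd < 0:
            raise ValueError("noise/thickness SDs must be nonnegative")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    seed: int
    bold: Volume4D | None
    occupancy: Volume3D
    true_gm_cbf: Volume3D
    measured_cbf: Volume3D
    latent_band_powers: np.ndarray  # shape + (8,)


def _smooth_field(rng, shape, sigma, sd):
    """Zero-mean Gaussian random field with unit-calibrated SD after smoothing."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="reflect")
    s = f.std()
    return f * (sd / s) if s > 0 else f


def _region_name_grid(atlas: LabelAtlas) -> np.ndarray:
    """Map each voxel to a bilateral region index (-1 outside parcels)."""
    names = atlas.region_names
    idx_of = {n: i for i, n in enumerate(names)}
    out = np.full(atlas.labels.shape, -1, dtype=np.int64)
    for lab, (name, _) in atlas.lut.items():
        out[atlas.labels == lab] = idx_of[name]
    return out


def _regional_scalar_field(atlas: LabelAtlas, values: np.ndarray,
                           fill: float) -> np.ndarray:
    region_idx = _region_name_grid(atlas)
    out = np.full(atlas.labels.shape, fill, dtype=np.float64)
    inside = region_idx >= 0
    out[inside] = values[region_idx[inside]]
    return out


def _base_regional_pattern(phantom: Phantom, params: GenerativeParams) -> np.ndarray:
    """Fixed per-region CBF offsets shared by every subject of a study."""
    rng = np.random.default_rng(params.pattern_seed)
    n = len(phantom.atlas.region_names)
    return params.regional_pattern_sd * rng.standard_normal(n)


# cache of per-(phantom, params) effect calibrations; keyed on geometry + the
# generative scales that determine between-subject regional variance
_CALIBRATION_CACHE: dict = {}


def _calibration_key(phantom: Phantom, params: GenerativeParams):
    return (id(phantom),
            params.gm_cbf_mean, params.regional_pattern_sd,
            params.between_subject_sd, params.voxel_sd, params.band_jitter_sd,
            params.wm_cbf, params.noise_sd_frac, params.thickness_subject_sd,
            params.pattern_seed, params.band_weights, params.intercept)


def effect_calibration(phantom: Phantom, params: GenerativeParams,
                       n_subjects: int = 300) -> tuple[np.ndarray, np.ndarray]:
    """Per-region (SD of measured regional CBF, mean occupancy) across subjects.

    Injected effect sizes are defined on the measurement scale: a case shift
    of d in region r moves the regional mean of *measured* CBF by
    d x SD_r, where SD_r is the between-subject SD of that regional mean in
    the control population.  That SD mixes several generative components
    (regional CBF fluctuation, thickness variation, field noise), so it is
    estimated once by simulating ``n_subjects`` effect-free control subjects
    with a fixed internal seed derived from ``pattern_seed``; the result is
    cached per (phantom, parameter) combination.
    """
    key = _calibration_key(phantom, params)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    clean = replace(params, effect_map={})
    seq = np.random.SeedSequence([params.pattern_seed, 0xCA11B])
    seeds = seq.generate_state(n_subjects) % (2 ** 31)
    names = phantom.atlas.region_names
    mask = phantom.mask.data.astype(bool)
    region_idx = _region_name_grid(phantom.atlas)
    means = np.empty((n_subjects, len(names)))
    occ_sum = np.zeros(len(names))
    for i, s in enumerate(seeds):
        subj = simulate_subject(phantom, clean, group="control", seed=int(s),
                                with_bold=False)
        for j in range(len(names)):
            sel = (region_idx == j) & mask
            means[i, j] = subj.measured_cbf.data[sel].mean()
            occ_sum[j] += subj.occupancy.data[sel].mean()
    result = (means.std(axis=0, ddof=1), occ_sum / n_subjects)
    _CALIBRATION_CACHE[key] = result
    return result


def _synthesize_bold(rng, latent_powers: np.ndarray, params: GenerativeParams
                     ) -> np.ndarray:
    """Time series whose periodogram band powers match the latent powers.

    Each band is filled with complex Gaussian rFFT coefficients restricted to
    the band's frequency range (clipped at Nyquist) and rescaled so the
    one-sided periodogram power in the band equals the latent target; a
    broadband floor of relative power ``broadband_frac`` is added on top.
    """
    shape = latent_powers.shape[:-1]
    n_vox = int(np.prod(shape))
    p = latent_powers.reshape(n_vox, -1)
    T = params.n_timepoints
    tr = params.tr_seconds
    freqs = np.fft.rfftfreq(T, d=tr)
    nyquist = freqs[-1]
    n_freq = freqs.size

    Z = np.zeros((n_vox, n_freq), dtype=np.complex128)
    # one-sided periodogram weight per ordinate (matches spectral.periodogram_power)
    w = np.full(n_freq, 2.0)
    w[0] = 1.0
    if T % 2 == 0:
        w[-1] = 1.0

    for k, (lo, hi) in enumerate(params.schema.edges):
        sel = np.nonzero((freqs >= lo) & (freqs < hi) & (freqs > 0))[0]
        if sel.size == 0:
            if lo < nyquist:
                raise ValueError("time series too short for the band schema")
            continue  # band entirely above Nyquist: unrepresentable, skip
        coef = rng.standard_normal((n_vox, sel.size)) \
            + 1j * rng.standard_normal((n_vox, sel.size))
        current = (w[sel] * np.abs(coef) ** 2).sum(axis=1) / T
        coef *= np.sqrt(p[:, k] / current)[:, None]
        Z[:, sel] = coef

    # broadband floor across all positive frequencies
    sel = np.arange(1, n_freq)
    floor = rng.standard_normal((n_vox, sel.size)) \
        + 1j * rng.standard_normal((n_vox, sel.size))
    current = (w[sel] * np.abs(floor) ** 2).sum(axis=1) / T
    target = params.broadband_frac * p.sum(axis=1)
    floor *= np.sqrt(target / current)[:, None]
    Z[:, sel] += floor

    series = np.fft.irfft(Z, n=T, axis=1)
    return series.reshape(shape + (T,))


def simulate_subject(phantom: Phantom, params: GenerativeParams,
                     group: str = "control", seed: int = 0,
                     subject_id: str = "sub-0001",
                     occupancy_scale: float = 1.0,
                     with_bold: bool = True,
                     calibration: tuple[np.ndarray, np.ndarray] | None = None
                     ) -> SyntheticSubject:
    """Draw one subject from the forward model.

    ``occupancy_scale`` uniformly thins (or thickens) the subject's cortex;
    ``with_bold=False`` skips time-series synthesis for analyses that only
    need the CBF maps.  At ``noise_sd_frac = 0`` the measured map satisfies
    the mixing identity exactly.
    """
    if group not in ("case", "control"):
        raise ValueError("group must be 'case' or 'control'")
    nyq = 1.0 / (2.0 * params.tr_seconds)
    if params.schema.edges[0][1] > nyq:
        raise ValueError("TR too long: the lowest band lies above Nyquist")
    rng = np.random.default_rng(seed)
    atlas = phantom.atlas
    shape = atlas.labels.shape
    names = atlas.region_names
    n_regions = len(names)

    # regional CBF targets: fixed pattern + subject fluctuation + group effect
    base = _base_regional_pattern(phantom, params)
    u = params.between_subject_sd * rng.standard_normal(n_regions)
    if group == "case" and params.effect_map:
        if calibration is None:
            calibration = effect_calibration(phantom, params)
        sigma_r, occbar_r = calibration
        shift = np.array([params.effect_map.get(n, 0.0) for n in names])
        # shift true GM CBF so the *measured* regional mean moves by d * SD_r
        u += shift * sigma_r / np.maximum(occbar_r, 1e-6)
    regional_cbf = params.gm_cbf_mean + base + u
    cbf = _regional_scalar_field(atlas, regional_cbf, fill=params.gm_cbf_mean)
    cbf = cbf + _smooth_field(rng, shape, params.smooth_voxels, params.voxel_sd)

    # latent band powers: positive profile scaled so a . p reproduces the CBF
    a = np.asarray(params.band_weights)
    profile = a / (a @ a)          # a . profile == 1
    g = cbf - params.intercept
    if np.mean(g <= 0) > 0.01:
        raise ValueError("parameters drive >1% of voxels to non-positive CBF")
    g = np.maximum(g, 1e-3)
    jitter = np.stack([
        _smooth_field(rng, shape, params.smooth_voxels, params.band_jitter_sd)
        for _ in range(len(a))], axis=-1)
    powers = profile[None, None, None, :] * g[..., None] * np.exp(jitter)
    true_gm = params.intercept + np.tensordot(powers, a, axes=([-1], [0]))

    # subject occupancy: base ribbon modulated by regional thickness factors
    t_r = 1.0 + params.thickness_subject_sd * rng.standard_normal(n_regions)
    t_field = _regional_scalar_field(atlas, t_r, fill=1.0)
    occ = np.clip(phantom.occupancy.data * t_field * occupancy_scale, 0.0, 1.0)

    mask = phantom.mask.data.astype(bool)
    noise_sd = params.noise_sd_frac * float(true_gm[mask].std())
    noise = noise_sd * rng.standard_normal(shape) if noise_sd > 0 else 0.0
    measured = occ * true_gm + (1.0 - occ) * params.wm_cbf + noise

    bold = None
    if with_bold:
        series = _synthesize_bold(rng, powers, params)
        bold = Volume4D(series, phantom.occupancy.voxel_size_mm,
                        params.tr_seconds, phantom.occupancy.affine,
                        phantom.occupancy.space_id)
    geom = phantom.occupancy
    return SyntheticSubject(
        subject_id=subject_id, group=group, seed=seed, bold=bold,
        occupancy=geom.with_data(occ),
        true_gm_cbf=geom.with_data(true_gm),
        measured_cbf=geom.with_data(measured),
        latent_band_powers=powers,
    )


def simulate_cohort(n_case: int, n_control: int,
                    phantom: Phantom | None = None,
                    params: GenerativeParams | None = None,
                    seed: int = 0, with_bold: bool = True,
                    age_mean: float = 50.0, age_sd: float = 15.0
                    ) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Independent subjects with per-subject seeds plus a demographic manifest.

    Ages are drawn from a clipped normal and sexes as a fair coin for both
    groups, so train/test balancing has something to balance.  Returns the
    subject list and a manifest DataFrame (subject_id, age, sex, group, seed).
    """
    if n_case < 0 or n_control < 2 or (n_case == 1):
        raise ValueError("need n_control >= 2 and n_case == 0 or >= 2")
    phantom = phantom or make_phantom()
    params = params or GenerativeParams()
    master = np.random.default_rng(seed)
    n = n_case + n_control
    sub_seeds = master.integers(0, 2 ** 31 - 1, size=n)
    ages = np.clip(master.normal(age_mean, age_sd, size=n), 20.0, 85.0)
    sexes = np.where(master.random(n) < 0.5, "M", "F")
    groups = ["case"] * n_case + ["control"] * n_control

    calibration = None
    if n_case and params.effect_map:
        calibration = effect_calibration(phantom, params)

    subjects, rows = [], []
    for i in range(n):
        sid = f"sub-{i + 1:04d}"
        subj = simulate_subject(phantom, params, group=groups[i],
                                seed=int(sub_seeds[i]), subject_id=sid,
                                with_bold=with_bold, calibration=calibration)
        subjects.append(subj)
        rows.append((sid, float(ages[i]), sexes[i], groups[i], int(sub_seeds[i])))
    manifest = pd.DataFrame(rows, columns=["subject_id", "age", "sex", "group", "seed"])
    return subjects, manifest
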
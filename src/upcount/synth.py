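"""Synthetic ground-truthed inputs: point patterns, microscopy images, transients.

Emulates the three experimental observables of the transport-efficiency
method so every downstream stage can be validated against a known truth:

* a near-random spatial pattern of ~70-80 nm upconversion nanoparticles in
  a thin gel layer (~7000 per mm², optionally overdispersed);
* background-free upconversion-microscopy images of those particles
  (Gaussian spots with shot noise on an essentially zero background);
* single-particle ICP-MS transients produced by raster laser ablation of
  the layer, under three regimes: 2940 nm (soft, near-quantitative
  desorption of intact particles), 213 nm (partial desorption, residual and
  redeposited material recoverable by a second ablation pass) and 193 nm
  (particle disintegration: countable peaks lost to an elevated baseline).

Every generator takes an explicit seed and is bit-reproducible.  The event
log records the fate of each particle (desorbed / decayed / residual /
not_swept) so that counting, coincidence correction and the transport
efficiency estimator can be checked against exact ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .raster import RasterPlan, pulse_pitch
from .transient import TransientSignal

__all__ = [
    "GroundTruthLayer",
    "RegimeConfig",
    "regime_config",
    "sample_point_pattern",
    "crop_layer",
    "render_ucm_image",
    "simulate_transient",
    "simulate_reablation",
    "write_image",
    "write_event_log",
]


@dataclass(frozen=True)
class GroundTruthLayer:
    """Known particle positions in a rectangular gel area.

    ``x_um``/``y_um`` are particle coordinates (origin top-left), and
    ``mass_scale`` a dimensionless per-particle brightness/mass factor
    (narrowly distributed around 1 for a monodisperse batch).
    """

    x_um: np.ndarray
    y_um: np.ndarray
    mass_scale: np.ndarray
    area_width: float
    area_height: float
    density: float
    overdispersion: float = 1.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x_um, dtype=float)
        y = np.asarray(self.y_um, dtype=float)
        m = np.asarray(self.mass_scale, dtype=float)
        if not (x.shape == y.shape == m.shape):
            raise ValueError("x_um, y_um, mass_scale must have equal shapes")
        if x.size and (np.any(m <= 0)):
            raise ValueError("mass_scale must be positive")
        if x.size and (x.min() < 0 or y.min() < 0 or
                       x.max() > self.area_width or y.max() > self.area_height):
            raise ValueError("particles must lie within the layer area")
        object.__setattr__(self, "x_um", x)
        object.__setattr__(self, "y_um", y)
        object.__setattr__(self, "mass_scale", m)

    @property
    def count(self) -> int:
        return int(self.x_um.size)

    @property
    def area_mm2(self) -> float:
        return self.area_width * self.area_height * 1e-6


@dataclass(frozen=True)
class RegimeConfig:
    """Stochastic particle-fate model for one laser regime.

    desorption_prob
        Probability a swept, non-decayed particle is desorbed intact and
        produces a countable peak.
    redeposition_prob
        Probability a non-desorbed particle is displaced (redeposited) by
        up to one pulse pitch rather than left in place.
    decay_prob
        Probability a swept particle disintegrates; its signal is smeared
        into a local baseline elevation instead of a countable peak.
    baseline_mean
        Mean ion background in counts per dwell.
    peak_width_range_us
        Single-particle peak duration range (uniform draw).
    peak_area_mode / peak_area_sigma
        Log-normal peak-area distribution, parametrised by its mode in
        counts and log-space sigma.
    washout_tail_ms
        Mean exponential delay between ablation and detection (aerosol
        washout from the cell).
    stage_jitter_um
        Half-width of the uniform XY-stage positioning error.
    decay_spread_ms
        Gaussian sigma of the baseline smear left by a decayed particle.
    """

    regime: str
    desorption_prob: float
    redeposition_prob: float
    decay_prob: float
    baseline_mean: float
    peak_width_range_us: tuple[float, float] = (200.0, 500.0)
    peak_area_mode: float = 220.0
    peak_area_sigma: float = 0.25
    washout_tail_ms: float = 10.0
    stage_jitter_um: float = 2.5
    decay_spread_ms: float = 2.5
    # Fraction of a decayed particle's ion yield that reaches the detector
    # as smeared background; the rest is lost to sub-detection-limit
    # fragments and surface evaporation.
    decay_signal_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("desorption_prob", "redeposition_prob", "decay_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.peak_width_range_us
        if not (0 < lo <= hi):
            raise ValueError("peak_width_range_us must be positive and ordered")
        if self.baseline_mean < 0:
            raise ValueError("baseline_mean must be non-negative")


_REGIME_DEFAULTS = {
    # 2940 nm IR: laser energy absorbed by the gel, intact particles softly
    # desorbed; reablation recovers <1% of the first pass.
    "ir_2940": dict(desorption_prob=1.0, redeposition_prob=0.0, decay_prob=0.0,
                    baseline_mean=0.05),
    # 213 nm at low fluence: incomplete desorption plus redeposition leave
    # ~6% of particles for the second pass; rare (<5%) decay.
    "uv_213": dict(desorption_prob=0.94, redeposition_prob=0.5, decay_prob=0.03,
                   baseline_mean=0.05),
    # 193 nm: strong absorption by the particles themselves; most
    # disintegrate, leaving <~45% countable.  The instrument background is
    # the same as for the other lasers; the elevated transient baseline
    # emerges from the smeared debris of decayed particles.
    "uv_193": dict(desorption_prob=0.95, redeposition_prob=0.2, decay_prob=0.55,
                   baseline_mean=0.05),
}


def regime_config(name: str, **overrides) -> RegimeConfig:
    """Default fate model for ``ir_2940``, ``uv_213`` or ``uv_193``."""
    if name not in _REGIME_DEFAULTS:
        raise ValueError(f"unknown regime {name!r}; choose from {sorted(_REGIME_DEFAULTS)}")
    params = dict(_REGIME_DEFAULTS[name])
    params.update(overrides)
    return RegimeConfig(regime=name, **params)


# -- point pattern ------------------------------------------------------------

def sample_point_pattern(density: float, area_um: tuple[float, float],
                         overdispersion: float = 1.0, seed: int = 0,
                         cluster_sigma_um: float = 20.0,
                         mass_sigma: float = 0.1) -> GroundTruthLayer:
    """Sample a particle layer at a given density (particles per mm²).

    ``overdispersion`` = 1 gives a homogeneous Poisson process (count RSD of
    repeated draws = 100/sqrt(N)); values above 1 give a Neyman-Scott
    parent-offspring process whose count variance/mean ratio is roughly the
    requested overdispersion (offspring are Poisson with mean
    ``overdispersion - 1`` per parent, scattered by ``cluster_sigma_um``).
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if overdispersion < 1.0:
        raise ValueError("overdispersion must be >= 1")
    w, h = area_um
    rng = np.random.default_rng(seed)
    area_mm2 = w * h * 1e-6
    mean_count = density * area_mm2
    if area_mm2 <= 0 or mean_count == 0:
        empty = np.empty(0)
        return GroundTruthLayer(empty, empty.copy(), empty.copy(), w, h,
                                density, overdispersion)
    if overdispersion == 1.0:
        n = rng.poisson(mean_count)
        x = rng.uniform(0, w, n)
        y = rng.uniform(0, h, n)
    else:
        m = overdispersion - 1.0  # offspring mean -> var/mean = 1 + m
        n_parents = rng.poisson(mean_count / m)
        kids = rng.poisson(m, n_parents)
        px = rng.uniform(0, w, n_parents)
        py = rng.uniform(0, h, n_parents)
        x = np.repeat(px, kids) + rng.normal(0, cluster_sigma_um, kids.sum())
        y = np.repeat(py, kids) + rng.normal(0, cluster_sigma_um, kids.sum())
        # wrap offspring into the area to preserve counts and density
        x = np.mod(x, w)
        y = np.mod(y, h)
    mass = rng.lognormal(mean=-0.5 * mass_sigma ** 2, sigma=mass_sigma, size=x.size)
    return GroundTruthLayer(x, y, mass, w, h, density, overdispersion)


def crop_layer(layer: GroundTruthLayer, x0: float, y0: float,
               width: float, height: float) -> GroundTruthLayer:
    """Extract the particles inside an axis-aligned sub-rectangle, re-origined
    to the crop's top-left corner."""
    sel = ((layer.x_um >= x0) & (layer.x_um < x0 + width) &
           (layer.y_um >= y0) & (layer.y_um < y0 + height))
    return GroundTruthLayer(layer.x_um[sel] - x0, layer.y_um[sel] - y0,
                            layer.mass_scale[sel], width, height,
                            layer.density, layer.overdispersion)


# -- microscopy image ---------------------------------------------------------

def render_ucm_image(layer: GroundTruthLayer, pixel_size_um: float = 0.5,
                     psf_sigma_um: float = 0.4, photon_scale: float = 2000.0,
                     background: float = 0.0, seed: int = 0) -> np.ndarray:
    """Render an upconversion-microscopy image of a layer.

    Each particle becomes a Gaussian PSF carrying ``photon_scale *
    mass_scale`` photons; pixel values are Poisson draws around PSF +
    ``background`` (upconversion imaging is essentially background-free, so
    the default background is zero).  Returns a float array of counts with
    shape covering the layer area.
    """
    if pixel_size_um <= 0 or psf_sigma_um <= 0:
        raise ValueError("pixel_size_um and psf_sigma_um must be positive")
    rng = np.random.default_rng(seed)
    ny = max(1, int(np.ceil(layer.area_height / pixel_size_um)))
    nx = max(1, int(np.ceil(layer.area_width / pixel_size_um)))
    img = np.zeros((ny, nx), dtype=float)
    sig_px = psf_sigma_um / pixel_size_um
    r = max(2, int(np.ceil(4 * sig_px)))
    win = np.arange(-r, r + 1)
    for x, y, m in zip(layer.x_um, layer.y_um, layer.mass_scale):
        cx = x / pixel_size_um - 0.5  # pixel-centre coordinates
        cy = y / pixel_size_um - 0.5
        ix, iy = int(round(cx)), int(round(cy))
        gx = np.exp(-0.5 * ((win + ix - cx) / sig_px) ** 2)
        gy = np.exp(-0.5 * ((win + iy - cy) / sig_px) ** 2)
        patch = np.outer(gy, gx)
        patch *= photon_scale * m / patch.sum()
        y0, y1 = max(0, iy - r), min(ny, iy + r + 1)
        x0, x1 = max(0, ix - r), min(nx, ix + r + 1)
        img[y0:y1, x0:x1] += patch[y0 - (iy - r): y1 - (iy - r),
                                   x0 - (ix - r): x1 - (ix - r)]
    return rng.poisson(img + background).astype(float)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an image as 16-bit grayscale TIFF (values clipped to uint16)."""
    tifffile.imwrite(str(path), np.clip(image, 0, 65535).astype(np.uint16))


# -- transient simulation -----------------------------------------------------

def _sweep_schedule(layer: GroundTruthLayer, plan: RasterPlan,
                    x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First time each particle is covered by the laser spot.

    Returns ``(sweep_time_s, swept)``.  Line j sits at origin_y + j*spacing;
    a particle is ablated by the first line whose spot (diameter d) reaches
    it, nominally when the spot centre crosses its x coordinate (the
    material removed by a top-hat spot is centred on the beam axis).
    """
    d2 = plan.spot_diameter / 2.0
    rel_y = y - plan.origin_y
    j = np.ceil((rel_y - d2) / plan.line_spacing).astype(int)
    j = np.maximum(j, 0)
    swept = (j < plan.n_lines) & (np.abs(rel_y - j * plan.line_spacing) <= d2)
    rel_x = x - plan.origin_x
    tx = np.clip(rel_x / plan.scan_speed, 0.0, plan.line_duration_s)
    swept &= (rel_x >= -d2) & (rel_x <= plan.area_width + d2)
    t = j * plan.line_period_s + tx
    return t, swept


def simulate_transient(layer: GroundTruthLayer, plan: RasterPlan,
                       regime: RegimeConfig, dwell_us: float = 100.0,
                       seed: int = 0,
                       ) -> tuple[TransientSignal, GroundTruthLayer, pd.DataFrame]:
    """Simulate the SP-ICP-MS transient of one laser pass over a layer.

    Every particle swept by the spot is assigned a fate: ``decayed`` with
    ``decay_prob`` (its area is smeared as a local baseline elevation),
    otherwise ``desorbed`` with ``desorption_prob`` (a peak of 200-500 μs is
    deposited at its sweep time plus an exponential washout delay), otherwise
    ``residual`` (left on the slide, possibly redeposited up to one pulse
    pitch away).  Unswept particles are residual too.  Coincidence is
    emergent: peaks landing in overlapping dwells simply add.

    Returns the transient, the residual layer for a reablation pass, and a
    per-particle event log (columns: x_um, y_um, fate, sweep_time_s,
    arrival_time_s, peak_area, peak_width_us).
    """
    rng = np.random.default_rng(seed)
    dwell_s = dwell_us * 1e-6
    tail_margin_s = 0.2 + 6 * regime.washout_tail_ms * 1e-3
    n_dwells = int(np.ceil((plan.total_duration_s + tail_margin_s) / dwell_s))
    signal = rng.poisson(regime.baseline_mean, n_dwells).astype(float)

    n = layer.count
    jx = rng.uniform(-regime.stage_jitter_um, regime.stage_jitter_um, n)
    jy = rng.uniform(-regime.stage_jitter_um, regime.stage_jitter_um, n)
    x_eff = layer.x_um + plan.origin_x + jx  # layer coords -> stage coords
    y_eff = layer.y_um + plan.origin_y + jy
    sweep_t, swept = _sweep_schedule(layer, plan, x_eff, y_eff)
    if n and not swept.any():
        warnings.warn("raster plan never sweeps the layer: all particles residual")

    u_decay = rng.uniform(size=n)
    u_des = rng.uniform(size=n)
    fate = np.full(n, "residual", dtype=object)
    fate[~swept] = "not_swept"
    decayed = swept & (u_decay < regime.decay_prob)
    desorbed = swept & ~decayed & (u_des < regime.desorption_prob)
    fate[decayed] = "decayed"
    fate[desorbed] = "desorbed"

    areas = np.full(n, np.nan)
    widths = np.full(n, np.nan)
    arrivals = np.full(n, np.nan)

    # desorbed: countable peaks
    idx = np.flatnonzero(desorbed)
    if idx.size:
        sigma = regime.peak_area_sigma
        mu_log = np.log(regime.peak_area_mode) + sigma ** 2  # mode -> log-mean
        areas[idx] = rng.lognormal(mu_log, sigma, idx.size) * layer.mass_scale[idx]
        widths[idx] = rng.uniform(*regime.peak_width_range_us, idx.size)
        arrivals[idx] = sweep_t[idx] + rng.exponential(
            regime.washout_tail_ms * 1e-3, idx.size)
        for i in idx:
            n_w = max(1, int(round(widths[i] / dwell_us)))
            profile = np.exp(-np.arange(n_w) / max(n_w / 2.0, 1.0))
            profile *= areas[i] / profile.sum()
            k0 = min(int(arrivals[i] / dwell_s), n_dwells - 1)
            k1 = min(k0 + n_w, n_dwells)
            signal[k0:k1] += profile[: k1 - k0]

    # decayed: baseline smear around the sweep position, no countable peak
    idx = np.flatnonzero(decayed)
    if idx.size:
        sigma = regime.peak_area_sigma
        mu_log = np.log(regime.peak_area_mode) + sigma ** 2
        smear_area = (rng.lognormal(mu_log, sigma, idx.size) *
                      layer.mass_scale[idx] * regime.decay_signal_fraction)
        sd_dwells = max(regime.decay_spread_ms * 1e-3 / dwell_s, 1.0)
        half = int(np.ceil(3 * sd_dwells))
        kk = np.arange(-half, half + 1)
        kernel = np.exp(-0.5 * (kk / sd_dwells) ** 2)
        kernel /= kernel.sum()
        arrivals[idx] = sweep_t[idx] + rng.exponential(
            regime.washout_tail_ms * 1e-3, idx.size)
        for i, a in zip(idx, smear_area):
            k0 = min(int(arrivals[i] / dwell_s), n_dwells - 1)
            lo, hi = max(0, k0 - half), min(n_dwells, k0 + half + 1)
            signal[lo:hi] += a * kernel[lo - (k0 - half): hi - (k0 - half)]

    # residual layer (layer-local coordinates)
    res = (fate == "residual") | (fate == "not_swept")
    rx = layer.x_um[res].copy()
    ry = layer.y_um[res].copy()
    if regime.redeposition_prob > 0 and rx.size:
        pitch = pulse_pitch(plan)
        move = rng.uniform(size=rx.size) < regime.redeposition_prob
        rx[move] += rng.uniform(-pitch, pitch, move.sum())
        ry[move] += rng.uniform(-pitch, pitch, move.sum())
    rx = np.clip(rx, 0, layer.area_width)
    ry = np.clip(ry, 0, layer.area_height)
    residual = GroundTruthLayer(rx, ry, layer.mass_scale[res],
                                layer.area_width, layer.area_height,
                                density=rx.size / max(layer.area_mm2, 1e-12),
                                overdispersion=1.0)

    log = pd.DataFrame({
        "x_um": layer.x_um, "y_um": layer.y_um, "fate": fate,
        "sweep_time_s": np.where(swept, sweep_t, np.nan),
        "arrival_time_s": arrivals,
        "peak_area": areas, "peak_width_us": widths,
    })
    return TransientSignal(signal, dwell_us), residual, log


def simulate_reablation(residual: GroundTruthLayer, plan: RasterPlan,
                        regime: RegimeConfig, dwell_us: float = 100.0,
                        seed: int = 0,
                        ) -> tuple[TransientSignal, GroundTruthLayer, pd.DataFrame]:
    """Second ablation pass over the residual layer; identical contract to
    :func:`simulate_transient`."""
    return simulate_transient(residual, plan, regime, dwell_us, seed)


def write_event_log(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, sep="\t", index=False, float_format="%.6g")
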
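"""Linear–nonlinear–Poisson filter arrays applied to movie stimuli.

Each unit is a spatiotemporally separable filter: a 2-D Gaussian spatial
kernel (optionally with a subtracted surround Gaussian), a causal temporal
kernel shaped as a difference of two gamma lobes, a rectifying output
nonlinearity r(t) = max(0, baseline + drive), and inhomogeneous-Poisson
spike instantiation from the resulting rate.  Because the kernel is rank-1,
the per-frame spatial inner product followed by a 1-D temporal convolution
equals the full 3-D convolution of the kernel with the movie.

Movies are dense [frame, row, col] arrays with a frame rate (Hz) and a
degrees-per-pixel scale; contrast convention: values are centered on zero
after subtraction of the temporal-mean frame (:meth:`Movie.to_contrast`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import gamma as gamma_fn

from .model import ReportSeries, SpikeSet

__all__ = [
    "Movie",
    "FilterUnit",
    "FilterBank",
    "linear_drive",
    "firing_rate",
    "instantiate_spikes",
    "build_mosaic",
]


@dataclass
class Movie:
    """A dense grayscale movie: data[frame, row, col]."""

    data: np.ndarray
    frame_rate: float
    degrees_per_pixel: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("movie data must be 3-D [frame, row, col]")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_frames / self.frame_rate

    def to_contrast(self) -> "Movie":
        """Subtract the temporal-mean frame (zero-centered contrast)."""
        return Movie(self.data - self.data.mean(axis=0, keepdims=True),
                     self.frame_rate, self.degrees_per_pixel)

    # -- raw binary container (array file + JSON sidecar) ------------------

    def save(self, path) -> None:
        path = Path(path)
        self.data.astype("<f8").tofile(path)
        sidecar = {"shape": list(self.data.shape), "dtype": "<f8",
                   "frame_rate": self.frame_rate,
                   "degrees_per_pixel": self.degrees_per_pixel}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "Movie":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        data = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
        return cls(data, meta["frame_rate"], meta.get("degrees_per_pixel", 1.0))


@dataclass
class FilterUnit:
    """One LNP unit: spatial center-surround Gaussian + difference-of-gammas.

    Spatial kernel (degrees):
        G_c(x, y) - surround_weight * G_s(x, y),
    G_c a unit-integral Gaussian of width sigma_s scaled by ``gain``, G_s a
    Gaussian of width sigma_surround (0 weight disables the surround).

    Temporal kernel (causal, finite): difference of two gamma-shaped lobes
        k(t) ∝ t^{n1} exp(-t/tau1) - lobe_weight * t^{n2} exp(-t/tau2)
    with each lobe normalized to unit area before weighting, truncated at
    ``kernel_duration_ms`` and sampled on the movie's frame grid.
    """

    x: float = 0.0
    y: float = 0.0
    sigma_s: float = 1.0
    gain: float = 1.0
    surround_weight: float = 0.0
    sigma_surround: float = 2.0
    tau1: float = 15.0
    n1: int = 3
    tau2: float = 30.0
    n2: int = 5
    lobe_weight: float = 0.7
    baseline: float = 10.0
    kernel_duration_ms: float = 300.0
    output_rate: float = 1000.0

    def __post_init__(self):
        if self.baseline < 0:
            raise ValueError("baseline rate must be non-negative")
        if self.sigma_s <= 0 or self.sigma_surround <= 0:
            raise ValueError("spatial widths must be positive")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("temporal time constants must be positive")

    def spatial_kernel(self, movie: Movie) -> np.ndarray:
        """Kernel sampled on the movie's pixel grid (same [row, col] shape)."""
        n_rows, n_cols = movie.data.shape[1:]
        deg = movie.degrees_per_pixel
        ys = (np.arange(n_rows) - (n_rows - 1) / 2.0) * deg
        xs = (np.arange(n_cols) - (n_cols - 1) / 2.0) * deg
        dx2 = (xs[None, :] - self.x) ** 2
        dy2 = (ys[:, None] - self.y) ** 2
        r2 = dx2 + dy2

        def gauss(sig):
            return np.exp(-r2 / (2 * sig ** 2)) / (2 * np.pi * sig ** 2) * deg ** 2

        k = gauss(self.sigma_s)
        if self.surround_weight:
            k = k - self.surround_weight * gauss(self.sigma_surround)
        return self.gain * k

    def temporal_kernel(self, frame_rate: float) -> np.ndarray:
        """Causal kernel sampled at the movie frame interval, k[0] at lag 0."""
        dt = 1000.0 / frame_rate
        t = np.arange(0.0, self.kernel_duration_ms, dt)

        def lobe(n, tau):
            k = (t ** n) * np.exp(-t / tau)
            area = gamma_fn(n + 1) * tau ** (n + 1) / dt  # continuous-area norm
            return k / area

        return lobe(self.n1, self.tau1) - self.lobe_weight * lobe(self.n2, self.tau2)


@dataclass
class FilterBank:
    """A mosaic of filter units in a rectangular visual-field extent."""

    units: list[FilterUnit]
    extent: tuple[float, float, float, float] = (-10.0, 10.0, -10.0, 10.0)  # x0,x1,y0,y1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        x0, x1, y0, y1 = self.extent
        for i, u in enumerate(self.units):
            if not (x0 <= u.x <= x1 and y0 <= u.y <= y1):
                raise ValueError(f"unit {i} center ({u.x}, {u.y}) outside extent {self.extent}")


def linear_drive(unit: FilterUnit, movie: Movie, contrast: bool = True,
                 boundary: str = "zero_pad") -> np.ndarray:
    """Linear filter response, one value per movie frame.

    Per-frame spatial inner product with the spatial kernel, then causal
    convolution with the temporal kernel.  Spatial support reaching outside
    the frame is zero-padded by construction (the kernel is evaluated on the
    movie grid only); ``boundary="error"`` instead rejects units whose
    3-sigma spatial support exits the frame.
    """
    if boundary not in ("zero_pad", "error"):
        raise ValueError("boundary must be 'zero_pad' or 'error'")
    if boundary == "error":
        n_rows, n_cols = movie.data.shape[1:]
        deg = movie.degrees_per_pixel
        half_w, half_h = (n_cols - 1) / 2.0 * deg, (n_rows - 1) / 2.0 * deg
        support = 3.0 * max(unit.sigma_s,
                            unit.sigma_surround if unit.surround_weight else 0.0)
        if (abs(unit.x) + support > half_w) or (abs(unit.y) + support > half_h):
            raise ValueError(
                f"filter support at ({unit.x}, {unit.y}) +/- {support} deg exceeds movie frame")
    if contrast:
        movie = movie.to_contrast()
    k_space = unit.spatial_kernel(movie)
    spatial = np.tensordot(movie.data, k_space, axes=([1, 2], [0, 1]))
    k_time = unit.temporal_kernel(movie.frame_rate)
    return np.convolve(spatial, k_time)[: movie.n_frames]


def firing_rate(unit: FilterUnit, movie: Movie, contrast: bool = True) -> ReportSeries:
    """Rectified rate r(t) = max(0, baseline + drive), resampled to the
    unit's output rate (Hz) by linear interpolation between frame samples."""
    drive = linear_drive(unit, movie, contrast=contrast)
    frame_dt = 1000.0 / movie.frame_rate
    t_frames = frame_dt * np.arange(movie.n_frames)
    out_dt = 1000.0 / unit.output_rate
    n_out = int(np.floor(movie.duration_ms / out_dt))
    t_out = out_dt * np.arange(n_out)
    drive_resampled = np.interp(t_out, t_frames, drive)
    rate = np.maximum(0.0, unit.baseline + drive_resampled)
    return ReportSeries(variable="firing_rate", dt=out_dt, data=rate[:, None], units="Hz")


def instantiate_spikes(rate: ReportSeries, n_trials: int, seed: int,
                       population: str = "filter", channel: int = 0) -> SpikeSet:
    """Inhomogeneous Poisson spike trains from a rate series, by thinning.

    Candidate spikes are drawn homogeneously at the max rate and kept with
    probability r(t)/r_max; one independent train per trial, node_id = trial
    index.
    """
    r = rate.data[:, channel]
    if np.any(r < 0):
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    duration = rate.n_samples * rate.dt
    r_max = float(r.max())
    ids_out, times_out = [], []
    if r_max > 0:
        for trial in range(n_trials):
            n_cand = rng.poisson(r_max * duration / 1000.0)
            t_cand = np.sort(rng.random(n_cand) * duration)
            r_at = np.interp(t_cand, rate.start + rate.dt * np.arange(rate.n_samples), r)
            keep = rng.random(n_cand) < r_at / r_max
            times_out.append(t_cand[keep])
            ids_out.append(np.full(int(keep.sum()), trial, dtype=np.int64))
    if not ids_out:
        return SpikeSet(sort_order="by_time")
    return SpikeSet.from_arrays(population, np.concatenate(ids_out),
                                np.concatenate(times_out), sort="by_time")


def build_mosaic(n: int, extent: tuple[float, float, float, float],
                 template: FilterUnit, seed: int, jitter: float = 0.0,
                 placement: str = "uniform") -> FilterBank:
    """Place n copies of ``template`` in ``extent`` (degrees), reproducibly.

    placement="uniform" draws centers i.i.d. uniform over the extent;
    "grid" lays them on a near-square grid, with optional uniform jitter of
    +/- ``jitter`` degrees (clipped to the extent).  n=1 with zero jitter
    centers the single unit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x0, x1, y0, y1 = extent
    if n == 1 and jitter == 0.0:
        xs, ys = np.array([(x0 + x1) / 2]), np.array([(y0 + y1) / 2])
    elif placement == "uniform":
        xs = x0 + (x1 - x0) * rng.random(n)
        ys = y0 + (y1 - y0) * rng.random(n)
    elif placement == "grid":
        cols = int(np.ceil(np.sqrt(n)))
        rows = int(np.ceil(n / cols))
        gx = x0 + (x1 - x0) * (np.arange(cols) + 0.5) / cols
        gy = y0 + (y1 - y0) * (np.arange(rows) + 0.5) / rows
        xx, yy = np.meshgrid(gx, gy)
        xs, ys = xx.ravel()[:n], yy.ravel()[:n]
        if jitter:
            xs = np.clip(xs + jitter * (2 * rng.random(n) - 1), x0, x1)
            ys = np.clip(ys + jitter * (2 * rng.random(n) - 1), y0, y1)
    else:
        raise ValueError(f"unknown placement {placement!r}")
    units = [replace(template, x=float(px), y=float(py)) for px, py in zip(xs, ys)]
    return FilterBank(units=units, extent=extent,
                      metadata={"seed": seed, "placement": placement, "jitter": jitter})
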
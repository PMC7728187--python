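"""Activity post-processing: firing rates, population rate series, spectral
peaks, and the optogenetic modulation index (OMI).

The OMI of a cell compares its firing rate during a perturbation against the
unperturbed control:

    OMI = (f_perturbed - f_control) / (f_perturbed + f_control)

bounded in [-1, 1]; -1 means full suppression, +1 firing only under the
perturbation, and the value is undefined when both rates are zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .model import ReportSeries, SpikeSet

log = logging.getLogger(__name__)

__all__ = [
    "firing_rates",
    "population_rate",
    "psd_peak",
    "omi",
    "omi_table",
    "OMITable",
    "cv_isi",
]


def firing_rates(spikes: SpikeSet, window: tuple[float, float],
                 population: str | None = None,
                 n_cells: int | None = None,
                 n_trials: int = 1) -> pd.DataFrame:
    """Mean firing rate (Hz) per cell over ``window`` = (t0, t1) ms.

    Counts spikes in [t0, t1) and divides by the window length and by
    ``n_trials`` (events from repeated trials may be pooled into one
    SpikeSet).  With ``n_cells`` given, cells that never fired are included
    at 0 Hz.  Returns a DataFrame indexed by node_id with a ``rate`` column.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window end must exceed start")
    if population is None:
        pops = spikes.population_names()
        if len(pops) > 1:
            raise ValueError(f"multiple populations present, specify one of {pops}")
        population = pops[0] if pops else ""
    ids, times = spikes.select(population)
    m = (times >= t0) & (times < t1)
    counts = pd.Series(ids[m]).value_counts()
    if n_cells is not None:
        counts = counts.reindex(np.arange(n_cells), fill_value=0)
    duration_s = (t1 - t0) / 1000.0
    out = pd.DataFrame({"rate": counts.sort_index() / duration_s / n_trials})
    out.index.name = "node_id"
    return out


def population_rate(spikes: SpikeSet, bin_ms: float, n_cells: int,
                    duration: float, population: str | None = None,
                    t0: float = 0.0) -> ReportSeries:
    """Binned population firing rate (Hz): count / (bin * n_cells).

    The integral of the series over time equals (total spike count)/n_cells.
    """
    if bin_ms <= 0:
        raise ValueError("bin must be positive")
    if population is None:
        pops = spikes.population_names()
        population = pops[0] if pops else ""
    _, times = spikes.select(population)
    n_bins = int(round((duration - t0) / bin_ms))
    counts, _ = np.histogram(times, bins=n_bins, range=(t0, t0 + n_bins * bin_ms))
    rate = counts / (bin_ms / 1000.0) / n_cells
    return ReportSeries(variable="population_rate", dt=bin_ms, start=t0,
                        data=rate[:, None], units="Hz")


def psd_peak(series: ReportSeries, band: tuple[float, float],
             channel: int = 0, nperseg: int | None = None,
             prominence_ratio: float = 2.0) -> dict:
    """Dominant frequency of a series within ``band`` (Hz), Welch PSD.

    Returns {"frequency", "resolution", "power", "prominent"}: the peak
    frequency, the frequency-bin width, peak power, and a flag that is False
    when the peak does not stand out above the median in-band power by
    ``prominence_ratio`` (e.g. featureless/white spectra).
    """
    fs = 1000.0 / series.dt  # Hz
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist {fs / 2} Hz")
    x = series.data[:, channel] - series.data[:, channel].mean()
    if len(x) < 2 * fs / lo:
        raise ValueError("series too short: need at least two cycles of the lowest band frequency")
    if nperseg is None:
        nperseg = min(len(x), max(256, int(4 * fs / lo)))
    freqs, pxx = signal.welch(x, fs=fs, nperseg=nperseg)
    m = (freqs >= lo) & (freqs <= hi)
    if not m.any():
        raise ValueError("band contains no frequency bins")
    fb, pb = freqs[m], pxx[m]
    k = int(np.argmax(pb))
    med = float(np.median(pb))
    prominent = bool(pb[k] > prominence_ratio * med) if med > 0 else bool(pb[k] > 0)
    if not prominent:
        log.info("psd_peak: low-prominence peak at %.2f Hz (ratio %.2f)", fb[k],
                 pb[k] / med if med > 0 else np.inf)
    return {"frequency": float(fb[k]), "resolution": float(freqs[1] - freqs[0]),
            "power": float(pb[k]), "prominent": prominent}


def omi(f_perturbed: float, f_control: float) -> float | None:
    """Optogenetic modulation index; None when both rates are zero.

    (f_p - f_c) / (f_p + f_c): -1 iff fully suppressed (f_p = 0 < f_c),
    +1 iff firing only during perturbation, 0 for unchanged rates.
    """
    if f_perturbed < 0 or f_control < 0:
        raise ValueError("firing rates must be non-negative")
    denom = f_perturbed + f_control
    if denom == 0:
        return None
    return (f_perturbed - f_control) / denom


@dataclass
class OMITable:
    """Per-cell OMI results plus the group mean over defined entries."""

    frame: pd.DataFrame
    n_undefined: int = 0
    group_mean: float | None = None
    cells: list = field(default_factory=list)


def omi_table(perturbed: pd.DataFrame, control: pd.DataFrame) -> OMITable:
    """Per-cell OMI from two :func:`firing_rates` tables (aligned on node_id).

    The group mean is the mean of per-cell OMIs over cells where the index is
    defined; cells silent in both conditions are excluded and counted.
    """
    joined = perturbed.join(control, how="outer", lsuffix="_perturbed", rsuffix="_control")
    joined = joined.fillna(0.0)
    fp = joined["rate_perturbed"].to_numpy(dtype=float)
    fc = joined["rate_control"].to_numpy(dtype=float)
    denom = fp + fc
    values = np.where(denom > 0, (fp - fc) / np.where(denom > 0, denom, 1.0), np.nan)
    frame = pd.DataFrame({"f_perturbed": fp, "f_control": fc, "omi": values},
                         index=joined.index)
    n_undef = int(np.isnan(values).sum())
    if n_undef:
        log.info("omi_table: %d cells silent in both conditions excluded from group mean",
                 n_undef)
    defined = values[~np.isnan(values)]
    return OMITable(frame=frame, n_undefined=n_undef,
                    group_mean=float(defined.mean()) if len(defined) else None)


def cv_isi(spikes: SpikeSet, population: str | None = None,
           min_spikes: int = 3) -> pd.Series:
    """Coefficient of variation of inter-spike intervals per cell.

    Cells with fewer than ``min_spikes`` spikes are omitted.  CV(ISI) well
    below 1 indicates regular (clock-like) firing; 1 is Poisson-like.
    """
    if population is None:
        pops = spikes.population_names()
        population = pops[0] if pops else ""
    ids, times = spikes.select(population)
    order = np.lexsort((times, ids))
    ids, times = ids[order], times[order]
    out = {}
    for cell in np.unique(ids):
        t = times[ids == cell]
        if len(t) < min_spikes:
            continue
        isi = np.diff(t)
        m = isi.mean()
        out[int(cell)] = float(isi.std() / m) if m > 0 else np.nan
    return pd.Series(out, name="cv_isi")
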
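"""Extracellular signal chain: passive-cable currents, line-source
potentials, low-pass LFP, and delta-source inverse CSD.

The chain mirrors how extracellular recordings arise in tissue: distributed
transmembrane currents of compartmental neurons superpose into a potential
at each electrode (here via the line-source approximation for a homogeneous
ohmic medium), the low-frequency component is the LFP, and laminar LFP
profiles are inverted into a current-source-density estimate under a
planar-disk source model of chosen column diameter.

Units: µm (geometry), ms, nA (currents), mV (potentials), S/m (conductivity),
Ω·cm (axial resistivity), µF/cm² (capacitance), Ω·cm² (membrane resistance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, sparse

from .model import ReportSeries

__all__ = [
    "Morphology",
    "CurrentMatrix",
    "ElectrodeArray",
    "CSDProfile",
    "simulate_passive_cable",
    "line_source_potential",
    "lowpass_lfp",
    "icsd_delta",
]


@dataclass
class Morphology:
    """A neuron as a tree of cylindrical segments.

    ``proximal``/``distal`` are (n, 3) endpoint arrays (µm), ``radius`` per
    segment (µm), ``parent`` the index of each segment's parent (-1 for the
    root).  Passive electrical constants are uniform over the tree.
    """

    proximal: np.ndarray
    distal: np.ndarray
    radius: np.ndarray
    parent: np.ndarray
    axial_resistivity: float = 150.0      # Ω·cm
    capacitance: float = 1.0              # µF/cm²
    membrane_resistance: float = 20_000.0  # Ω·cm²

    def __post_init__(self):
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        n = self.n_segments
        if self.proximal.shape != (n, 3) or self.distal.shape != (n, 3):
            raise ValueError("endpoint arrays must be (n, 3)")
        if np.any(self.radius <= 0):
            raise ValueError("segment radii must be positive")
        if np.sum(self.parent < 0) != 1:
            raise ValueError("exactly one root segment (parent -1) required")
        # connectivity: every segment must reach the root
        root = int(np.nonzero(self.parent < 0)[0][0])
        seen = {root}
        pending = [i for i in range(n) if i != root]
        progress = True
        while pending and progress:
            progress = False
            for i in list(pending):
                if int(self.parent[i]) in seen:
                    seen.add(i)
                    pending.remove(i)
                    progress = True
        if pending:
            raise ValueError(f"disconnected segments: {pending}")

    @property
    def n_segments(self) -> int:
        return len(self.radius)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.distal - self.proximal, axis=1)

    @property
    def areas_cm2(self) -> np.ndarray:
        """Lateral membrane area per segment in cm²."""
        return 2 * np.pi * (self.radius * 1e-4) * (self.lengths * 1e-4)


@dataclass
class CurrentMatrix:
    """Transmembrane currents [segment × time] (nA) with geometry reference.

    ``injected`` is the per-time total intracellular injection (nA); at every
    step the summed transmembrane current equals it (Kirchhoff closure).
    """

    currents: np.ndarray
    dt: float
    morphology: Morphology
    injected: np.ndarray | None = None

    def __post_init__(self):
        self.currents = np.asarray(self.currents, dtype=float)
        if self.currents.ndim != 2:
            raise ValueError("currents must be [segment x time]")
        if self.injected is None:
            self.injected = np.zeros(self.currents.shape[1])

    def kirchhoff_residual(self) -> float:
        """Max relative violation of sum(membrane currents) == injected."""
        total = self.currents.sum(axis=0)
        scale = max(1e-12, float(np.max(np.abs(self.injected))), float(np.max(np.abs(total))))
        return float(np.max(np.abs(total - self.injected)) / scale)


@dataclass
class ElectrodeArray:
    """Extracellular recording sites (µm) in a homogeneous medium."""

    positions: np.ndarray
    sigma_e: float = 0.3  # S/m

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] != 3:
            raise ValueError("electrode positions must be (n, 3)")
        if self.sigma_e <= 0:
            raise ValueError("conductivity must be positive")
        if len(np.unique(self.positions, axis=0)) != len(self.positions):
            raise ValueError("electrode positions must be distinct")

    @classmethod
    def from_text(cls, path, sigma_e: float = 0.3) -> "ElectrodeArray":
        return cls(np.loadtxt(path, ndmin=2), sigma_e=sigma_e)

    def save_text(self, path) -> None:
        np.savetxt(path, self.positions, fmt="%.6g", header="x y z (um)")


@dataclass
class CSDProfile:
    """CSD estimate per depth and time; sinks are negative by convention."""

    depths: np.ndarray
    values: np.ndarray  # [depth x time], current per volume (nA/mm^3)
    dt: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")


# ---------------------------------------------------------------------------
# passive cable
# ---------------------------------------------------------------------------

def simulate_passive_cable(m: Morphology, stimuli: dict[int, np.ndarray],
                           duration: float, dt: float) -> CurrentMatrix:
    """Integrate the discretized passive cable equation (backward Euler).

    ``stimuli`` maps segment index → injected current time series (nA), each
    of length ``round(duration/dt)`` (shorter series are zero-padded).
    Returns capacitive + leak transmembrane current per segment; Kirchhoff
    closure (sum of membrane currents == injected current) holds to solver
    precision because the implicit step enforces it identically.
    """
    n = m.n_segments
    n_steps = int(round(duration / dt))
    # work in units: V in mV, I in nA, t in ms  =>  C in nF, g in µS
    area = m.areas_cm2                             # cm²
    c_m = m.capacitance * area * 1e3               # µF -> nF
    g_leak = (area / m.membrane_resistance) * 1e6  # S·(cm²/Ω·cm²)=S -> µS

    # axial conductance between segment centers (series of half-segments)
    half_res = (m.axial_resistivity * (m.lengths * 1e-4 / 2.0)
                / (np.pi * (m.radius * 1e-4) ** 2))  # Ω
    G = sparse.lil_matrix((n, n))
    for i in range(n):
        p = int(m.parent[i])
        if p < 0:
            continue
        g_ax = 1e6 / (half_res[i] + half_res[p])  # µS
        G[i, i] += g_ax
        G[p, p] += g_ax
        G[i, p] -= g_ax
        G[p, i] -= g_ax
    G = G.tocsr()

    # backward Euler: (C/dt + g_leak + G) V_{k+1} = C/dt V_k + I_inj
    A = sparse.diags(c_m / dt + g_leak) + G
    A = A.tocsc()
    lu = sparse.linalg.splu(A)

    inj = np.zeros((n, n_steps))
    for seg, series in stimuli.items():
        series = np.asarray(series, dtype=float)
        inj[seg, : min(len(series), n_steps)] = series[:n_steps]

    v = np.zeros(n)  # deviation from rest, mV
    i_mem = np.zeros((n, n_steps))
    for k in range(n_steps):
        rhs = c_m / dt * v + inj[:, k]
        v_new = lu.solve(rhs)
        # membrane current = capacitive + leak = injected + axial inflow
        i_mem[:, k] = c_m * (v_new - v) / dt + g_leak * v_new
        v = v_new

    return CurrentMatrix(currents=i_mem, dt=dt, morphology=m,
                         injected=inj.sum(axis=0))


# ---------------------------------------------------------------------------
# line-source extracellular potential
# ---------------------------------------------------------------------------

def line_source_potential(c: CurrentMatrix, e: ElectrodeArray) -> ReportSeries:
    """Extracellular potential (mV) per electrode via line sources.

    Each segment is treated as a uniform line current of length L in an
    infinite homogeneous medium of conductivity sigma_e:

        phi = I / (4 pi sigma_e L) * ln |(sqrt(h² + r²) - h) / (sqrt(l² + r²) - l)|

    with h, l the axial distances from the electrode's projection to the two
    segment ends and r the perpendicular distance, clamped below at the
    segment radius to avoid the on-axis singularity.  Superposition over
    segments.
    """
    m = c.morphology
    lengths = m.lengths
    if np.any(lengths <= 0):
        raise ValueError("zero-length segment")
    pos = e.positions
    n_el = len(pos)

    # geometry per (electrode, segment)
    axis = (m.distal - m.proximal) / lengths[:, None]
    rel = pos[:, None, :] - m.proximal[None, :, :]        # electrode - proximal end
    l_axial = np.einsum("esk,sk->es", rel, axis)          # along-axis coordinate
    r_perp2 = np.maximum(np.einsum("esk,esk->es", rel, rel) - l_axial ** 2, 0.0)
    r_perp = np.sqrt(r_perp2)
    r_perp = np.maximum(r_perp, m.radius[None, :])        # singularity clamp
    # signed axial distances of the electrode projection from the two ends:
    # h from the distal end, l from the proximal end (l = h + L)
    h = l_axial - lengths[None, :]
    l = l_axial
    num = np.sqrt(h ** 2 + r_perp ** 2) - h
    den = np.sqrt(l ** 2 + r_perp ** 2) - l
    # both terms are positive for r>0; guard tiny values
    eps = 1e-30
    log_term = np.log(np.maximum(num, eps) / np.maximum(den, eps))

    # nA / (S/m * µm) -> convert: I[nA]=1e-9 A, L[µm]=1e-6 m => A/(S/m·m)=V
    # phi[V] = I*1e-9 / (4 pi sigma L*1e-6) * |ln| -> mV: *1e3
    coef = 1e-9 / (4 * np.pi * e.sigma_e * lengths * 1e-6) * 1e3  # mV per nA
    weights = coef[None, :] * log_term  # (electrode, segment); note sign of ln

    phi = weights @ c.currents  # (electrode, time)
    return ReportSeries(variable="extracellular_potential", dt=c.dt,
                        data=phi.T, channel_ids=np.arange(n_el), units="mV")


# ---------------------------------------------------------------------------
# LFP filtering
# ---------------------------------------------------------------------------

def lowpass_lfp(phi: ReportSeries, cutoff: float = 500.0, order: int = 4) -> ReportSeries:
    """Zero-phase Butterworth low-pass (forward-backward), unit DC gain."""
    fs = 1000.0 / phi.dt
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    data = signal.sosfiltfilt(sos, phi.data, axis=0)
    return ReportSeries(variable="lfp", dt=phi.dt, start=phi.start, data=data,
                        channel_ids=phi.channel_ids, units=phi.units)


# ---------------------------------------------------------------------------
# delta-source inverse CSD
# ---------------------------------------------------------------------------

def delta_icsd_forward_matrix(depths: np.ndarray, diameter_um: float,
                              sigma_e: float) -> np.ndarray:
    """Forward matrix mapping planar CSD (nA/mm²) at each electrode depth to
    potentials (mV) at all electrode depths.

    Each source is an infinitesimally thin uniform disk of the given diameter
    centered on the depth axis; the potential of disk j at depth z_i is

        phi_ij = C_j / (2 sigma_e) * (sqrt((z_i - z_j)^2 + R^2) - |z_i - z_j|).
    """
    z = np.asarray(depths, dtype=float) * 1e-3  # µm -> mm
    R = (diameter_um * 1e-3) / 2.0
    dz = np.abs(z[:, None] - z[None, :])
    geom = np.sqrt(dz ** 2 + R ** 2) - dz      # mm
    # C [nA/mm²] * mm / (S/m): nA/mm = 1e-6 A/m; /(S/m) -> 1e-6 V = 1e-3 mV
    return geom * 1e-3 / (2.0 * sigma_e)


def icsd_delta(lfp: ReportSeries, depths: np.ndarray, diameter_um: float = 800.0,
               sigma_e: float = 0.3) -> CSDProfile:
    """Delta-source inverse CSD from a laminar LFP profile.

    ``depths`` (µm) must be strictly increasing and evenly spaced, one per
    LFP channel.  The planar estimate is converted to a volume CSD by
    dividing by the electrode spacing; forward-mapping the estimate
    reproduces the input LFP to numerical precision.  Sinks (current leaving
    the extracellular space) come out negative.
    """
    depths = np.asarray(depths, dtype=float)
    if len(depths) != lfp.data.shape[1]:
        raise ValueError("one depth per LFP channel required")
    spacing = np.diff(depths)
    if np.any(spacing <= 0):
        raise ValueError("depths must be strictly increasing")
    if np.max(np.abs(spacing - spacing[0])) > 1e-6 * spacing[0]:
        raise ValueError("delta-source iCSD requires evenly spaced electrodes")

    F = delta_icsd_forward_matrix(depths, diameter_um, sigma_e)
    cond = np.linalg.cond(F)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(f"singular forward matrix (cond={cond:.3g})")
    planar = np.linalg.solve(F, lfp.data.T)  # (depth, time), nA/mm²
    h_mm = spacing[0] * 1e-3
    volume = planar / h_mm                   # nA/mm³
    return CSDProfile(depths=depths, values=volume, dt=lfp.dt,
                      metadata={"method": "delta_icsd", "diameter_um": diameter_um,
                                "sigma_e": sigma_e})
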
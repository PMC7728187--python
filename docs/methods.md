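# Methods

This note documents the models implemented in circuitkit, the parameter
choices behind the packaged examples, the numerical schemes, and what the
synthetic fixtures do and do not establish about real data.

## File dialect

Networks are stored in a deliberately narrow SONATA subset: one group
(id 0) per node/edge population in HDF5, type tables as space-delimited text
with a header row and `NULL` for missing values, spike files as
per-population `timestamps`/`node_ids` datasets with a `sorting` attribute
(default sort: by time). Units are fixed globally — ids 0-based, times in
ms, positions in µm. Readers are tolerant (unknown config keys warn and are
kept; arbitrary attribute columns round-trip bit-faithfully), writers are
strict (referential integrity is validated before anything touches disk).
The restriction to a single group keeps files readable by generic SONATA
tooling while avoiding multi-group bookkeeping that none of the packaged
models need.

## Builder semantics

`add_edges` evaluates one independent Bernoulli trial per ordered
(source, target) pair; autapses are excluded by default (the conventional
choice — at the packaged network's size the expected edge count differs by
only 0.01% between the two conventions). Each `add_edges` call draws from
an RNG sub-stream keyed by (master seed, call index), so appending a rule
never perturbs earlier draws; together with blockwise vectorized sampling
and (source, target)-lexicographic emission this makes entire builds, and
the files they produce, bitwise reproducible. Pair blocks are capped at
8·10⁶ uniforms (~64 MB) so the full 12,500² pair matrix never materializes.

## Point-neuron model

Current-based LIF with exponential PSCs:

    τ_m dV/dt     = −(V − V_rest) + R_m (I_syn + I_ext)
    τ_syn dI_syn/dt = −I_syn,      arrival: I_syn += w

Between step boundaries the (V, I_syn) system is linear, so both states are
advanced with the exact propagator (the particular solution for an
exponentially decaying input is V_p = c·I_syn with
c = R_m τ_syn/(τ_syn − τ_m); the degenerate τ_m = τ_syn case uses the
t·e^{−t/τ} limit). Subthreshold dynamics therefore carry no discretization
error; the only dt-dependence is spike detection at step boundaries
(V ≥ V_th → reset, refractory countdown, delayed delivery). Delays are
rounded to whole steps and must be ≥ dt. Delivery uses one CSR weight
matrix per distinct delay and a ring buffer of length max-delay+1, which
keeps the cost per step proportional to the number of spikes times mean
out-degree. The f–I curve of the implementation matches the closed form
1000/(t_ref + τ_m ln((IR + V_rest − V_reset)/(IR + V_rest − V_th))) to
better than 1% at dt = 0.01 ms (tested).

Rheobase is (V_th − V_rest)/R_m. Perturbations are rectangular currents on
[onset, offset), specified absolutely (pA) or as a per-cell rheobase
fraction; "silencing" is injection of −5× rheobase, which is configurable —
the sign and magnitude guarantee suppression for any drive the packaged
models produce, but an extremely driven cell could in principle overcome it.

### The packaged E/I example

10,000 excitatory + 2,500 inhibitory neurons, recurrent Bernoulli(0.1)
connectivity (≈15.6 M edges), 1,000 external Poisson sources at 150 Hz with
feedforward in-degree 10, all delays 1.5 ms. The dynamical parameters are a
design choice of this package (frozen once, in `fixtures.EI_PARAMS`):

| parameter | value | note |
|---|---|---|
| τ_m | 50 ms | sets the ~50 ms recharge period of the rhythm |
| V_rest = V_reset | −70 mV | |
| V_th | −55 mV | rheobase 150 pA with R_m = 100 MΩ |
| t_ref | 2 ms | |
| τ_syn | 2 ms | |
| w_ext | 80 pA | mean external drive ≈ 24 mV, clearly suprathreshold |
| w_exc | 2 pA | recruits laggards into each population burst |
| w_inh | −8 pA | terminates the burst and resets the phase |

Mechanism: after a synchronized burst, every neuron is reset and recharges
toward the suprathreshold mean drive with time constant τ_m; the recharge
time τ_m·ln(μ/(μ−15 mV)) ≈ 50 ms sets a near-deterministic ~20 Hz rhythm,
recurrent excitation sharpens burst onset, and inhibition terminates it.
This deterministic-recharge design was chosen over a fluctuation-driven
variant (τ_m = 20 ms, near-threshold drive) because the latter's period
jitters enough that the measured spectral peak wanders far outside the
15–25 Hz target band from seed to seed; with the frozen parameters the peak
is 17.5–21.25 Hz across seeds, mean excitatory rate ≈ 19 Hz, median
CV(ISI) ≈ 0.19.

Scaling: `make_ei_example(scale=k)` divides neuron counts by k and raises
the recurrent connection probability to min(1, 0.1k), preserving every
neuron's expected in-degree (at k = 10 the recurrent graph is all-to-all);
the external population and feedforward in-degree are kept. The regime is
verified to be quantitatively identical at scale 1 and scale 10, which is
why the test suite runs the scaled clone (seconds) while the acceptance
script runs the full network (~25 s).

The feedforward wiring uses fixed in-degree 10 from the 1,000 sources
(12,500 × 10 = 125,000 feedforward edges), an interpretation chosen because
it fixes each cell's drive statistics exactly.

## Filter model

Each unit is spatiotemporally separable: a center(−surround) Gaussian
spatial kernel sampled on the movie's pixel grid (unit continuous integral
per lobe, scaled by `gain`), and a causal difference-of-gammas temporal
kernel t^n e^{−t/τ} (each lobe normalized to unit continuous area,
truncated at 300 ms by default). Because the kernel is rank-1, per-frame
spatial inner products followed by 1-D causal convolution equal the full
3-D convolution; the test suite checks this identity against a brute-force
triple loop to 10⁻¹⁰ relative. Movies are converted to contrast by
subtracting the temporal-mean frame (grayscale only). Rectification is
r = max(0, baseline + drive) — gain is applied inside the linear stage,
before baseline and rectification. Spatial support that exits the movie
frame is zero-padded by construction; a `boundary="error"` switch rejects
such units instead (3σ support criterion). Rates are resampled from the
frame grid to the output rate (default 1000 Hz) by linear interpolation,
and spikes are drawn by Poisson thinning against the rate maximum.

## Population-rate model

An explicit substitution: instead of a population-density (master-equation)
solver, populations follow delayed Wilson–Cowan-type relaxation dynamics

    τ_a dr_a/dt = −r_a + F_a(Σ_b w_ab r_b(t − d_ab) + I_a)

with threshold-linear or logistic gains, integrated by explicit Euler
(default dt 0.1 ms; dt must not exceed the smallest positive delay) with
per-connection delay ring buffers. Rates are clipped at 0 each step (the
gains are nonnegative; clipping guards accumulated Euler error). External
populations are constant-rate sources: their pooled output is treated as
stationary even though the underlying spikes are irregular.

`reduce_network` collapses a built network: coupling weight between groups
is (mean |syn_weight·nsyns|) × (mean in-degree per target-group neuron),
signed by the source group's class; delays are averaged. This mean-field
summary ignores weight–degree correlations, which none of the packaged
networks have.

The packaged 3-node model (E, I, constant 150 Hz source; parameters in
`fixtures.RATE_PARAMS`) is a relaxation oscillator: supercritical
self-excitation (w_EE = 1.3 at 2 ms delay) regenerates an excitatory burst,
delayed inhibition (E→I at 5 ms, I→E at −4 weight) crushes it to the
rectification floor, and the cycle repeats at 20.0 Hz with rate minima
around 2% of the peak — the excitatory trace collapses to near-silence
between bursts. The model is deterministic; no finite-size noise is
modeled.

## Extracellular chain

The passive-cable toy neuron discretizes a segment tree into one
compartment per segment, with axial conductances from half-segment series
resistances and backward-Euler time stepping; transmembrane current is
capacitive + leak, which the implicit step makes identically equal to
injected + axial inflow, so Kirchhoff closure (Σ membrane currents =
injected current) holds to solver precision at every step. This is a
current source for testing the signal chain, not a conductance-based neuron
model.

Line-source potential of segment length L at perpendicular distance r,
with h and l the signed axial distances of the electrode's projection from
the segment's distal and proximal ends:

    φ = I / (4π σ_e L) · ln[(√(h²+r²) − h) / (√(l²+r²) − l)]

superposed over segments in a homogeneous, isotropic medium (σ_e default
0.3 S/m); r is clamped below at the segment radius to avoid the on-axis
logarithmic singularity. The far-field limit reproduces the point-source
I/4πσr to 0.1% (tested), and φ is invariant under joint translation of
neuron and electrodes.

LFP: zero-phase (forward–backward) 4th-order Butterworth low-pass, unit DC
gain, default cutoff 500 Hz — the filter order and cutoff are package
defaults, documented rather than derived.

Delta-source inverse CSD: laminar electrodes (strictly increasing, evenly
spaced depths along z) are modeled as infinitesimally thin uniform disks of
configurable diameter (default 0.8 mm); the forward matrix
F_ij = (√((z_i−z_j)² + R²) − |z_i−z_j|)/2σ_e maps planar CSD to potentials
and is inverted directly (conditioning checked; the geometry makes F
well-conditioned for realistic probe layouts). Planar estimates are
divided by the electrode spacing to give volume CSD, sinks negative. The
estimator recovers a planted disk source through its own forward model to
10⁻⁶ and approaches the classical second-spatial-difference CSD in the
large-diameter limit (both tested).

## Analysis conventions

Spectral peaks use Welch's averaged periodogram on the mean-subtracted
series, restricted to a stated band; a peak is flagged non-prominent when it
does not exceed twice the median in-band power (white-noise inputs are
flagged, tested). OMI is undefined when both rates are zero; such cells are
excluded from group means with a logged count, and group means average
per-cell OMIs rather than taking the OMI of mean rates. The default OMI
window is the perturbation window.

## What the fixtures do and do not show

All test inputs are generated programmatically: Bernoulli/Gaussian-rule
networks with statistically exchangeable nodes, homogeneous Poisson drive,
noise/grating/flash movies, ball-and-stick morphologies, planted single-disk
CSD profiles. Passing tests establish the correctness of the machinery —
integrators against closed forms, estimators against their own forward
models, statistics against analytic error bands — and the existence of the
packaged dynamical regimes. They do not establish that these parameter
choices reproduce any particular biological circuit: real cortical networks
have heterogeneous cell classes, structured (non-Bernoulli) connectivity,
conductance-based synapses, and LFP contributions from morphologies far
richer than a ball-and-stick; the ~20 Hz regime here is one deliberately
selected operating point, not a prediction.

## Known limitations

- Single-process execution; no MPI/threading.
- One synaptic time constant per neuron (no per-synapse-type kinetics);
  current-based synapses only; no plasticity, adaptation, or GLIF
  after-spike currents.
- The rate module is a mean-field reduction, not a population-density
  solver; it carries no finite-size fluctuations.
- Extracellular conductivity is uniform and isotropic; no kernel-based CSD
  (kCSD) estimator.
- Movie stimuli are grayscale; filter parameters are package defaults, not
  fits to recordings.
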
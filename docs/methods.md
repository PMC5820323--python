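# Methods

## The model

`sinres` simulates a random recurrent neural network (rRNN) of N nodes with
a **sinusoidal** activation,

    x_{n+1} = mu * sin( W x_n + W_off b + W_fb alpha y_n ),

and studies its computation — one-step-ahead learning and closed-loop
free-run prediction of the Mackey-Glass (MG) chaotic series — as a function
of the single bifurcation parameter mu (the feedback amplification).
Unlike the usual tanh echo-state network, whose resting state destabilizes
once and then stays chaotic, the periodic activation creates a *cascade* of
regular (non-chaotic) windows at large mu, separated by chaotic gaps.  The
package measures five complexity indices across mu: the closed-loop
prediction NMSE, the autonomous output variation sigma_alpha0, the spatial
synchronization error delta, the mutual-information sum C, and the maximal
Lyapunov exponent lambda_max.

## Weight construction

* `W`: dense N x N, entries uniform on [0, 1], exactly
  `floor((1-connectivity) N^2)` uniformly chosen entries zeroed
  (connectivity 0.99 by default), then **scaled to unit spectral radius**.
  The scaling makes mu the effective loop gain: the resting state
  destabilizes near mu = 1 and the regular windows land where the
  bifurcation scan reports them (first window up to mu ~ 2.6-2.8, second
  from ~ 4.7, third near ~ 8.0-8.6).  Without the scaling the spectral
  radius is ~ N/2 and the network is chaotic for every mu > 0 — there is
  then no window structure at all, so the normalized form is the only
  defensible reading of the model.
* `W_off`: uniform [0, 1].  Together with b = 0.2 it spreads the node
  operating points; the window positions depend on it.
* `W_fb`: uniform [-1, 1] (signed).  The input weights do not enter the
  autonomous dynamics, so the windows are unaffected; signing them matters
  for computation.  An all-positive W is dominated by its Perron mode
  (eigenvalue 1 after scaling, eigenvector nearly uniform), while the rest
  of its spectrum is confined to a disk of radius ~ sqrt(1/(3N)) ~ 0.03 at
  N = 500.  All-positive input weights would project the input almost
  entirely onto that single Perron channel; signed weights spread it across
  the bulk modes and roughly double the usable rank of the state matrix.

### A structural limitation worth knowing

The Perron-dominated spectrum is also a hard ceiling on free-run prediction
accuracy.  The bulk radius ~ 0.03 means every non-mean-field mode forgets
its excitation within a single step: the network effectively carries one
scalar memory channel plus instantaneous nonlinear features.  Closed-loop
(output-fed-back) MG prediction over a 35-step horizon therefore saturates
around NMSE ~ 0.1 at the optimum instead of the much smaller errors a
conventional signed-weight echo-state network reaches (a control experiment
with W uniform [-1, 1] at unit spectral radius, all else identical, reaches
NMSE ~ 1e-7 at mu = 0.9 — but has no regular windows beyond mu ~ 1.1).
Window structure and high-accuracy free-running prediction pull the weight
spectrum in opposite directions; this package keeps the window-reproducing
convention and reports prediction accuracy as it actually comes out.  The
*relative* structure survives and is what the trend tests assert: NMSE and
sigma_alpha0 co-vary across mu, both drop inside the regular windows, and
the chaotic gaps are orders of magnitude worse.

## Teacher signal

The MG series is generated by the discrete map

    y[n+1] = y[n] + dt * ( 0.2 y_tau / (1 + y_tau^10) - 0.1 y[n] ),

with delay tau_m = 17, step dt = 1/10 (so the delay buffer holds 170
iterates), keeping every 10th iterate: one retained sample = 1 MG time
unit, making the 35-step prediction horizon twice the MG delay.  The delay
buffer is initialized to the constant 1.2 and the first 1000 retained
samples are discarded as transient; both are conventional choices for this
benchmark.  The retained block is shifted by its own mean so the teacher
oscillates around zero (required by the tanh output layer, and centering is
idempotent).  The series is strictly positive and bounded in (0, 2) before
centering; histories at the map's fixed points 0 and 1 are conserved
exactly, which the tests use as oracles.

## Training and evaluation

* Teacher forcing: the update producing state row t consumes teacher sample
  t-1; the readout target for row t is sample t.  Training uses 2000
  samples with alpha = 0.8; the first 100 rows (washout) are excluded from
  the regression to remove initial-state bias.
* The readout y_out = tanh(w_out . x) is linear-in-parameters after the
  exact substitution z = atanh(y) (valid since |y| < 1); w_out solves
  min ||X w - z|| by SVD pseudoinverse (`lstsq` at its machine-epsilon
  scaled cutoff; no ridge term).  The effective rank is reported.
* Closed loop: after the training block the input is replaced by the
  network's own output, scaled by alpha like the teacher was, for a 35-step
  free run; the NMSE (mean squared error over the whole horizon, normalized
  by the truth's population variance) is the performance figure.  Output
  saturation (|y_out| > 0.999) for more than half the horizon raises a
  `diverged` flag without suppressing the NMSE.
* sigma_alpha0: from the post-training state the network runs with the
  input off (alpha = 0); the first 10 output samples are discarded and the
  variance of the remaining 25 is compared to the aligned teacher window as
  [sigma(y_out)/sigma(y)]^2.  Values near zero mean learning has silenced
  the spontaneous dynamics in the output.

## Diagnostics

* **Synchronization error** delta_n = std_over_nodes(x_n) / mu.  The mean
  field is subtracted by construction, so a common shift of all nodes
  leaves delta unchanged; scaling all states by c scales delta by c.
* **Embedding parameters.**  Lag: first local minimum of the lagged self
  MI (32-bin histogram estimator); lag 1 is accepted when the curve is
  already at its floor, as for white noise.  Dimension: Kennel
  false-nearest-neighbors with R_tol = 15, A_tol = 2, threshold 1%,
  Theiler exclusion of one delay, in the multiplicative form
  `extra > rtol * d` so exact-recurrence neighbors (periodic data) are
  counted true; pairs whose lifted distance is below 1e-12 of the attractor
  size are rounding artifacts and are never false.  On the default MG
  series these give lag 12 and dimension 3 (the noise-free discrete-map
  attractor unfolds one dimension earlier than the conventional quote of 4
  for this system; the acceptance band covers both).
* **Maximal Lyapunov exponent** (Rosenstein).  Embed, find each point's
  nearest neighbor outside a Theiler window of delay*dim, average the log
  pair separation as both trajectories advance, and fit the slope over
  steps (1, max(2*delay, 5)).  The divergence curve of delay-embedded
  oscillatory signals ripples with period ~ the embedding delay; the
  two-delay fit window averages a whole number of ripples, which is why it
  is the default (a shorter window aliases the ripple into the slope).
  Validated against the logistic map (ln 2 within a few percent); on the
  default MG series it gives ~ 3.9e-3 per step.  Flat divergence curves
  (periodic signals), constant series and neighbor-starved inputs return
  `valid = False` rather than a number.
* **Network exponent**: the maximum of per-node estimates.  Nodes are
  strongly synchronized, so per-node values are nearly identical; the
  default evaluates a seeded sample of 32 nodes to keep mu-scans at
  desk scale (all nodes: `node_sample=None`).  For autonomous runs the
  embedding delay is re-estimated per mu, since autonomous timescales
  differ from the teacher's.
* **Regime classification.**  Peak-to-peak amplitude below 1e-6 * mu is a
  fixed point.  Given a valid Lyapunov estimate, lambda_max <= 0.005
  (slack for estimator bias) is periodic, larger is chaotic, and an invalid
  fit on a large-amplitude signal is flagged hyper-chaotic.  Dense
  bifurcation scans instead use an exact-recurrence test (some period
  p <= 80 matching to 1e-3 of the amplitude over the sample block), which
  is orders of magnitude cheaper and exact for the post-transient
  deterministic trajectories being classified.
* **Mutual information / capacity.**  Plug-in equal-width 2-D histogram,
  32 x 32 bins over the observed ranges, in bits; no bias correction, which
  keeps the discrete-table oracles exact.  The price is a positive bias
  floor of about (bins-1)^2 / (2 n ln 2) bits per pair — ~ 0.37 bits at
  n = 1900 — which is what survives when the input is shuffled; shuffling
  removes the genuine information but not the floor.  C is the sum of
  same-time per-node MI with the aligned input (lagged variants are a
  different quantity and out of scope).

## Scans

A scan evaluates a mu grid times `n_realizations` weight seeds; the MG
teacher is generated once (it is deterministic — only the weights vary).
Per-cell seeds derive from `SeedSequence([base_seed, mu_index,
realization])`, so refining a grid never reshuffles existing cells, and the
whole scan is reproducible from `base_seed`.  Cell failures are recorded in
the row rather than aborting the scan.  Summaries report per-mu mean,
standard deviation and standard error.  Default averaging depth is 10
realizations (a desk-scale choice; the study conditions quote 100 — pass
`n_realizations=100` for the full profile).

Windows are maximal runs of consecutive non-chaotic grid points, reported
as closed mu intervals.  Runs narrower than `min_width` grid points
(default 2) are below the scan's resolution and are dropped — the scans
genuinely contain, e.g., a single-grid-point period-3 window near mu = 2.9
that a 0.1-resolution window list should not promote to a "region".  On the
coarse trend grids (step 0.4) the narrow third window itself spans one
point, so trend analyses use `min_width=1` there.

## Synthetic data: what it does and does not emulate

Everything in this study is synthetic by construction — the teacher is the
MG map, the networks are seeded random draws — so the tests probe the
method, not data quality.  What the generator does *not* emulate:
measurement noise (the MG series is noise-free, which is why the FNN
criterion resolves one dimension lower than the noisy-data convention),
continuous-time MG integration (only the discrete map), and
hardware imperfections of physical reservoirs.  Conclusions about
robustness to noisy teachers cannot be drawn from these tests.

## Numerical choices and degenerate inputs

Centering is exact to rounding; constant series center to ~ 1e-16, and
assertions use tolerances accordingly.  NMSE and sigma_alpha0 refuse
zero-variance references.  The sync error refuses mu = 0 (the
normalization is undefined).  MI returns exactly 0 for constant inputs.
`MGConfig` rejects non-integer delay-buffer lengths; the generator raises
with the failing iteration index on divergence, as does the network
update on NaN states.

## Known limitations

* Free-run NMSE magnitudes are structurally limited by the Perron-dominated
  weight spectrum (see above); only the mu-dependence is meaningful.
* Hyper-chaos is flagged, never quantified (no second exponent).
* The bifurcation windows R4/R5 at mu > 12 are outside the scanned ranges;
  they are reported to destabilize under perturbation and are not analyzed.
* The plug-in MI bias floor makes capacity values comparable only at fixed
  sample count and bin count.
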
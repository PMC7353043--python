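# Methods

`sparkdrop` quantifies the responses of a droplet-forming PKA-activity
biosensor (SPARK-type reporter) in time-lapse fluorescence movies, and
validates the whole measurement chain on synthetic data whose ground truth
is known exactly. This note documents the models, the parameters that
matter, and the limits of what the synthetic validation shows.

## The measurement problem

A SPARK-type reporter diffuses evenly through the cytoplasm and, upon
PKA-dependent phosphorylation, phase-separates into bright fluorescent
droplets. Droplet formation is therefore a binary, per-cell readout of
PKA activation, and the population statistic of interest is the **share of
responding cells**:

    share = 100 x (gated cells forming droplets after stimulation)
                / (gated cells)

where *gated* means the biosensor expression exceeds a threshold below
which droplet formation could not be detected anyway. Shares are computed
per replicate field and summarized as mean ± SE across replicates.

## Synthetic population (ground truth)

A field contains `n_cells` non-overlapping disk-shaped cells
(rejection-sampled placement) with log-normal biosensor expression
`E_i ~ LogNormal(mu=log 300, sigma=0.4)` (arbitrary fluorescence units).
Population structure:

- A fraction `frac_capable` (default 0.482) possesses adenylyl cyclase and
  can respond to receptor agonists and to forskolin.
- A fraction `frac_pka_responsive` (default 0.912) responds to a direct PKA
  activator (6-Bnz-cAMP style), regardless of adenylyl-cyclase status.
- Each hormone has a responder set of exactly `round_half_up(n x f)` cells.
  In the default **nested** mode the sets are prefixes of one shuffle of
  the capable cells (largest responder set first), so the hormone-responsive
  subpopulations coincide up to an optional epsilon — the structure implied
  by sequential-stimulation experiments in which a second hormone activates
  almost only cells the first one already activated. An **independent**
  mode draws each set independently within the capable subset.

Set sizes are deterministic (seeded shuffle, round-half-up) so the
roster-level share is exact and every recovery error observed downstream is
attributable to imaging and analysis, not to sampling of the roster.

The default five-hormone panel uses the responder fractions
adenosine 0.370, noradrenaline 0.347, dopamine 0.252, serotonin 0.166,
histamine 0.042; the first three respond with strong transient kinetics
(amplitude mean 1.0), the last two with weak sustained kinetics (amplitude
mean 0.25, i.e. 0.25x the transient mean). Amplitudes are log-normal with
CV 0.3.

## Latent kinetics

Per cell and stimulus, PKA activity `a(t)` follows an archetype law:

- transient: `A (exp(-t/tau_d) - exp(-t/tau_r))`, tau_r = 0.5 min,
  tau_d = 5 min — a strong, short-lived pulse;
- sustained: `A (1 - exp(-t/tau_rs))`, tau_rs = 3 min — a weak plateau that
  lasts until wash-off;
- dissolving: no activity; pre-existing droplets dissolve (below).

Droplet mass `D(t)` integrates (forward Euler, dt = 0.05 min)

    dD/dt = k_on * max(a - theta, 0) * max(1 - D / C(a), 0) - k_off * D
    C(a)  = d_max * clip((a - theta) / a_ref, 0, 1)

with `k_on = 5 /min`, nucleation threshold `theta = 0.05`, capacity scale
`d_max = 9` mass units, `a_ref = 0.4`, and disassembly
`k_off = ln2/45 /min` (half-life 45 min — droplet disassembly is slow and
droplets partially persist at least 30 min after wash; the constructor
rejects any `k_off` implying a half-life under 30 min). The dissolving
archetype adds `-k_diss * D` (k_diss = 0.5 /min) from its stimulus onward.
A wash event zeroes all activity but leaves `D` decaying at `k_off`.

The capacity term `C(a)` is the package's key modelling choice: only the
phosphorylated reporter fraction can condense, and that fraction tracks
current kinase activity. Without it, mass is the time-integral of activity
and a weak 20-minute plateau accumulates *more* droplet mass than a strong
transient pulse — the opposite of the observed "strong and transitory"
versus "long but weak" contrast. With it, a weak sustained stimulus holds
a low droplet mass indefinitely while a strong pulse reaches a high mass
quickly; halving dt changes endpoint masses by well under 1%.

## Rendering

Each cell renders as a uniform disk of `E_i x photon_scale` counts over a
`background_level` of 100 counts. Droplet mass becomes
`N_i(t) ~ Poisson(D_i(t) / mass_per_punctum)` Gaussian puncta
(sigma 1.1 px, footprint capped at `droplet_unit_area` = 12 px^2) at
positions drawn once per cell and reused in seniority order, so droplet
patterns are temporally coherent. The per-frame count is produced by
inverting the Poisson CDF at one fixed uniform variate per cell (common
random numbers): each frame's count is marginally Poisson, and the count
trace is comonotone with the latent mass trace — real droplets do not
blink in and out between frames, and independent redraws would add
`sqrt(D) x punctum_area` of artificial flicker to every area trace.

Punctum peak brightness is `E_i x droplet_intensity_gain` (gain 0.35):
droplet visibility scales with biosensor expression, which is what creates
the detection floor — at default optics (Gaussian read noise, SD 3 counts),
puncta of cells with `E_i` below ~65 counts are indistinguishable from
noise. Frames are clipped to the 16-bit range and quantized.

Not emulated: cell migration, division and shape change; photobleaching,
focus drift, stage jitter; photon shot noise (read noise only); the 6x6
large-image tiling of a real acquisition (a single field stands in);
non-disk morphologies and touching cells. Passing the recovery tests
therefore shows the analysis chain is unbiased under these idealized
conditions; it does not certify segmentation or tracking performance on
real movies, where cell boundaries and motion dominate the error budget.

## Image analysis

1. **Background subtraction** — the classical rolling-ball estimate:
   background = grayscale opening of the frame with a flat disk, output =
   frame − background (white top-hat, everywhere >= 0). The ball must be
   larger than a punctum and fit inside a cell (radius below the cell
   radius), so the cell body and shading are absorbed into the background
   and only the puncta survive. Defaults: radius 10 px for radius-15
   demo cells, 5 px for the radius-10 replicate-field cells. On discrete
   grids the opening leaves isolated 1–2 px rim pixels at plateau height
   for *any* ball/cell radius pair; these fall below the minimum droplet
   area and are filtered.
2. **Segmentation** — threshold the pre-stimulus baseline frame at
   `median + 6 x 1.4826 x MAD` (robust background statistics; valid while
   cells cover a minority of pixels), 8-connected components above
   `min_cell_area` become cells. Masks are reused for all frames (cells
   are stationary by construction). `B_c` = mean baseline intensity minus
   the frame median — an expression proxy proportional to `E_i`.
3. **Expression gating** — keep cells with `B_c` above a threshold
   (default 65 counts, matching the default detection floor; a percentile
   mode is available). Gating is monotone in the threshold.
4. **Droplet detection** — within each gated cell, droplet pixels exceed
   `median + 6 x MAD` of the cell's background-subtracted pixels (the
   median matters: the opening rides the noise lower envelope, offsetting
   the residual by a few counts). 8-connected components of >= 4 px become
   droplets; droplets never cross cell boundaries. On droplet-free cells
   the false-positive rate is below 1 droplet per 100 cell-frames.
5. **SPARK statistics** — per cell and frame:
   `intensity_ratio` (droplet-pixel intensity over total cell intensity on
   the raw frame, droplet pixels from a raw-frame `median + 3 x MAD`
   cutoff), `sd` (within-cell intensity SD, raw frame), and `area` (total
   droplet area on the subtracted frame). Traces can be normalized to
   their maximum or to their t=0 value (fold-change "contrast"; the area
   statistic's zero baseline takes a 1 px^2 epsilon floor). The area
   statistic has the lowest max-normalized resting level and the highest
   contrast of the three, and is the default for responder calling.

## Responder calling

For each stimulus the baseline is the mean statistic over the 6 min window
ending at the stimulus; the baseline window is re-anchored before *each*
stimulus of a sequential protocol because droplets persist through washes.
A cell responds if its trace exceeds

    baseline + max(abs_min_rise, k_resp x noise)

for at least `min_frames = 3` consecutive frames, with `abs_min_rise =
8 px^2` (two minimum-size droplets), `k_resp = 5`, and `noise` the
1.4826xMAD of the baseline window (a droplet-laden baseline steps by whole
puncta when mass crosses a count boundary; a plain SD would inflate the
margin and mask genuine re-stimulation). A *dissolving* call — the trace
falling below `baseline − margin` — is only possible when the baseline
itself exceeds `abs_min_rise` (there must be droplets to dissolve), and is
never counted as droplet formation in shares.

**Archetype.** Droplet disassembly has a >= 30 min half-life, so a
transient response cannot return to half its amplitude within a movie;
the half-return rule familiar from fast reporters is unusable here.
Instead, a responder is *transient* if its smoothed trace (3-frame moving
average) falls below `baseline + 0.88 x amplitude` within 15 min of the
peak, and *sustained* otherwise. The 0.88 cut sits midway between the
expected 15-min retention of a decaying transient (exp(−15·ln2/45) ≈ 0.79)
and the ≈0.97 retention of a still-integrating sustained response. With
~5–9 puncta per cell the area trace is quantized in ~12 px^2 steps, which
caps per-cell archetype accuracy near 70–80% at replicate-field geometry;
population shares are unaffected, and the population-median amplitude of
sustained responders remains clearly below that of transient responders.

## Population summaries

- `population_share`: share per replicate field, mean ± SE (sample SD /
  sqrt(R)) across replicates; empty replicates are excluded with a warning.
- `sequential_overlap`: per stimulus, responders, *new* responders (no
  response to any earlier stimulus) and the cumulative union share, on the
  cells gated in every stimulus. In nested mode the union equals the
  largest single share and new responders ≈ 0.
- `clone_summary`: per-clone shares with the clone as the replicate unit,
  plus the grand mean ± SE.

Known limitation: a second stimulus on already-droplet-laden cells is
called conservatively (the cell is near droplet capacity, so the
measurable rise is small); in the nested emulation only ~20% of cells are
re-called against a 34.7% single-stimulus share. Overlap conclusions (new
responders, union share) do not depend on re-calls and are unaffected.

## Adenylyl-cyclase census

On a sparse gene x cell count matrix, the census counts cells with zero
counts across *every* gene of a named set (default ADCY1–ADCY10 /
Adcy1–Adcy10). "Lacking expression" means count == 0, not a low-count
threshold, mirroring a presence filter on transcripts. Percentages are
rounded half-up to one decimal. The synthetic matrix generator plants an
exact all-zero fraction (round-half-up) and guarantees every other cell at
least one count on the set (zero-inflated Poisson per gene), so census
arithmetic is testable exactly; background genes are Poisson noise.
Human/mouse symbol dialects are bridged by a case-insensitive match mode.

## Problem sizes

Replicate-field recoveries use 704x704 px fields of 250 radius-10 cells
imaged every 2 min for 30 min (16 frames), with a 5 px ball radius — large
enough that the deterministic roster dominates the error budget (recovered
shares land within ~0.5 points of the planted fraction) and small enough
to run on a desk machine in a few seconds per field. Demo geometry is a
512x512 field of radius-15 cells at 1 min intervals. Clone analyses use 7
fields of 36–44 cells; the size spread makes per-clone shares differ, as
they do between real clones.
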
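# Methods

## Scope

`furrownet` models and quantifies cortical myosin II dynamics at the
invagination front of the cellularizing *Drosophila* embryo.  It has two
halves that meet in the middle:

1. a stochastic contractile-network simulation on a hexagonal furrow
   lattice, able to reproduce both the wild-type regime (anisotropic flow,
   interconnected network) and the *dunk*-mutant regime (misdirected flow,
   rupture, myosin accumulation at vertices), and
2. the live-imaging quantification pipeline applied to such movies:
   synthetic confocal rendering, particle image velocimetry, kymographs,
   laser-ablation recoil analysis, vertex/edge intensity partitioning,
   band-width measurement, edge-length–intensity correlation and FRAP
   half-recovery estimation.

Because the pipeline's inputs are synthesized with known ground truth, every
analysis stage can be validated end to end without any microscope data.

## The contractile-network model

### State

Myosin nodes are point particles in the plane (µm), threaded on bundles of
`fibers_per_edge` = 3 parallel fibers that run along each edge of a regular
hexagonal template (edge length L = 6 µm, the order of internuclear
spacing).  Each fiber carries `nodes_per_fiber` = 11 equispaced nodes; the
fiber rows span an initial band of width w₀ = 2 µm, reflecting the broad
meshwork-like appearance of the cortex at the onset of cellularization.
One anchor node sits at every lattice vertex; fibers are bonded
consecutively along their length, to the vertex anchors at both ends, and
to the neighbouring row at matching positions (rungs).  Total capacity
N_max is fixed at the seeded count; dead slots are reused.

Interfaces (bonds) are *persistent*: they represent the fiber segment and
crosslink between two specific neighbouring nodes, not a geometric
proximity relation.  The invariant that an interface joins two alive nodes
at distance ≤ r_c is maintained by stretch rupture (below).

### Forces and integration

Each interface carries a constant active tension T (motor tension is
strain-independent to first order):

    F_i = T · Σ_j unit(x_j − x_i),   over interface partners j,

with pairs closer than the contact distance d_min = 0.2 µm contributing
nothing (prevents collapse and oscillation at contact).  Positions follow
overdamped explicit Euler, x ← x + µ·F, with µ·T = 0.005 µm/step.  The
integrator is stable for µ·T ≤ 0.2·d_min, which `SimParams` enforces.
Minimizing total interface length is the energy interpretation of this
force law; with turnover disabled, total interface length is monotonically
non-increasing (tested).

An early design used an interface graph rebuilt every step from an
interaction radius.  That variant is a neighbour-counting dynamical system:
with constant-magnitude attraction, any density fluctuation pulls more
partners from the denser side, and every edge band deterministically
coarsens into isolated clumps — even without turnover, and at any k_on.
The persistent-fiber topology removes this instability while keeping the
same force law and interface invariants.

### Turnover

Per step, each alive node dies with probability k_off, and the number of
recruits is drawn as B ~ Binomial(N_max − N_alive, k_on), so the occupied
fraction of turnover-eligible slots follows a two-state Markov chain with
stationary value k_on/(k_on + k_off) (tested to ±0.01).

Three rules couple turnover to network integrity, and their interplay is
what separates the two regimes:

* **Crosslink inheritance.**  When a node dies, the fiber ends it held can
  stay joined if another myosin engages before they slip apart.  For each
  pair of former partners at distance d (a spanning tree over the partner
  set, shortest pairs first), inheritance succeeds with probability
  1 − (1 − k_on)^m, where m = (r_c − d)/(µT) is the number of steps a
  mesh-held end needs to slip beyond the interaction radius.  This is a
  pure re-engagement-versus-slippage race with no free parameters.  Links
  to the vertex anchors always survive: the fiber terminates *at* the
  junction, so that attachment is structural, not myosin-limited.
* **Severed-pair repair.**  Failed inheritances are tracked as exposed
  fiber ends for as long as they remain within r_c and within their
  slippage window m; afterwards the ends have frayed and the break is
  permanent.  Recruits bind at the midpoint (plus isotropic Gaussian
  jitter, σ = d_min) of an interface or severed pair chosen with
  probability ∝ max(d − ℓ₀, 0) + ε, where ℓ₀ = 0.75 µm is the exposed
  length needed to present a binding site and ε = 10⁻⁴ a small basal
  weight.  Severed gaps and stretched interfaces are therefore repaired
  preferentially; fully ruptured regions present no interfaces at all and
  can never be repopulated.
* **Stretch rupture.**  Interfaces stretched beyond r_c = 1.6 µm snap.

With the wild-type rates (k_on, k_off) = (0.05, 0.001), breaks are
reconnected promptly: over 5 seeds × 8000 steps on a 3×3 lattice, every
edge retains middle-third occupancy at every recorded snapshot and the
interface graph remains a single connected component, while the band
narrows perpendicular to each edge.  With the mutant-like rates
(0.003, 0.001), reconnection loses the race; 55–75% of edges rupture by
step 8000 and the nodes reel into discrete foci centred at the vertices.

Vertex anchor nodes are exempt from turnover by default
(`vertex_turnover=False`): they stand for the tri-cellular junction
complexes where three furrows meet, not for individual myosin puncta.
Outermost lattice vertices are additionally pinned (zero mobility),
emulating the surrounding embryo cortex.

### Parameter summary

| parameter | default | units | meaning |
|---|---|---|---|
| k_on | 0.05 | /step/slot | recruitment probability per vacant slot |
| k_off | 0.001 | /step/node | dissociation probability |
| T·µ | 0.005 | µm/step | displacement of a singly pulled node |
| r_c | 1.6 | µm | interaction radius / rupture threshold |
| d_min | 0.2 | µm | contact distance (zero-force core, jitter σ) |
| L | 6 | µm | hexagon edge length |
| n_f × n_per | 3 × 11 | – | fibers per edge × nodes per fiber |
| w₀ | 2 | µm | initial band width |
| ℓ₀ | 0.75 | µm | exposed length presenting a binding site |
| ε | 10⁻⁴ | – | basal binding weight |
| n_steps | 8000 | steps | preset run length |

The presets (0.05, 0.001) and (0.003, 0.001) at 8000 steps define the two
regimes.  Geometry and rate defaults were fixed by requiring that the
high-k_on network remain fully intact and the low-k_on network rupture on
a majority of edges across seeds, before any acceptance quantity was
measured; they are conditions of the study, not tuning knobs.

### In-silico ablation

`ablate` removes every alive node strictly within a radius of an edge
midpoint, together with its interfaces.  The surviving chain ends are
unbalanced and retract away from the incision; because the chains run
along the cut edge, the recoil field is anisotropic with the parallel
component dominating, and with T = 0 no recoil occurs.  Both behaviours
are read out by PIV on rendered movies in the test suite.

## Synthetic microscopy

Nodes render as isotropic 2-D Gaussians (peak amplitude 100 counts,
σ_PSF = 0.1 µm ≈ the diffraction limit of a 63×/1.3 NA objective at GFP
emission) on a 0.096 µm pixel grid, one frame per recorded snapshot
(default every 200 steps; 12 s nominal frame interval).  Optional
Gaussian or Poisson noise is applied last; acquisition photobleaching is
off by default (the imaging protocol it emulates was chosen to avoid it).

Self-contained generators provide ground-truthed movies for each analysis:

* **Recruitment phase** — static nodes at uniform arc-length spacing along
  all edges, per-node amplitude growing linearly; the true vertex/edge
  ratio is 1 at all frames and total intensity rises strictly.
* **FRAP** — the cortical band (five node rows across 1 µm, matching the
  width of the invagination front) is static; a constant cytoplasmic
  background at 30% of the cortical peak is present in every z-slice (the
  cytoplasmic pool is treated as unbleachable and instantly mixing).  At
  the bleach frame the cortical fluorescence inside the bleach rectangle
  is zeroed and recovers per site as 1 − exp(−k_ex·Δt); signal is
  distributed over six 1-µm z-sections with a fixed Gaussian axial
  profile, frames every 2.35 s.  Ground truth t½ = ln 2 / k_ex.
* **Translation oracle** — a band-limited random texture (Gaussian
  spectral envelope, σ = 1 px, which makes the correlation peak ideally
  conditioned for 3-point subpixel fits) rigidly translated by an exact
  Fourier shift with periodic wrap; the applied shift is the PIV oracle.

What these generators deliberately do not emulate: 3-D PSF and
deconvolution artefacts, camera-specific noise, nuclei/membrane
structures, furrow ingression along z, or stage drift.  Passing tests
therefore demonstrate correctness of the analysis pipeline on movies whose
physics matches the model assumptions, not robustness to every real-world
imaging artefact.

## Quantification pipeline

* **PIV** — 32×32 px interrogation windows on an 8 px grid; mean-subtracted
  zero-padded FFT cross-correlation, normalized and compensated for the
  shrinking overlap at non-zero lag (which otherwise biases peaks toward
  zero); 3-point Gaussian subpixel fit per axis; vectors with
  first-to-second peak ratio < 1.2 (second peak outside a 5×5 exclusion
  zone) are flagged invalid and excluded from averages.  Verified to
  ≤ 0.2 px on noise-free integer shifts in [−5, 5]² and ≤ 0.5 px median at
  SNR 5.
* **Kymographs** — bilinear sampling along a line at one-pixel spacing,
  averaged across the stated width; time-reversal equals row reversal.
* **Recoil** — PIV between the last pre-cut and first post-cut frames;
  reports box-averaged |V_parallel| and |V_perpendicular| relative to the
  ablated edge axis, an outwardness score (mean cosine between velocity
  and the outward radial direction from the cut), and a pre-cut baseline
  speed; replicate cuts average via `average_recoil`.
* **Vertex/edge partition** — cell outline polygons (known synthetic
  geometry) resampled at ≤ pixel-size spacing; points within R_v = 1.2 µm
  of the nearest polygon corner are "vertex", the rest "edge"; intensity
  is integrated across a w_s = 0.6 µm line width by bilinear sampling on a
  half-pixel grid.  The ratio of class means is the vertex/edge ratio
  (NaN sentinel when the edge class is empty).
* **Band width** — FWHM of the background-subtracted intensity profile
  perpendicular to an edge, averaged along the middle third of the edge;
  a moment-based Gaussian σ is recorded alongside.  Undefined (NaN) when
  the peak does not exceed background.
* **Edge length vs intensity** — Pearson r per frame between realized edge
  lengths and mean edge intensity sampled between the effective corners
  (vertex caps of R_v excluded).  Realized geometry takes each template
  vertex to the centroid of alive nodes within 1.5 µm, so that contracted
  (myosin-rich) edges shorten and ruptured (myosin-poor) edges stretch —
  the negative correlation of the rupture regime.
* **FRAP analysis** — background = 50% of the cytoplasmic level is
  subtracted per pixel (50% rather than 100% so the earliest cortical
  recovery is not clipped); z-slices are combined by a weighted sum with
  per-frame weights ∝ the background-corrected control-region signal;
  region series are min-max normalized to [0, 1] (the bleached region
  recovers nearly fully, anchoring the plateau at 1); the ratio used for
  thresholding is formed from the raw series *before* normalization and
  then min-max scaled, so any per-frame gain common to the whole stack
  cancels exactly.  t½ is the first time the ratio reaches 0.5, linearly
  interpolated between frames (the frame-quantized crossing is stored
  alongside); a 3-frame moving average guards the first-crossing rule
  against single-frame noise spikes.  A min-max guard rescales
  near-constant series (range < 5% of scale) by their pre-bleach mean,
  since min-max of pure noise is meaningless.

## Numerical choices and degenerate inputs

* Determinism: one seeded `numpy` Generator per run; all set iterations go
  through `sorted()`; identical seed + parameters give bitwise-identical
  trajectories.
* Sentinels: +inf for the vertex/edge density ratio with empty strips,
  NaN for undefined ratio / band width / t½; empty states raise.
* Tie-breaks: recruitment slot = lowest free index; spanning-tree
  inheritance adds shortest pairs first; argmax ties resolve to the first
  (smallest-displacement) index.
* `network_metrics` reports both the per-area density ratio (discs of
  radius R_v versus edge strips of width 2 R_v) and a per-arc-length
  `line_ratio`; the latter is the one commensurate with intensity
  quantification, because area normalization over-weights strips relative
  to discs by ×1.9 for outline-concentrated distributions.

## Problem sizes

Default study conditions: 3×3 lattice (38 edges, ~1290 nodes), 8000 steps,
41 rendered frames at 0.096 µm/px (~350×320 px); FRAP movies 1×2-hexagon
field, six z-slices, 2.35 s frames to 5 half-times post-bleach.  A full
regime run with rendering and quantification takes ~30 s on one CPU; the
whole acceptance recomputation (3 seeds per regime, 5 seeds per FRAP
scenario) runs in a few minutes.

## Known limitations

* The model is 2-D and ignores furrow ingression mechanics, nuclei,
  membrane and the basal ring-constriction phase.
* k_on/k_off are per-step probabilities of an abstract binding-site pool;
  they are not the FRAP exchange rate (the two regimes share the same
  FRAP half-time by construction, matching the observation that cortical
  exchange is unchanged in the mutant).
* The crosslink-inheritance race and severed-pair bookkeeping are
  mesoscopic closures for unresolved fiber mechanics; their functional
  forms are the simplest ones expressible in the model's own quantities.
* Quantification operates on known synthetic geometry; segmentation of
  real movies is out of scope.
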
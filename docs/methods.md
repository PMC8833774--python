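# Methods

## System and data model

A 40-bp DNA duplex carries an ¹²⁵I atom in base 0, offset 0.15 nm toward
strand 0 (the iodine-proximal strand; "strand 1" in the experimental
literature is strand 0 here, stated once and used everywhere).  Each decay
releases an Auger-electron cascade whose interactions are scored per decay
as (strand, base, energy) energy-deposition records inside backbone
volumes, plus (strand, base) records of OH radicals scavenged at the
strand.  Decays that deposit nothing still count: datasets carry an
explicit decay count, and the event-file format preserves it in a comment
header because empty decays have no rows.

## Synthetic generator — what it emulates, and what it does not

The generator replaces the transport and chemistry codes with their net
per-base observables:

* **Interaction counts** per (decay, strand, base) are Poisson with mean
  `λ_i = a·(i+1)^−k + b` per strand (defaults `a = 1.507`, `k = 1.5`,
  `b = 0.01`).  The constants are fixed so that ~5% of decays deposit a
  non-zero amount of energy in base 10, an anchor typical of scored
  Geant4-DNA-like data; the power law reproduces steep proximal dominance
  with three interpretable constants.  The count law is a maximum-entropy
  default — real counts emerge from transport physics — and the damage
  layer is agnostic to it.  `count_law="fixed"` (exactly `round(λ)`
  interactions) expresses degenerate deterministic worlds for testing.
* **Interaction energies** are i.i.d. from a mixture: a uniform continuum
  on (0.25, 12] eV (weight 0.60) plus narrow Gaussian peaks at 17 eV
  (0.15) and 32 eV (0.25), σ = 0.3 eV, mimicking the discrete ionisation
  energies of water on top of a low-energy background.  The mixture mean is
  14.2 eV, i.e. ~14.6 eV per depositing decay at base 10.  These weights
  are illustrative, not a fit to any transport code.  Deposits below
  0.25 eV (vibrational/quasi-elastic, <1% of deposited energy in real
  spectra) are not generated; histograms can flag them excluded on read.
* **OH hits** are Poisson with `μ_i = 0.05·(i+1)^−0.5 + 0.01`, decaying
  more slowly than the physical rate because radicals diffuse before
  scavenging.  No diffusion–reaction kinetics are simulated; the chemistry
  stage is replaced by its net observable (scavenged hits per base), which
  is all the damage model consumes.

What a green test on this world establishes: the *estimation machinery*
(break calling, fragment statistics, inversion, grid fitting) behaves
correctly on data with the right sparsity, spatial decay and spectral
structure.  What it does not establish: agreement with any real transport
code's spectra, per-physics-list thresholds, or experimental yields —
reproducing published best-fit values requires the real scored data.

## Damage models

* **Direct threshold**: a site breaks iff the energy accumulated in its
  backbone volume during one decay is *strictly greater* than `e_thresh`
  (literal reading of "more than"; measure-zero effect on continuous
  energies, documented for reproducibility).
* **Direct window**: break probability 0 at/below `e_low`, rising linearly
  to 1 at `e_high`, one seeded uniform draw per candidate site.  Width 0 is
  the threshold model; (5, 37.5) eV is the classic literature window.
* **Indirect**: each scavenged OH breaks its site with probability `p_oh`,
  independently; n hits combine to `1 − (1 − p_oh)^n`.
* **DSB**: within one decay, opposite-strand breaks within `dsb_max_sep`
  bases (default 10) pair into DSBs.  Pairing scans strand-0 breaks from
  base 0 upward and takes the lowest-index unpaired strand-1 partner in
  range; for equal-width windows this two-pointer rule provably attains
  the maximum matching, so the count is pairing-order independent
  (verified against exhaustive matching).  A nearest-partner rule was
  rejected: it undercounts on patterns such as strand-0 {5, 16} vs
  strand-1 {0, 6}.
* Direct and indirect breaks at one site count once toward yields (direct
  wins the bookkeeping tag).  Each stochastic operation draws from its own
  RNG stream derived from (seed, operation tag), so direct and indirect
  calls are independent and reproducible from one master seed.

## Fragment statistics and the inversion

The assay detects, per decay, only the break most distant from the iodine
at sites up to the last measured position; more distant unmeasured breaks
cannot affect the observation and are ignored.  Distributions carry their
normalisation explicitly: `breaks_only` (over detected fragments — what a
gel measures) or `include_unbroken` (over all decays, with an unbroken
entry — what a simulation knows).

Forward model under independent per-site breaking:
`F_i = p_i · Π_{j>i}(1 − p_j)`, unbroken fraction `Π_j(1 − p_j)`.

Iterative correction (inverse): from the most distant site inward,
`p_i = f_i / (1 − Σ_{j>i} f_j)`, clipped to [0, 1].  On `include_unbroken`
data this inverts the forward model exactly (telescoping identity).  On
`breaks_only` data it is *degenerate*: the denominator at the innermost
occupied site equals that site's own fraction, so the corrected
probability there is always 1 — absolute yields are unrecoverable from
normalised fragment data.  Two profiles sharing a breaks-only fragment
distribution (a true profile and its pinned-at-1 inversion) are
indistinguishable to the assay despite very different total yields.

Numerics: the denominator is evaluated as
`(1 − total) + unbroken + Σ_{j≤i} f_j` accumulated from the iodine side,
which is algebraically identical but avoids the catastrophic cancellation
of `1 − (almost 1)` when distant sites carry nearly all the mass; the
round trip then holds to ~1e−15 even for profiles with joint survival
~1e−300.  An inconsistent distribution (inner mass left with no
probability budget) raises a degeneracy error naming the site.

## Fitting

Goodness of fit is `SSE = Σ_i (ln f_i − ln F_i)²` over site bins — squared
log residuals because the experimental fractions carry no uncertainties.
The log base is a global constant factor and cannot move the argmin;
natural log is used.  Bins where either distribution is zero are excluded
by default (log undefined) and the exclusion count is reported; a
pseudo-fraction floor `1/(10·n_events)` is available as an alternative
policy.  Whether the iodine-site bin is included is configurable through
the observed table itself; it is included by default.

Protocol: high-scavenging data (radicals quenched) are fitted with direct
damage alone, scanning `e_thresh` on a 10–40 eV grid in 0.25 eV steps;
low-scavenging data are fitted by freezing `e_thresh` at its
high-scavenging best fit and scanning `p_oh` on 0–1 in 0.01 steps.  One
event dataset is reused across grid points; stochastic calls re-seed
deterministically per grid point.  Ties in the argmin break toward the
lower parameter value.  The quoted uncertainty is half the grid step, and
`FitResult.values_within(2.0)` reports the grid values within twice the
minimum SSE — the breadth-of-minimum diagnostic.

### Identifiability — a deliberate, documented limitation

Because the fitted data are normalised, a threshold change that scales all
per-site break probabilities by a common factor is nearly invisible; the
information about the threshold comes from the spectral structure (the
peaks) and from multi-interaction pile-up at proximal bases.  In the
default two-peak mixture the band ≈(29.9, 31.4) eV — above the largest
17-peak+continuum sum and below the 32-peak tail — carries essentially
zero spectral density, so thresholds there produce *identical* break
calls and no estimator can localise a generating value of 29.5 eV to a
0.25 eV grid step from fragment data alone: measured SSE valleys are flat
from ~17.5 to ~31.4 eV with sharp walls at the ionisation peaks, and
recovered argmins cluster at the peak edges.  The corresponding acceptance
check is left failing at its stated tolerance rather than widened; the
window-median and `p_oh` fits, whose objectives vary smoothly with the
parameter, recover their generating values within one grid step.  The SSB
yield, by contrast, is *not* identified by fragment shape at all (the
non-identifiability tests construct matched-shape worlds whose yields
differ by >50%).

## Geometry

Bases occupy half-open 0.34 nm slabs along the helix axis; the base region
is the r < 0.5 nm cylinder; the backbone annulus (0.5 ≤ r < 1.15 nm) is
split per slab into two arcs of equal angular width (default 180°, i.e.
two semicircles), strand 0 centred on azimuth `i·36°` and strand 1
opposite, rotating one step per slab (ten bases per turn).  The arch
azimuthal extent is not fixed by the published construction; the
equal-arc model is a declared approximation and is configurable.  OH
scavenging applies strictly inside r < 1.65 nm.  Half-open intervals make
the classification an exact partition; classification agrees with an
independent re-implementation on random points and is periodic under
(θ + 36°, z + 0.34 nm) up to float rounding at region boundaries.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| `e_thresh` | 29.5 eV | direct-break threshold (strict) |
| `window` | none | linear-ramp alternative, e.g. (5, 37.5) eV |
| `p_oh` | 0.16 | per-OH-hit break probability |
| `dsb_max_sep` | 10 bp | maximum opposite-strand separation of a DSB |
| energy grid | 10–40 eV, 0.25 | threshold scan |
| `p_oh` grid | 0–1, 0.01 | indirect scan |
| `max_site` | 30 | last measured fragment class |
| half-life | 59.4 d | ¹²⁵I; 20 days ⇒ 20.8% decayed |

All pipeline tables are delimited text with a config-hash comment line;
identical configs produce byte-identical tables (placement-only settings
are excluded from the hash).  Figures are regenerated from exported table
contents only.
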
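# kymoquant

Kymograph-based quantification of two-channel axonal transport imaging,
with a seeded synthetic movie generator that ships ground truth for every
measurement.

## The problem

Trafficking studies in *C. elegans* neurons (and neurons generally) film
fluorescently tagged cargo moving along a neurite and reduce each movie to
a kymograph — a space–time image in which time runs downward, distance from
the cell body runs rightward, moving vesicles draw sloped lines and
stationary clusters draw vertical streaks. From annotated kymographs the
field derives a standard panel of quantities:

- **Co-migration.** With two spectrally distinct markers (e.g. an SV
  protein such as SNB-1 in one channel, RAB-3 or a lysosomal protein such
  as CTNS-1 in the other), moving vesicles are scored as A-only, B-only,
  or carrying both. The two summary statistics are

  ```text
  % co-migrating vesicles      = 100 · n_both / (n_A_only + n_B_only + n_both)
  fraction of A moving with B  =       n_both / (n_A_only + n_both)
  ```

  A small cargo whose signal is contained within a larger vesicle moving
  on an identical path counts as co-transported (containment rule).
- **Direction calling.** A moving vesicle's direction is the sign of its
  net displacement: ending farther from the cell body is anterograde,
  closer is retrograde; near-zero net displacement is excluded or assigned
  the direction of motion just before the trace ends.
- **Kinematics.** Per-trace mean speed (μm/s), segment run lengths between
  pauses and reversals, pause statistics, and anterograde flux normalized
  to a 20 μm × 10 s kymograph window.
- **Morphometry and distributions.** Vesicle length as the FWHM of the
  sloped line along the spatial axis inside random non-overlapping ROIs;
  penetrance (percent of animals with marker signal at or beyond 25/50/150
  μm from the cell body); percent of dendrite length showing signal;
  puncta per 10 μm; punctum/cytosol intensity ratios per cell body;
  background-subtracted intensity of moving trajectories (reference taken
  1 s earlier on the same path, 3 rows at 3 fps); microtubule polarity
  from anterograde/retrograde plus-end comet counts.
- **Statistics.** Shapiro–Wilk per group gates each comparison into
  Student's t / one-way ANOVA + Tukey (normal) or Mann–Whitney /
  Kruskal–Wallis + Dunn (otherwise), two-sided, α = 0.05.

Real microscope movies for these assays are rarely deposited, so the
package includes `kymoquant.simulate`: a generator of dual-channel neurite
movies (Markov run/pause/reverse advection, PSF-blurred finite-length
vesicles, Poisson + read noise, co-labelling probability, cell body,
stationary clusters) and static fixtures (cell-body puncta, neurite
profiles, dendrite extents) that export per-frame ground truth. Every
quantifier is validated as a recovery of the generating parameters.

## Worked example

The `demo` subcommand simulates a wild-type SNB-1/RAB-3 dual-channel
movie (80 vesicles, 3 min at 3 fps, co-labelling probability 0.35), builds
and synchronizes both kymographs, ingests the ground-truth traces, matches
moving traces across channels and applies the formulas:

```text
$ kymoquant demo --seed 1
co-migration result
  A-only moving vesicles : 33
  B-only moving vesicles : 16
  co-migrating (both)    : 21
  total moving vesicles  : 70
  % co-migrating         : 30.00
  fraction A with B      : 0.3889
  fraction B with A      : 0.5676
recovered fraction A with B: 0.389 (preset co-label probability 0.35)
```

Of the 70 moving vesicles in this movie, 21 carried both markers; the
recovered fraction of SNB-1 (channel A) vesicles co-transporting RAB-3
(channel B), 21/54 ≈ 0.39, estimates the preset co-labelling probability
0.35 with single-movie binomial noise. Averaged over 25 seeded movies the
estimate lands within a point or two of the preset (see below).

The same workflow is available as a library:

```python
import kymoquant as kq

cfg = kq.make_preset_config("WT_SNB1_RAB3", seed=1)
movie_a, movie_b, truth = kq.simulate_movie(cfg)
result, table = kq.run_comigration(
    movie_a, movie_b,
    traces_a=truth.trace_table("A"), traces_b=truth.trace_table("B"),
)
print(result.to_report())
```

Other subcommands: `simulate`, `kymo`, `trace`, `comigrate`, `quantify`,
`stats`. Each writes a `manifest.json` (command, config, input checksums,
seed, version) into its output directory.

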
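# Methods

## Scope and model overview

`lymphdsb` models internal *ex vivo* irradiation of whole blood in an
8 mL cylindrical vial containing 1000 lymphocytes (125 cells/mL),
each a 3.75 µm water sphere with a concentric 3.1 µm-radius water
nucleus as the only scoring volume. The chain is:

1. **Geometry** — random non-overlapping sphere packing in the vial;
   geometric constants of the sensitive-volume damage model.
2. **Phase space** — records of particles crossing each cell surface
   (the cells are cold sources: no decays inside them), translated to
   cell-local coordinates, merged into one total phase space, and
   stripped of anti-neutrinos.
3. **Track synthesis** — a seeded generator of energy-deposition
   event lists inside the nucleus that stands in for a
   track-structure physics engine.
4. **Damage scoring** — probabilistic strand-break sampling and
   DBSCAN clustering into SSB/DSB categories, per primary particle.
5. **Dosimetry** — per-decay energy tallies with history-by-history
   uncertainty, activity/dose conversions, the nucleus dose
   coefficient, DSB·cell⁻¹·mGy⁻¹.
6. **Alpha analysis** — track counting under detectability
   thresholds and the linear DSB density per µm of track.

## Geometry

The nominal vial is 7.2 mm radius × 49.12 mm height = 7.9996 mL;
`VialGeometry.check_volume` enforces consistency with a nominal label
to 1 %. Cell placement is rejection sampling: candidate centers are
drawn uniformly over the margin-shrunk cylinder (radial ≤ R − r_cell,
|z| ≤ H/2 − r_cell, so the wall constraint holds by construction) and
rejected only on overlap with accepted cells. At the nominal
occupancy the packing fraction is ~3×10⁻⁸ and rejections essentially
never occur; the per-cell attempt budget (default 10⁶) exists to turn
infeasible requests into a clear `PackingError`. Coordinates are µm,
right-handed, origin at the axis midpoint, z along the axis (the
upstream convention is unstated; this one is declared and used
throughout).

Sensitive-volume constants, with defaults and derivations:

| quantity | value | derivation |
|---|---|---|
| DNA cylinder volume | 8.27 µm³ | π (1.1 nm)² × 0.34 nm/bp × 6.4×10⁹ bp |
| DNA contour length | 2.176 m | 0.34 nm/bp × 6.4×10⁹ bp |
| nucleus volume | 124.79 µm³ | (4/3)π(3.1 µm)³ |
| nucleus cross-section | 30.19 µm² | π(3.1 µm)² |
| nucleus mass | 1.248×10⁻¹³ kg | volume × 1000 kg/m³ (water) |
| geometric sensitive fraction | 0.0663 → 7 % | DNA volume / nucleus volume |
| molecular DNA volume | 3.8 µm³ | (6.41+6.51)/2 pg ÷ 1.7 g/mL |
| molecular sensitive fraction | 0.0302 → 3 % | molecular volume / nucleus volume |

Percentages are reported with round-half-up to integer percent, with
the unrounded fraction always available. The nucleus mass is
sometimes quoted as 1.24×10⁻¹³ kg; our water-density value differs by
0.6 % and both are accepted within 1 % — the rounding convention
behind the shorter figure is unknown.

## Phase-space bookkeeping

Records carry name, kinetic energy (MeV), position (µm), unit
direction, statistical weight, event id and cell id; validation
enforces E ≥ 0, |direction| = 1 within 10⁻⁶ and weight > 0. The frame
(`vial` or `cell-local`) is explicit metadata, never inferred, and
translation guards against being applied twice. Merging requires
cell-local inputs with matching radionuclide and decay count; a
particle crossing several cells contributes one record per crossing —
each crossing is an independent source particle for the single-cell
simulation, with no deduplication. Anti-neutrino stripping matches a
case-insensitive name set (`anti_nu_e`, `nu_e_bar`, …) because
generator spellings vary. HDF5 files hold one `/phasespace` group
with a 1-D dataset per column and metadata as root attributes; CSV
uses the same columns with a `#` metadata line. Weights are carried
through; downstream tallies would multiply by weight (all defaults
are 1).

## Synthetic tracks

Primaries travel along straight chords: entry points uniform on the
nucleus surface, inward directions cosine-weighted (the flux law on
the surface of an isotropically irradiated sphere), kinetic energies
uniform over each model's range. For a surface point e and unit
direction d the chord is −2(e·d), at most the 6.2 µm diameter. The
alpha track length inside the nucleus is identified with this chord —
the straight-path idealization is the generator's main fidelity
limit, along with the absence of delta-ray geometry, scattering and
any chemistry stage. Depositions are a 1-D Poisson process along the
chord with linear density LET(E)/⟨E_dep⟩, where LET(E) interpolates a
user-editable two-column table (MeV → keV/µm) and deposition energies
are i.i.d. lognormal. Defaults:

* alpha: LET table spanning 60–230 keV/µm over 0.01–8.36 MeV with the
  Bragg-peak maximum near 0.7 MeV — a placeholder with the right
  order of magnitude for alphas in liquid water, not a calibrated
  stopping-power dataset;
* electron: fixed 0.5 depositions/µm (sparse low-LET plumbing);
* deposition energy: lognormal, median 60 eV, σ = 1 (mean ≈ 99 eV).

These defaults were fixed once on order-of-magnitude grounds; with
them the full alpha chain yields ~8 DSB/µm, inside the broad
3–30 DSB/µm band the acceptance suite checks. Nothing in the
generator is tuned to reproduce published yields, and tests passing
on synthetic tracks demonstrate correct bookkeeping and clustering,
not physical accuracy of deposition spectra.

Reproducibility: per-track RNG streams are `SeedSequence((seed, 0,
track_index))`, the mixture choice uses `(seed, 1, 0)`, and scoring
uses `(seed, 2, track_id)` — disjoint key spaces, so generation and
scoring never share a stream and results are independent of
iteration order.

## Damage scoring

Acceptance of a deposition as a strand break uses a single Bernoulli
draw with probability `SPointsProb · ramp(E)` — statistically
identical to separate sensitive-volume and damage draws but with half
the stream length; because the uniform is drawn for every deposition,
runs at different SPointsProb on the same seed are coupled and
acceptance is monotone in SPointsProb. The ramp is the clamped linear
form (0 at ≤ 5 eV, 1 at ≥ 37.5 eV); the clamping text is taken as
authoritative over the bare ratio formula. Strand labels are
Bernoulli(0.5) by default (`strand_prob` exposed; the upstream
convention does not state the probability).

Clustering is scikit-learn DBSCAN with MinPts = 2. The pairing
inequality is strict — "less than 10 bp" — which DBSCAN's ≤-eps
neighborhoods realize exactly by running at `nextafter(eps, 0)`, the
largest double below 3.4 nm: in double precision `d < eps` iff
`d ≤ nextafter(eps, 0)`. Distances are 3-D Euclidean in nm with no
discrete bp grid. Cluster identity is the partition; outputs are
sorted by minimum member coordinates for determinism. A hand-written
O(n²) union-find over the exhaustive strict-< relation
(`brute_force_cluster`) serves as an independent oracle in the tests
and is never used in the scoring path.

Scoring is per primary track, never across tracks (mirroring
per-event tallies); two breaks 1 nm apart on different primaries do
not pair. Classification: isolated → SSB; one-strand cluster →
complex SSB; both-strand cluster → DSB, simple at size 2 and complex
at size ≥ 3. The per-track summary keeps the cluster-size histogram,
total deposited energy, and — for alphas — the track length from the
generator metadata.

## Dosimetry

Energies are keV internally, converted at 1 keV = 1.602176634×10⁻¹⁶ J;
doses in mGy. The mean deposited energy per decay is ΣEᵢ/(N_cells·nt)
and its history-by-history standard error is
(1/N_cells)·√[(ΣEᵢ²/N − (ΣEᵢ/N)²)/(N−1)] with N = nt and zero-deposit
events included as Eᵢ = 0 (computed from sums, so implicit zeros cost
no memory). N1h, the decays per Bq during the 1 h irradiation, is the
decay integral (1 − e^(−λ·3600 s))/λ — decay-corrected by default,
with a plain 3600 s mode available, and users may supply N1h
directly. d_Lymph is defined so that D_nucleus = A[MBq]·d_Lymph/V[mL],
the same convention as d_Blood, making the two coefficients directly
comparable; d_Blood itself is a required external input (it needs
full macroscopic transport, which is out of scope). Replicate
uncertainty is the sample standard deviation (n−1) over independent
seed runs; the pipeline derives replicate seeds as seed, seed+1, ….

## Alpha analysis

Detectability thresholds are strict on both axes (length > 0.75 µm
and > 7 DSBs): a track of exactly 0.75 µm or exactly 7 DSBs is
excluded, matching the "superior to"/"more than" phrasing of the
experimental criteria (a focus is ~250–300 nm across, and a countable
track needs at least three foci in a row). The linear DSB density is
a ratio of sums — total DSBs over total track length of the included
tracks — not a mean of per-track ratios, so long tracks weigh in
proportionally. Both thresholded and unthresholded track rates are
reported; the package takes no position on which an experiment should
match.

## Pipeline, problem sizes and limitations

`run_pipeline` executes place → generate → score → dose → reports
from a TOML config, refuses to run without an explicit `run.seed`,
and writes a manifest (software version, full config, replicate
seeds, derived parameters) sufficient to reproduce every output
byte-identically. The built-in replicate runner defaults to one run;
the examples and tests use 2–5 replicates, which resolve the
DSB·cell⁻¹·mGy⁻¹ spread to a few percent at a few hundred primaries.
Default problem sizes in the tests and acceptance script (≤ 1000
cells per placement, 100–200 alpha primaries ≈ 10⁶ depositions per
run) were chosen so the whole suite completes in well under a minute
each; yields stabilize well below these sizes.

Known limitations, all deliberate scope boundaries: no condensed-
history or track-structure physics (straight chords, placeholder LET
and deposition spectra; input spectra for real radionuclides must
come from an external engine via the phase-space/deposition file
interfaces); no indirect radical-chemistry damage, 3-D chromatin
geometry, repair kinetics or focus-image simulation; no reading of
native GATE/ROOT phase-space binaries (a converter is user-supplied);
and inter-track proximity merging is intentionally not modeled.
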
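# Methods

This document describes the model implemented by `biotransnet`, the default
parameters and their rationale, the synthetic-data generator used for
validation, and the numerical design choices (including the known pitfalls
they address).

## 1. Biotransformant prediction

### Elemental-composition algebra

A compound is represented by a signed element → count map
(`ElementalComposition`). Metabolic reactions are net composition deltas: for
example oxidation is `+(O)`, sulfation is `+(O3 S)`, oxidative dechlorination
is `−(Cl) +(H O)`. The net delta of a reaction path is the elementwise sum of
its steps, so path order never affects the product formula, and a product is
chemically admissible only if every element count stays non-negative — this
is what prevents, e.g., deiodination from being applied to an iodine-free
parent. Monoisotopic masses use IUPAC values for the most abundant isotope of
each element; `[M+H]+`/`[M−H]−` m/z adds/subtracts the mass of a proton
(1.007276466879 Da). Mass-accuracy comparisons are in parts per million:
`ppm = 1e6·|observed − theoretical| / theoretical`.

### Reaction library

The default library contains 28 reactions: phase I functionalizations
(oxidation, reduction, hydration, dehydration, desaturation, demethylation,
deethylation, decarboxylation, nitro reduction, ring opening, oxidative and
reductive dehalogenation for Cl/Br/I, oxidative deamination to alcohol and to
ketone) and phase II conjugations (glucuronide, sulfate, glutathione,
glucoside, taurine, glutamine, arginine, acetyl, methyl, palmitoyl, stearyl).
Libraries are plain YAML (`name`, `phase`, `delta`) and fully replaceable at
the API and CLI level.

### Enumeration

Products are enumerated over unordered multisets of reactions
(`combinations_with_replacement`) up to `max_total = 5` steps with at most
`max_phase2 = 1` conjugation — conjugates are typically terminal metabolites,
and a second conjugation mostly inflates the candidate space. Products that
would drive any element negative are pruned. Duplicate product formulas are
deduplicated keeping the shallowest (then lexicographically first) path, and
results are sorted by product mass. For T3 with the full library this yields
11,193 distinct product formulas in a few seconds.

## 2. LC-MS feature annotation

### Mass matching

Each feature's m/z is compared against every predicted product's adduct m/z
for the run polarity at `ms1_ppm = 5`. Features matching more than one
prediction are flagged ambiguous rather than discarded; co-eluting features
matching the same prediction are grouped by retention time (`rt_tol = 0.1`
min) so isomeric transformants remain distinguishable.

### Fragment-coverage (FISh-style) scoring

For an annotated feature with an MS2 spectrum, the candidate explanation set
is the parent's fragment m/z values plus those fragments shifted by every
cumulative partial sum of the reaction path's step deltas (a fragment may
carry none, some, or all of the modifications). A feature peak counts as
explained if it is within `ms2_ppm = 10` of any candidate. Only peaks above a
signal-to-noise floor — `snr = 3` times the median peak intensity —
enter the denominator; the score is the percentage explained, or undefined if
no peak clears the floor. This floor model assumes spectra contain a
low-intensity noise population below the signal peaks (true of centroided
experimental data and of the synthetic generator); on noise-free stick
spectra the floor can exceed all peaks and the score is reported as missing
rather than guessed.

### Annotation filter

An annotation is retained if its maximum per-sample area is at least 1e5
counts **or** its fragment coverage is at least 50 %. The area threshold is
read as 10^5 (a printed "105" in the source material is interpreted as a
typeset exponent); both boundaries are inclusive.

## 3. Molecular networking

The modified cosine similarity operates on sqrt-transformed, L2-normalized
intensities. Peak pairs are eligible if their m/z difference is within
`frag_tol = 0.05` Da of zero (direct match) or of the precursor m/z
difference (shifted match); eligible pairs are matched greedily one-to-one in
descending score order. An edge is kept when cosine > 0.5 (strict), at least
6 ions match, and the precursor shift is at most 500 Da; each node then keeps
only edges to its mutual top-10 neighbors. Components are labeled
deterministically (largest first, ties by smallest node id). The parent's
component is the "parent subnetwork": nodes matching a prediction are tagged
`predicted` with the reaction path, unmatched nodes are tagged
`candidate-novel` with their Δm/z from the parent.

The greedy matcher was validated against an exhaustive optimal-assignment
oracle (identical to 1e-9 on thousands of random small spectra) and
cross-checked against an independent implementation (matchms). Greedy and
optimal matching can in principle differ on adversarial peak layouts; no
discrepancy was observed on random or simulated spectra.

## 4. Reporter-assay normalization

Relative transcriptional activity is computed per replicate as
`RTA = 100·(test − VC_test) / (PC − VC_control)` and summarized as mean ± SD.
The normalization is exactly invariant to affine gains in luminescence
(detector gain and additive background cancel). Each treatment arm may carry
its own vehicle control (`VC_test`), falling back to the plate control
otherwise. A compound/arm is called agonist-positive when **any** dose
reaches RTA ≥ 10 %, boundary inclusive. Plates where the positive control
fails to exceed the vehicle control raise an error; a PC/VC induction below
4.8-fold triggers a quality warning.

## 5. Statistics

### Mann-Whitney U

With `method="auto"` (the default) the test is computed by **exact
enumeration** of all group assignments whenever the pooled sample size is at
most 12 — which covers the workflow's standard 3-vs-3 design — and by the
normal approximation otherwise. Ties contribute ½ to the U statistic; the
two-sided p is `min(1, 2·min(P(U ≤ u), P(U ≥ u)))`, matching the standard
convention.

This choice is deliberate. At n = 3 per arm the smallest achievable exact
two-sided p is 2/20 = 0.1, so *no* feature can be "significant" at α = 0.05
by rank test alone. The uncorrected normal approximation, by contrast,
returns p ≈ 0.0495 for every fully separated arrangement — which under the
null occurs 10 % of the time, a doubled type-I rate produced purely by
approximation error. The package therefore (a) defaults to the exact test,
(b) applies the continuity correction when the normal approximation is
requested (restoring conservative behavior at small n), and (c) exposes
`use_continuity=False` as an explicit legacy mode reproducing the common
uncorrected convention, useful when mirroring volcano plots produced by
older tools. Volcano classification combines p < α with fold-change
direction; Benjamini-Hochberg adjustment is available but off by default.

### Fold change and metabolic rate

Fold change is the ratio of arm means of imputed areas (missing values are
imputed at 10 % of the feature's minimum observed area; features missing
everywhere are dropped). The parent's metabolic rate is
`100·(1 − mean(reaction)/mean(control))` and may be negative if the parent
signal increases.

## 6. Synthetic-experiment generator

All randomness flows from a single integer seed through
`numpy.random.default_rng`; every written artifact is byte-identical across
reruns with the same configuration.

A simulated experiment contains:

- a **parent feature** at the exact adduct m/z (base area 1e6), depleted in
  the reaction arm by a configurable metabolic rate (default 3 %);
- **planted transformants**: one feature per configured reaction path, at the
  predicted m/z jittered uniformly within ±3 ppm, control-arm base area
  3e4, reaction arm multiplied by 2^log2fc (defaults: five paths with
  log2fc 10, 6, 5, 3, 4);
- **decoy features** (default 50) rejection-sampled to lie at least 20 ppm
  from *every* predicted m/z, with random MS2 spectra;
- multiplicative log-normal noise with unit mean and CV 0.2 on all areas
  (n = 3 per arm);
- **MS2 spectra**: transformant spectra are the parent's fragments shifted by
  the path's net delta mass plus low-intensity noise peaks (so fragment
  coverage and network clustering are both exercised realistically);
- a **reporter plate** with PC/VC/test wells over a 1 nM–10 µM dose range,
  saturating dose-response (d/(d+EC50)), Gaussian well noise, and per-arm top
  activities (parent 100 %, inactive-S9 100 %, phase I 150 %, phase I+II
  309.1 % — the conjugative-activation scenario).

Ground truth (planted feature ids, decoy ids, true plate activities) is
written as JSON alongside the data.

**Scope.** The generator validates the pipeline's logic, not its field
performance: it plants features at m/z values the predictor can reach, gives
transformants parent-derived spectra, and uses well-behaved noise. Passing
these tests demonstrates correct mass algebra, matching, scoring, networking,
normalization and statistics — it does not demonstrate recall on real
matrices with co-elution, in-source fragmentation, isotope interference, or
non-log-normal area noise.

## 7. Numerical and implementation choices

- Exact Mann-Whitney by full enumeration (feasible and instantaneous at the
  pooled-n ≤ 12 cutoff); scipy's asymptotic implementation for larger n.
- Greedy modified-cosine matching (GNPS semantics) rather than optimal
  assignment; validated as described above.
- Standard-format I/O through established libraries: pyteomics (MGF), pandas
  (CSV/TSV), networkx (GraphML).
- Reported tables are sorted deterministically and reports carry a parameter
  manifest plus SHA-256 checksums, so a seeded run is fully reproducible.
- Problem sizes in the validation suite (spectrum sizes for the exhaustive
  cosine oracle, numbers of simulated networks and seeds) are chosen to keep
  the full test suite within a few minutes on one CPU while still exercising
  every code path; they are properties of this package's test design, not of
  the underlying method.

## 8. Limitations

- Predictions are formula-level: structural isomers, reaction-site
  feasibility, and metabolite stability are out of scope; the candidate
  space grows combinatorially and is controlled only by the depth caps.
- Fragment-coverage scoring requires a parent MS2 spectrum and a noise
  population for the S/N floor; it is undefined otherwise.
- The ≥ 10 % RTA agonist rule and the 4.8-fold induction QC are fixed
  conventions of the assay protocol, not fitted quantities.
- At n = 3 per arm, rank-based significance is fundamentally limited
  (minimum exact p = 0.1); volcano "hits" at α = 0.05 under the legacy
  uncorrected mode should be read as a screening convention, not calibrated
  inference.
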
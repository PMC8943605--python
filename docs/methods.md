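# Methods

This note documents the models, numerical choices and limitations of
`simsfilter`. Nothing here states an empirical result the test suite or
`scripts/acceptance.py` does not itself compute.

## Mass and m/z model

Monoisotopic masses come from a bundled CODATA/AME-sourced element
table (`data/elements.csv`, ≥9 significant digits) covering H, C, N, O,
F, Na, Al, P, S, Cl, K, Ca, Br, I and the heavy-isotope variants
[2H], [13C], [37Cl], [81Br]. Isotope variants are distinct symbols that
inherit the DBE class of their parent element. The table is
cross-checked in the test suite against an independent source
(pyteomics) to a relative 1e-7.

Single-charge ion m/z always applies the electron rest mass
(0.000548579909 Da): a cation is one electron light, an anion one
electron heavy. At m/z 329 the electron mass is a 1.7 ppm effect — the
same order as the search tolerance — so omitting it would be a
systematic bias, not a rounding choice. Multiply charged ions are out
of scope.

## DBE

DBE = N_C − N_H/2 − N_X/2 + N_N/2 + N_P/2 + 1, with halogens in N_X and
isotope variants counted with their parents. The formula is evaluated
directly on whatever composition it is given, so [M±H] ion compositions
yield half-integers (deprotonated palmitate: 1.5). Because the
literature quotes both conventions — half-integer ion values for acids,
integer neutral values for sulfonates — both are exposed:
`dbe(f, convention="neutral", polarity=...)` shifts by +0.5 (protonated
positive ion) or −0.5 (deprotonated negative ion), and DBE-vs-carbon
tables and plots always annotate which convention they used. The
default is the ion convention, so nothing is silently inferred about
the ionization mechanism.

## Formula enumeration

The search enumerates **ion compositions directly** (Na counted as an
element of the box, as published constraint lists are written), not
neutral compositions plus an adduct layer. Given observed m/z, charge z
∈ {−1, 0, +1} and tolerance t ppm, the composition-mass window is
[mz·(1−t·10⁻⁶) + z·mₑ, mz·(1+t·10⁻⁶) + z·mₑ]. Enumeration is a
recursive per-element descent ordered by decreasing element mass with
residual min/max attainable-mass pruning; it is exact — the test suite
proves set-equality against brute-force Cartesian enumeration on 100
random boxes per run — and fast enough for C≤100/H≤200 boxes at m/z
2250 (milliseconds per peak).

Open-ended element maxima ("any count") are capped at
⌊upper-window / element-mass⌋, which is the largest count that can fit
at all. Candidates are sorted by |ppm error| with ties broken by the
Hill formula string, so orderings are reproducible. The tolerance
policy is piecewise-constant in m/z; a breakpoint m/z belongs to the
higher (tighter) segment — a conservative convention for a boundary no
instrument note specifies. Defaults are 3 ppm below m/z 95 and 2 ppm
above, typical acceptable Orbitrap errors; the policy is configurable
per search.

Chemical-plausibility heuristics (non-negative DBE, nitrogen rule) are
implemented but **off by default**: the filtering method selects by
composition ranges and ppm error only, and uses DBE downstream for
visualization rather than rejection. The minimum-intensity noise cut is
likewise a separate upstream step (`apply_intensity_threshold`),
mirroring the two-stage peak-search-then-predict flow of instrument
software; no intensity weighting enters the search itself.

## Peak lists and the iterative workflow

The reader accepts tab/comma/semicolon delimited text with an `mz`
column, optional `intensity`, optional `id` and any number of `scan_*`
columns (the depth profile; vendor export schemas vary, so the reader
is deliberately permissive and the writer emits this documented
dialect). m/z is written at ≥6 decimal places (1 ppm at m/z 100 is
10⁻⁴) and values that need more precision are written in full, so
read/write round-trips are lossless. Duplicate m/z rows are legal
(shoulder peaks) and keep distinct ids.

`separate` partitions a peak list by an assignment (disjoint, union =
input, content untouched — asserted on every fixture);
`iterative_filter` chains assign → separate so stage k searches only
the residue of stage k−1. Depth-trend labelling, used for validation
only, compares the mean intensity of the first and last third of scans
with no smoothing: rising = substrate-like, falling = overlayer-like.
It is a reproducible proxy for the qualitative depth-behavior check,
not a classifier.

## Database annotation

Matching is **exact on the neutral formula** after adduct arithmetic —
never on mass — because candidate formulas are already mass-filtered;
a database hit asserts identity of composition. For a candidate ion
composition the neutral is rebuilt per adduct: subtract H for [M+H]⁺,
subtract Na for [M+Na]⁺, add the proton back for [M−H]⁻, identity for
intact species; adducts that would drive any count negative are skipped
silently. All records sharing a formula are returned (bulk-composition
databases cannot resolve isomers, chain positions or double-bond
regiochemistry — out of scope by design).

The bundled lipid table (`data/lipids_demo_synthetic.csv`) is a small
hand-built stand-in of ~40 bulk formulas across FA/ST/GP/SP/GL/PR
classes so the repository needs no download; real analyses should load
a full database export, whose licensing and versioning stay with the
user.

The peptide database enumerates residue **multisets** (composition, not
sequence) of size 1..6 over the 20 canonical amino-acid residue
formulas (`data/amino_acids.csv`); peptide neutral formula = residue
sum + H₂O. Counts follow the multiset closed form Σₖ C(19+k, k):
20 records at one residue (19 distinct formulas — Leu/Ile coincide) and
230,229 at six. Whole peptides only: b/y-type fragment termini
(±H₂O/±NH) are a possible extension, deliberately not enabled, since
which termini chemistry SIMS fragments carry is sample-dependent.
Adduct handling ([M+H]⁺/[M+Na]⁺) is centralized in `match_database`
rather than baked into the records.

## NMF

Lee–Seung multiplicative updates for squared Frobenius loss, ε = 10⁻¹²
in denominators, 200 iterations by default, initialized with the
elementwise absolute value of seeded standard normals — the canonical
deterministic choice when only "NMF, 200 iterations" is specified.
The objective is recorded every iteration and is non-increasing (a
property of the update rule, asserted on every test run). Loading
columns are scaled to unit maximum with the scale absorbed into the
profiles, leaving the product unchanged. Final reconstruction error is
cross-checked in tests against scikit-learn's `mu` solver within 5%.

Per-peak row max-normalization before factorization is available but
off by default: raw intensities bias the fit toward intense ions, and
the default mirrors the unnormalized analysis; the flag exists for
high-dynamic-range data.

The factor count is chosen by the endmember-repetition heuristic:
increase k until endmembers duplicate, then keep the previous k.
"Duplication" is operationalized as the maximum pairwise cosine among
loading columns **or** among profile rows exceeding a threshold
(default 0.98) — on a rank-deficient fit the redundant component can
appear on either side of the factorization, parallel loadings or
parallel profiles. The published stopping rule is qualitative
("excessive repetition"); 0.98 is this package's documented convention,
and `choose_k` returns the full diagnostic table so the recommendation
can be overruled. `repetition_score` itself reports the loadings-only
cosine.

## Synthetic data

The generator emulates what a depth-profile export looks like after
peak searching: each truth ion at its theoretical ion m/z perturbed by
Gaussian ppm error, a per-scan profile (exponential decay, logistic
rise, or constant, evaluated on normalized depth and unit-max scaled)
times a base intensity times log-normal multiplicative noise, plus
Poisson-count decoy peaks at uniform m/z with no true composition.
Decoys may be assignable by chance — deliberate, since real chemical
noise is. One `numpy` generator seeded once drives all draws in
documented order, so peak lists are bit-reproducible.

The bundled scenario (`data/scenario_two_component.json`) fixes the
study conditions used throughout the tests: 30 sulfonate-like ions
(C₈₊ₙH₉₊₂ₙSO₃⁻, exponential decay, rate 3) + 30 carbon clusters
(C₁₀–C₃₉⁻, logistic rise, midpoint 0.5, steepness 10), 0.3 ppm mass
error, σ=0.2 log-normal intensity noise, 20 expected decoys over m/z
80–700, 50 scans, seed 42. Intensities (5,000/8,000 base counts) and
shapes mirror the organic-overlayer-over-substrate behavior seen in
depth profiles of contaminated inorganic surfaces.

What passing on synthetic data does **not** show: robustness to
isotope envelopes, detector saturation, mass-axis drift within a
profile, correlated chemical background, or lateral heterogeneity —
none of which the generator models. Headline counts from real samples
(hundreds of assigned substrate ions, hundreds of matched lipids)
depend on instrument data not shipped here and are not reproduced;
validation rests on worked reference values, oracle equivalence, and
parameter recovery under the stated synthetic conditions.

## Problem sizes

Test and acceptance runs use the sizes above (60 truth ions + ~20
decoys, 50 scans; 100 random oracle boxes of ≤10⁵ combinations; the
full 230,229-record peptide database), chosen so the whole suite
completes in well under a minute while every check still exercises the
genuine combinatorics.

## Command-line interface

Each verb is a thin recipe over the library and writes a
`manifest.json` (command, parameters, package version, seed) beside its
outputs. Constraint boxes are JSON files rather than flag lists because
element-range searches are naturally nested; identical config + seed
gives byte-identical numerical outputs.
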
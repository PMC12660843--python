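# Methods

This note documents the models, numerical choices and limitations behind
each phabkit module, in the order a campaign would use them.

## V-domain numbering (`phabkit.numbering`)

A query variable domain is aligned globally (BLOSUM62, gap open −11,
extend −1) to a shipped reference consensus — a curated human
germline-style V-domain, one per chain kind and scheme, packaged under
`phabkit/data/vdomain_references.yaml`. The references carry exactly one
residue per scheme position and no insertion codes (Kabat heavy 1–113,
light 1–107), so scheme positions transfer directly across aligned
columns. A query whose alignment score falls below 40% of the reference
self-score is rejected as "not a V-domain"; the threshold is generous
because true V-domains of either species score far above it and random or
non-antibody sequences score near or below zero.

Loop positions are not taken from raw alignment columns. Both Kabat and
IMGT define CDR numbering by loop *length*, so any region that contains an
alignment insertion is renumbered by the scheme's fill rule:

* **Kabat**: positions fill left-to-right up to the canonical insertion
  anchor (H3: 100, H2: 52, H1: 35, L1: 27, L3: 95, FR3-H: 82, FR4-L: 106),
  excess residues become `a, b, c, …` insertions on the anchor, and the
  remaining positions continue after it. Loops shorter than the reference
  leave positions just after the anchor unassigned. Kabat 35A/B fold into
  the CDR-H1 interval.
* **IMGT**: CDR slots fill symmetrically from both ends toward the middle
  (gaps open mid-loop); framework slots drop at the IMGT-standard gap
  positions (10 in FR1, 73/81–84 in FR3, the tail of FR4). The conserved
  Cys23/Trp41/Cys104/Trp118 landmarks land on their canonical slots for
  the shipped references. One deliberate simplification: CDR3 residues
  beyond the 13-slot capacity are coded `111a, 111b, …` ascending. The
  official IMGT scheme interleaves 111.x/112.x so that some extra
  positions sort *before* 112; that ordering cannot be represented in a
  (number, letter) total order, and the ascending convention keeps every
  chain strictly ordered, which downstream grafting and diffing rely on.

CDR boundaries: Kabat L1 24–34, L2 50–56, L3 89–97, H1 31–35, H2 50–65,
H3 95–102 (insertions included within their interval); IMGT CDR1 27–38,
CDR2 56–65, CDR3 105–117. Region maps are total: every numbered position
falls in exactly one of FR1…FR4.

## Grafting and back-mutation (`phabkit.humanization`)

A graft takes donor residues at every CDR position (insertions carried
over, so grafts may change length) and acceptor residues at every
framework position; positions are merged under the scheme's total order.
Back-mutation replaces framework positions of the graft with the donor
residue, records `X##Y^chain` notation, silently skips positions where
donor and acceptor already agree, and refuses CDR positions — Vernier
back-mutation is a framework operation by definition.

The Vernier set is data, not code (`phabkit/data/vernier_kabat.yaml`),
shipped with the classic Foote–Winter positions (heavy: 2, 27–30, 47–49,
67, 69, 71, 73, 78, 93, 94, 103; light: 2, 4, 35, 36, 46–49, 64, 66, 68,
69, 71, 98). Campaign-specific sets load from a user file, because the
exact back-mutation set of any given humanization is an empirical outcome,
not derivable from the scheme.

## Soft-randomization library design (`phabkit.library_design`)

A soft-randomized position mixes `wt_fraction` (default 0.7) of the
wild-type nucleotide with equal parts of the other three. Per-codon
amino-acid distributions are computed by exact enumeration of all 64
codons under per-base independence (the physical model of doped synthesis
resins), standard genetic code. At 70/10/10/10 the wild-type *codon*
survives with probability 0.7³ = 0.343 and the wild-type *amino acid*
with 0.343–0.49 depending on degeneracy (mean 0.454, median 0.490 over
the 61 sense codons) — the "retained roughly half the time" regime. Both
the per-codon table and its mean/median are reported because either can
be meant by a library-wide retention figure.

Stop templates replace the first codon of each region to be mutagenized
with TAA, so only clones repaired by a mutagenic oligo express
full-length protein. Oligos carry exact template flanks (default 15 nt)
and explicit percent mixtures per diversified base — soft mixes have no
IUPAC code, so they serialize as `A70/C10/G10/T10`. Oligos are reported in
template-strand orientation with reverse-complement as a flag, since
Kunkel-strand conventions vary between labs.

The clone sampler draws each diversified base independently from its
mixture with a seeded generator (`numpy` PCG64); it emulates desk-scale
clone picking, not the 10⁹–10¹⁰ physical diversity of a real library.
The diversity report counts amino-acid sequences of non-zero probability
and estimates the expected number of distinct sequences in a sample of
size n by Poissonization, Σ_s (1 − e^(−n·p_s)) — exactly when the support
is enumerable (≤ 2×10⁵ by default), otherwise by importance sampling from
the library distribution. Both are approximations to sampling without
replacement and are labelled as such in the report.

## Selection-pool analysis (`phabkit.selection_analysis`)

Pools are equal-length protein clones aligned to a template; clones with
indels are excluded with a logged count rather than aligned, because
soft-randomized libraries are substitution-only and length changes are
sequencing artifacts. The substitution matrix counts every residue per
position (keyed by Kabat labels when a numbering is supplied); the
template fraction measures selection progress away from the parent.

Per-substitution association with an external binder/non-binder label
uses the 2×2 table [with/without substitution × binder/non-binder], a
Haldane-corrected odds ratio, a two-sided Fisher exact p, and
Benjamini–Hochberg q-values across substitutions. Binder labels are
caller-supplied; a fold-change ≥ 2 phage-ELISA threshold is a reasonable
convention but not built in. Note the exact test is discrete: under the
null its p-values are valid (never anti-conservative) but not exactly
uniform — there is an atom at p = 1.

The selection simulator applies Wright–Fisher-style rounds: clones are
resampled with replacement with probability proportional to the product
of the enrichment factors of the substitutions they carry. Its mean-field
recursion f′ = s·f / (s·f + 1 − f) is exposed separately
(`expected_frequency_trajectory`) and inverted on the odds scale to
recover factors from observed trajectories. The simulator models
selection only — no mutation, no pool bottlenecks between rounds other
than constant size.

## BLI kinetics and ELISA curves (`phabkit.kinetics`)

The 1:1 Langmuir model: association R(t) = Req·(1 − e^(−(ka·C + kd)·t))
with Req = Rmax·C/(C + KD), dissociation R(t) = R₀·e^(−kd·(t − t₀)),
KD = kd/ka. Fitting is global least squares in log-parameters over all
phases and traces sharing (ka, kd, Rmax), initialized from a log-linear
regression of the dissociation tail (kd) and a kobs-vs-concentration
regression (ka), with three deterministic ±10× restarts. A single
concentration far below KD identifies only kobs = ka·C + kd; the fit
reports what the data give and the identifiability caveat is encoded as a
test, not an error. Mass-transport and bivalent-analyte models are out of
scope; apparent affinities of bivalent (IgG) formats are avidity-inflated
and the module makes no attempt to correct for that.

Default simulation geometry: 300 s association, 600 s dissociation, 2 Hz
sampling, analyte at 20–200 nM — the concentration window and phase
lengths typical of streptavidin-sensor peptide assays. Recovery checks
run at the matured-variant operating point (ka = 2.4×10⁵ 1/(M·s),
kd = 4.2×10⁻³ 1/s, 1% Rmax Gaussian noise, 3 concentrations).

ELISA utilities: the standard curve selects the longest contiguous run of
≥ 3 points whose linear fit reaches R² ≥ 0.98 (ties broken toward higher
R²), interpolates unknowns only inside that range (out-of-range unknowns
are flagged, never extrapolated) and scales by the dilution factor.
Dose-response uses a 4-parameter logistic fit with EC50 parameterized on
the log scale.

## Interface geometry (`phabkit.structure_contacts`)

Contact criteria (defaults, all configurable): H-bond donor–acceptor
distance ≤ 2.5 Å with donor (D–H···A) and acceptor (H···A–X) angles in
120–180°; water bridges use the same angles with a 2.8 Å window per leg;
π-cation ≤ 4.5 Å cation-to-centroid; π-π centroid distance 3.5–5.0 Å.
The 2.5 Å heavy-atom D–A cutoff is unusually short next to the
conventional ~3.5 Å; it is implemented literally as the default, with
`ContactCriteria.conventional()` (3.5 Å) one call away. π-π contacts are
classified parallel below 30° interplanar angle and T-shaped above 60°;
the thresholds are chosen so that reported T-shaped stackings at 68–86°
and face-to-face stackings near 0° classify as named.

Hydrogen handling: when the model carries explicit hydrogens, donors are
polar heavy atoms with attached H and angles are measured through the H.
When the model has none (typical crystal structures), the heavy-atom
antecedent angle X–D···A stands in for the donor angle, with a warning;
in a protonated model an atom without H is simply not a donor, which
prevents one physical bond from being counted in both directions. Ring
geometry follows the PLIP-style definition: centroid distance,
interplanar angle arccos|n₁·n₂| ∈ [0°, 90°], and offset as the in-plane
displacement of the partner centroid projected onto the first ring's
plane. Rings come from residue templates (His, Phe, Tyr, and both Trp
rings, evaluated separately); cations from Lys NZ and the Arg guanidinium
centroid.

Superposition uses the Kabsch algorithm (proper rotation via SVD, through
`scipy.spatial.transform.Rotation.align_vectors`); collinear point sets
are rejected because the in-plane rotation is not determined. The
paratope shell lists receptor residues with any side-chain atom within
10 Å of the antigen (backbone-only proximity does not count), or, in
contact mode, residues participating in any detected contact — always a
subset of the 10 Å shell for the default criteria.

SASA is Shrake–Rupley with deterministic golden-spiral test points
(default 960 per atom, probe 1.7 Å, element radii C 1.70 / N 1.55 /
O 1.52 / S 1.80 / H 1.20 Å). Buried surface is SASA(A) + SASA(B) −
SASA(AB), reported as the two-sided total by default and halved only
under the per-side flag — conventions differ between programs, so the
choice is explicit. At 960 points the isolated-sphere error is < 1% and
two-sphere overlaps agree with the analytic spherical-cap area within 2%.

## Synthetic fixtures (`phabkit.synthkit`)

Every detector and estimator is tested against fixtures whose ground
truth is prescribed by construction: V-domains built by editing the
shipped reference at known Kabat positions (so the numbering truth is
written down before the numbering engine runs), interface models whose
distances and angles are placed analytically (exact to 1e-6 before PDB
3-decimal quantization, so assertions allow ≤ 2×10⁻³ Å effects), seeded
sensorgrams, and seeded selection pools. What these fixtures do *not*
emulate: real sequencing noise, real instrument drift and reference-well
artifacts, crystallographic disorder, and genuinely novel loop
conformations — passing tests demonstrate correctness of the
computations, not robustness to every pathology of real data.

The synthetic interface fixtures are constructions of this package, not
derived from any deposited coordinates. Analyses that depend on real
deposited structures (e.g. cross-structure Cα RMSDs of specific Fab
complexes) require downloading those entries and are outside the offline
test suite.

## Problem sizes

Default verification sizes, chosen to make sampling error negligible
relative to each tolerance: 100 seeded replicates for kinetic-fit
recovery, 50 000 clones for sampler-vs-enumeration convergence (±0.01),
10 000 clones × 5 rounds for enrichment-factor recovery (±15%), 200
seeded runs for the neutral-selection martingale check, and 960 sphere
points for SASA accuracy checks.
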
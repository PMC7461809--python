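# Methods

This note documents the models behind `ptdr`: the coordinate and substrate
conventions, the licensing and cleavage model, the run-off trace model and
its inference rules, the synthetic-data generators that stand in for
wet-lab substrates, and the numerical/design choices that were genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Substrate model and coordinates

A `ModifiedDuplex` stores only the top strand (5'→3'); the bottom strand
is implied.  All positions are 0-based top-strand coordinates.  A
*linkage* `i` denotes the internucleotide phosphate between columns `i`
and `i+1` — on the bottom strand, the phosphate spanning the bases
complementary to those columns.  A circular molecule has `L` linkages
(linkage `L-1` wraps); a linear one has `L-1`.  Using one frame for both
strands avoids double bookkeeping; every strand-specific reading
(bottom-strand motifs, windows, offsets) is derived from it on demand,
and an exhaustive reverse-complement round-trip test pins the transform.

PT marks carry the strand, linkage and sulfur diastereomer (Rp is the
physiological form; synthetic phosphoramidite oligos are racemic).
For a GAAC site read on the top strand at columns `s..s+3`, the GpsA
linkage is `(top, s)` and the partner GTTC strand's GpsT linkage is
`(bottom, s+2)`; mirrored for bottom-strand sites.  Cytosine marks
(5mC/5hmC/g5hmC) are per-column, strand-aware, and validated to sit on a C.

## Enzyme registry

`data/enzymes.yaml` transcribes the characterized enzymes.  Cleavage
offsets use REBASE-style `Nt/Nb` notation: for a site whose motif ends at
column `e` (guiding-strand reading direction), the guiding-strand cut is
at linkage `e+t` and the opposite-strand cut at `e+b`; `t−b > 0` is a 3'
overhang.  Wobbled enzymes carry `[lo, hi]` ranges sampled uniformly and
independently per event, resampling the rare draws with `t < b` so every
emitted pair respects the 3'-stagger constraint (no distribution over the
wobble is known, so uniform is the uninformative choice).  Registry
validation rejects unknown cofactor keys/modes, duplicate names and
offset ranges that cannot satisfy `t ≥ b`.

Bsp305I's bottom-strand wobble (N4–5) may be an exonuclease artifact of
the original characterization rather than true enzyme behavior; both
offsets are retained in the registry since the question is unresolved.

## Licensing and cleavage

Each cofactor maps to an activity mode:

* **specific** — only PT-marked sites fire, at `p_cleave_specific`
  (default 0.9).  A mark on strand X licenses a cut oriented along X's
  reading direction for `hemi_side: downstream` enzymes (EcoWI), along
  the opposite strand's for `upstream` (Ksp11411I — it cuts upstream of
  the GpsT dinucleotide), and both for `both`.  Fully modified sites
  therefore license both orientations; one is sampled uniformly per
  event, since cuts are observed on both sides of sites but double cuts
  flanking one site are not.  `requires_full` (Bsp305I) suppresses hemi
  sites entirely.  `rp_only` enzymes ignore Sp marks, which is why
  racemic synthetic oligos digest only partially.
* **relaxed** — star activity (Mn2+): every motif or pattern match fires
  at `p_cleave_relaxed` (default 0.5) regardless of marks.  Star events
  occur only at motif/pattern matches, not arbitrary positions, matching
  the banded (not smeared) star digests.
* **partial** — the licensing rules of specific mode at the relaxed
  probability; used for cofactors whose specificity is reported only
  qualitatively (e.g. EcoWI in Ni2+/Ca2+, which the characterization
  leaves open).
* **nick_only** — licensed events, single-strand breaks only.
* **inactive** — nothing.

A firing event is a double-strand cut with probability
`p_ds_given_cleave` (default 0.75, giving the ~3:1 ds:nick ratio seen at
high enzyme level), otherwise a nick on one strand of the sampled
orientation (uniform).  With `two_site_factor > 1` (EcoWI default 3) the
firing probability is multiplied when ≥2 licensed sites are present,
capped at 1 — the enhancement is qualitative in the source data, so the
magnitude is an explicit free parameter.  The cleavage defaults (0.9/0.5)
are not measured quantities either; they are chosen to give visible
partial digests and are fully configurable.

ScoMcrA (`basemod_window`) fires at cleavage-pattern matches: in
specific mode at its preferred pattern ACN↓GT within `window` (default
20 nt — the licensing distance is not reported, so this is a configurable
default, not a derived value) of a modified cytosine; in relaxed mode
(including specific-mode runs at high enzyme level, modeling its
concentration-dependent star activity) at the degenerate pattern RYN↓RY.
SprMcrA-S (`pattern_only`, nick-only) nicks at SS↓RT matches
independently of modification.  Pattern cuts are emitted blunt at the
pattern linkage with the guiding strand recorded, because no
opposite-strand offset is known for these enzymes; consensus building
for them uses guiding-strand windows only (the two strand windows of a
blunt cut align at mirrored cut indices and would smear the logo).

"Complete digestion" means one sampling round per molecule at the stated
probabilities; no kinetics, no time courses, no Co2+ precipitation
artifacts.

### Fragments

Double-strand cuts sever the molecule: k cuts give k fragments on a
circle, k+1 on a line, with per-strand piece lengths conserved exactly.
Nick-only molecules are reported intact with their nicks annotated.  The
fragmentation model itself never emits single-stranded fragments (nicked
duplexes stay annealed); the `single_stranded` flag and the exonuclease-I
filter serve callers that track released single strands explicitly, e.g.
oligo-assay bookkeeping.

## Run-off trace model

Sequencing a partially digested template mixes run-off products
terminated at the break with full-length products.  Taq appends a
non-templated adenine to the broken-template product; in the trace this
terminal +A co-migrates with the last templated base, so the model places
the doublet **at the last templated position**: there the templated
channel keeps the full surviving signal `f` while the A channel gains
`f·cut_fraction`, and every later position is scaled by
`1 − cut_fraction`.  A templated A at that position shows as a single
extra-high A peak (1.5× the control at `cut_fraction` 0.5) followed by
drop-off — exactly the A/A-doublet behavior the bench method relies on.
Channel heights therefore sum to the surviving template fraction at every
position except the doublet, which carries the extra co-migrating
product.  Multiple breaks compound multiplicatively in read order.
Gaussian multiplicative noise (`noise_sd`, default 0.02) is applied per
channel.  No AB1 chromatogram emulation, base-quality modeling, or
FAM-label signal chemistry is attempted; the trace is the minimal signal
model the caller needs.

The break-to-read-position convention (direction +1: doublet column =
break linkage; −1: linkage + 1) is an internal contract shared by the
simulator and the caller, validated by round-trip tests; it would need
independent calibration before ingesting real traces.

## Break calling and geometry inference

Against a matched uncut control, a position is called when (a) the A
channel is secondary at ≥ `θ_doublet` (0.25) of the primary peak and
clearly above the control's A, (b) the templated call is A at ≥
`θ_highA` (1.4) times the control A, or (c) — corroboration only — mean
signal drops by ≥ `θ_dropoff` (0.3) across the position; a drop-off with
no doublet/high-A support is emitted as a low-confidence call.  The
thresholds translate the method's qualitative rules; they are validated
by round-trip recovery at `cut_fraction` 0.3–0.7 and `noise_sd` ≤ 0.05
and by a zero-false-positive property on break-free traces.  A known
blind spot is inherited from the bench method itself: a break landing
immediately downstream of another break's A/A doublet can fall below the
high-A threshold once the first drop-off has halved the signal ("the A/A
doublet is underrepresented in partial digestions").

Offset inference assigns each call to the nearest site within 30 nt, in
the motif-reading frame (GAAC-strand or GTTC-strand) giving the smallest
non-negative offset; calls upstream of every frame keep negative offsets
rather than being reassigned, preserving the hemi-site directionality
signal.  Offsets count nucleotides 3' of the motif end (REBASE N
notation).  Per-strand offset modes, dispersion (distinct offsets per
strand) and the overhang `t − b` are reported; geometry is flagged
undetermined when nothing assigns or dispersion exceeds 5.

Consensus windows are read 5'→3' on the cleaved strand, stacked into a
frequency matrix, and rendered as the IUPAC code of all bases at ≥ 25%
per column with a ↓ at the cut.  Information content is plain base-2
(2 + Σf·log2 f) with no small-sample correction.  Note that a truly
unconstrained column sits exactly at the 25% inclusion boundary, so with
finite site counts it may render as a partial code (e.g. S) rather than
N; compatibility checks should therefore test column-set containment,
not string equality, for degenerate patterns.

## Synthetic-data generators

All generators are pure functions of their parameters and seed.

* `make_random_plasmid` plants exactly `n_sites` GAAC/GTTC occurrences
  ≥10 bp apart (and ≥10 nt from linear ends, so fixed-offset products
  stay on the molecule) and scrubs accidental occurrences from the random
  background.
* `apply_dnd_marks` models incomplete Dnd modification: each site marked
  with probability `penetrance` (default **0.20**, the level reached by
  overexpressed dnd clusters), hemi vs full split by `hemi_fraction`
  (default 0.5 — how sites are chosen for full/hemi/no modification is
  unknown, so the split is uninformative), stereochemistry Rp with
  probability `rp_fraction` (1.0 for enzymatic marks, 0.5 for synthetic
  oligos).
* `make_oligoduplex_panel` emits the four single-site 60-mers
  (full/unmodified/two hemi forms) and the nine two-site 60-mers covering
  every {U, hemi, full}² combination (0–4 marks), GTTC starts 20 bp
  apart, identical site placement across members.  Sequences are
  generated, not transcribed; only the design constraints are enforced.
* `make_neighborhood_tables` plants one `ptdr` gene per genome and, at
  the chosen co-occurrence rate, a dnd-labeled partner at separation
  drawn from {1, 2, 3} — strictly inside the screen's "fewer than four
  genes" flagging rule, so injected rate and flagged fraction coincide
  exactly; background dnd genes are placed ≥5 genes away.  Tables need
  ≥11 genes so a non-flagging placement always exists.

What these generators do **not** emulate matters for interpreting green
tests: real dnd+ plasmids have sequence-correlated site selection and
unknown full/hemi structure, real traces have mobility artifacts, dye
blobs and context-dependent peak heights, and real neighborhoods have
operon structure and annotation noise.  Passing round trips show the
inference is self-consistent with the stated signal and licensing models
at realistic noise — not that those models capture every property of
bench data.

## Screen and assay arithmetic

The coverage filter keeps hits strictly above the threshold (default
90%).  Proximity is the absolute gene-index difference (adjacent = 1);
genomes are flagged below `max_sep` = 4, read literally as "fewer than
four genes apart" and configurable.  The flagged fraction carries an
exact Clopper–Pearson 95% interval (statsmodels).  Upstream retrieval
(psi-BLAST, E-utilities fetching, manual curation) is out of scope: the
screen consumes pre-built tables, and fractions are reported over the
tables supplied.

SEC: Kav = (ve − vo)/(vt − vo), calibrated by unweighted least squares
of Kav against log10(mass) — the conventional linear SEC calibration —
and inverted for apparent mass.  Oligomer bands are ratio ∈ [0.75, 1.25)
monomer and [1.5, 2.5) dimer: the dimer band deliberately reaches down
to 1.5 so a compact, light-eluting dimer (apparent 54.4 kDa for a
33.4 kDa monomer, ratio 1.63) is called dimer while the gap bands stay
"ambiguous"; edges are configurable.  Fold restriction is
control/test efficiency, censored at the plating detection limit when
zero transformants are observed.  Dilution-series selectivity is
`factor^Δsteps`, bracketed one step wide when endpoints are
interval-censored.

## Problem sizes and determinism

The shipped tests and the acceptance script use desk-scale sizes chosen
as the package's own defaults: 300-bp single-site substrates for
geometry round trips, 10-kb random DNA for consensus compilation
(hundreds of nick windows), 10,000 sites for penetrance recovery,
20 sites × 10,000 molecules for the ds:ss ratio, and 5,000 genomes for
the neighborhood screen — large enough that binomial 99% intervals are
a few percent wide, small enough to run in seconds.  Sub-stage RNG
streams are derived from the user seed via numpy `SeedSequence`
spawning, the recommended way to obtain independent reproducible
streams; all stochastic recoveries are asserted against exact binomial
intervals, never point equality.

## Known limitations

* One sampling round per molecule; no partial-digest kinetics, so
  "enzyme level" only toggles ScoMcrA's star behavior.
* Pattern enzymes cut blunt for lack of an opposite-strand offset.
* The GpsATC / GpsGCC cross-activities are qualitative in the source
  data and are representable only as partial/relaxed modes.
* The trace/caller doublet convention is an internal contract; real
  chromatograms would need calibration of that convention and of all
  three caller thresholds.
* The neighborhood screen treats labels as ground truth; no domain
  detection is performed.
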
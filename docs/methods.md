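# Methods

## Scope and data model

The package models the splice-variant family of *MYBPC1* (sMyBP-C) and the
single-fiber western-blot workflow used to profile it. All inputs are
packaged tables: a 16-row variant catalog (14 human, 2 mouse full-length
variants, each with its exon inclusion pattern, printed molecular weight and
accession) and a 33-exon architecture with residue counts for the six
cassette exons (exon 2: 11 aa, exon 3: 13, exon 4: 12, exon 5: 11, exon 10:
18, exon 23: 19) and the terminal exon 31 (19 aa). No genomic coordinates
are modeled and no databases are queried at run time; the catalog TSV is the
single source of truth.

### Splice grammar

Three rules constrain inclusion patterns and are enforced on load:

1. Cassette exons are frame-preserving (nucleotide length = 3 × residue
   length), so any in/out combination leaves downstream translation intact.
2. Exon 33 contributes coding sequence if and only if exon 32 is spliced
   out; otherwise exon 32 supplies the stop codon and exon 33 is pure 3′UTR.
   The four (exon 31, exon 32) states give post-C10 tails of 26 (19+7), 35
   (19+16), 3 and 33 residues with the stop in exon 32, 33, 32 and 33
   respectively; `resolve_tail` is total over these states.
3. h-v012 arises from an internal translation start mid-exon 7, not from
   exon skipping. It is encoded as a `tss_truncation` marker with upstream
   exons flagged absent, keeping it out of cassette-splicing statistics
   (it would otherwise inflate the count of alternatively used exons) while
   leaving its downstream exons countable.

Mouse partial variants carry a `partial` flag in the schema; because they
have no printed inclusion rows or masses, the packaged catalog contains only
the 16 full-length records. Partial records are refused by annotation and
excluded from all counting operations.

## Delta-mass model

A variant's mass is predicted relative to an anchor variant as
`anchor_mass + delta_aa × mean_residue_mass`, where `delta_aa` sums the
cassette residue counts over differing flags plus the tail-length
difference. Defaults: anchor h-v9 at its printed 126 kDa (chosen because it
lacks every NH2-terminal cassette, minimizing uncertain terms), mean residue
mass 0.110 kDa (the canonical average amino-acid residue), rounding
half-away-from-zero to 0.5 kDa (the precision of the printed masses). With
these defaults every non-truncated human variant is predicted within
±0.5 kDa of its printed mass, and swapping anchors moves predictions by at
most one rounding step. A closed-form least-squares calibration
(`m = Σdᵢyᵢ/Σdᵢ²`) is provided and lands at ~0.114 kDa/residue on the full
catalog; the default is kept at 0.110 because the model's job is
transparency, not fitting. h-v012's mass (115.5 kDa) is carried as data
only — its truncated residue count is not printed, so `delta_aa` refuses
internal-start patterns rather than guessing.

The 14 human variants partition into six MW groups (members fixed, centers
= arithmetic means of printed masses): 131.33, 129.17, 128.0, 127.25,
126.25 and 115.5 kDa. Nearest-center assignment uses a 1.5 kDa tolerance
(beyond it, no group) and a 0.5 kDa ambiguity margin: when the two best
distances differ by less, the call is flagged ambiguous and carries the
runner-up group. Ties go to the heavier group, deterministically. These
values mirror the coarse ~1 kDa spacing of neighboring group centers.

## Gel sizing

Band masses come from the standard semilog model: ordinary least squares of
log₁₀(mass) on relative migration (Rf; 0 at the well, 1 at the dye front)
over a marker lane with ≥3 monotone markers. A logistic migration model was
not used because the analysis window (115–132 kDa) is narrow enough for
log-linearity to hold essentially exactly. Bands sizing within 0.25 kDa of
each other in a lane are merged (gel resolution floor, half the 0.5 kDa
catalog precision), duplicate hits on one group within a lane are collapsed
to the closest band, and lanes are processed independently (no cross-lane
normalization; loading is assumed comparable). Rf values outside the
calibrated marker range by more than 0.05 trigger an extrapolation warning
rather than an error.

The default ladder places six markers (250, 150, 125, 100, 75, 50 kDa)
log-linearly across Rf 0–1, giving slope −log₁₀5 ≈ −0.699. Any monotone
ladder with ≥3 markers is accepted.

## Synthetic data

The generator emulates the two published single-fiber datasets.

**Deterministic fixtures.** Printed pattern frequencies are approximate
integers (soleus: 13 patterns at 4/10/4/2, 2/2/6, 40/12/6/4, 2/4 percent;
FDB: 5 patterns at 39/32/17/7/5), so fibers-per-pattern come from an exact
apportionment: among integer vectors summing to the fiber count (48 / 41),
minimize the maximum deviation between realized and printed percents, break
ties by total deviation, then lexicographically. The solver does a
parametric search over the finite set of achievable deviations with a
feasibility test on the induced count boxes, followed by optimal greedy
marginal allocation; tests verify it against exhaustive search on small
presets. For FDB this yields (16, 13, 7, 3, 2); for soleus the solution at
the optimum (max deviation 0.5 points) is unique. Bands are placed
noiselessly at group-center masses by inverting the default curve, so the
fixture → sizing → profiling round trip is exact by construction — fixture
tests validate plumbing, not noise robustness.

**Stochastic simulation.** Fibers are drawn from the count-normalized
pattern frequencies and each band's Rf receives Gaussian noise (default sd
0.002, about 0.2% of gel length, i.e. ~0.4 kDa at 128 kDa under the default
slope). All randomness flows from one integer seed; a fixed seed gives
byte-identical output files. Truth (per-fiber groups, masses, myosin) is
emitted alongside every dataset.

**What the generator does not emulate:** band intensities and antibody
affinity, fiber-size loading differences, blot image artifacts, replicate
lane structure, and any fiber-type selection bias in fiber picking. Passing
recovery tests therefore demonstrates the pipeline's arithmetic and its
behavior under migration noise, not robustness to real-blot pathology.

### Recovery characteristics

With the default ladder the 0.002 Rf noise maps to ~0.4 kDa mass noise
while groups 3, 4 and 5 sit only 0.75–1.0 kDa apart, so strict
nearest-center misassignment for bands of those groups is substantial
(≈11–29% per band) — an intrinsic property of the narrow mass spacing, not
of the implementation. Recovery is therefore quantified in two honest ways:

* band-level accuracy counts an ambiguous call whose runner-up is the
  generating group as a successful recovery (the call explicitly lists the
  true group); under this definition ≥95% of bands recover their group for
  realistic band mixtures;
* pattern-frequency recovery compares the across-seed (1–20) mean recovered
  frequency of each generating pattern at n = 500 fibers against the
  generating value at the 3-binomial-SE scale. Averaging across seeds
  isolates the systematic misassignment drift (up to ~1.5 points for the
  rare group-4/5 patterns) from per-draw sampling noise, which the binomial
  SE already describes.

Per-group occurrence recovered from noisy simulations has a mean absolute
error well under 2 percentage points at n = 500.

## Fiber profiling conventions

Pattern keys are sorted group tuples (band order is not semantic). Fibers
with no detected bands leave the denominator. Percentages are integers
rounded half-away-from-zero; the 1/2/3-group multiplicity distribution is
reconciled to 100 by the largest-remainder method. This matters because the
printed per-pattern percentages do not sum exactly to their printed
aggregates: the two-group patterns sum to 72 against a printed "~74%", and
the myosin I+IIa patterns to 82 against "~82%" (83.3% on the realized
fixture counts). The package always reports recomputed totals next to the
approximate printed ones rather than forcing agreement.

The soleus myosin complements follow the per-lane description (under which
the I+IIa total is the printed per-pattern sum); the separately tabulated
reference map disagrees for the single-group {2} and {3} patterns, and
`check_association` surfaces exactly those two rows as mismatches instead of
silently preferring either source.

## Problem sizes and runtime

All deterministic analyses run on the packaged 16-variant catalog and the
48/41-fiber fixtures. Stochastic checks use 500 fibers × 20 seeds (10,000
fibers, ~15,000 bands), chosen so binomial standard errors are a few
percentage points — tight enough to expose systematic drift, large enough
for stable averages. The full test suite runs in a few seconds on one CPU.

## Known limitations

* Amino-acid sequences are not reconstructed (not available as inputs), so
  masses are delta-model estimates, not sequence sums; the ±0.5 kDa
  agreement with printed masses is the strongest available check.
* Phospho-site and interaction annotations are categorical splice-logic
  rules; human phosphorylation is homology-predicted, and no affinities are
  modeled.
* Localization of v5/v10 and the function of several unique NH2-termini are
  genuinely unknown and reported as `unknown`, never imputed.
* The catalog is *MYBPC1*-specific by design; nothing generalizes to other
  genes without a new architecture and catalog.
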
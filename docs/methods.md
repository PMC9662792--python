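# Methods

This note documents the models, rules and numerical choices behind
`tsrnakit`, what the synthetic-data generator does and does not emulate, and
the limitations a user should know before applying the pipeline to real
data.

## Coordinate frame and reference model

All classification happens on mature tRNA coordinates: introns removed, 5′
leader and 3′ trailer cleaved, 3′-terminal CCA present, positions 1-based
inclusive.  Sequences are stored in the DNA alphabet (U→T on load) so reads
and references compare directly.  The anticodon triplet is the single
landmark; when an annotation table is absent the anticodon is located as the
occurrence nearest to round(L/2) − 4 (ties toward 5′), a convenience
heuristic that an annotation row always overrides.  Mitochondrial tRNAs are
processed identically to cytoplasmic ones; origin is carried as metadata
only, and mitochondrially derived fragments stay in the catalog tagged with
their origin.

## What counts as a tsRNA

A tsRNA is a *distinct read sequence* placed somewhere in tRNA space — not a
(parent, interval) pair.  This matches how sequence-named catalogs
(tRF-Gly-GCC-038 and the like) are built, and makes multi-mapping within an
isodecoder family collapse naturally: all placements are kept, and a
deterministic primary placement (fewest mismatches, then 5′-most, then
lexicographically smallest parent id) fixes the name and type.  Counts are
integers; each read contributes to exactly one row.

Placement is a direct search against every reference tRNA (plus trailers),
exact by default (`max_mismatch=0`), optionally allowing one substitution.
If a sequence is unplaceable, 1–3 trailing characters forming a prefix of
CCA are trimmed and the search retried, to catch fragments that run past the
templated 3′ end into non-templated CCA.  The 14–40 nt analysis window
reflects the fragment population the pipeline is built for; out-of-window
reads are counted and excluded.

## Classification rules

The typing rule table is evaluated in fixed order (trailer → tiRNA-5 →
tRF-5 → tiRNA-3 → tRF-3 → tRF-2 → unclassified), which makes it a
partition: exactly one label per placement.  Boundaries are parameters of
`ClassificationRules`:

* **loop_halfwidth = 3** — the anticodon loop is anticodon ± 3 nt (9-nt
  window).  A fixed, testable boundary rather than a structure prediction.
* **tRF-5 bins ≤16 / 17–24 / ≥25 nt; tRF-3 bins ≤19 / ≥20 nt** — the
  subtype names are standard but published boundaries vary; these close the
  conventional ~14–16 / 22–24 / 28–32 ranges into a partition of the
  analysis window.
* **strict anchoring** — tRF-5/tiRNA-5 require start = 1 and tRF-3/tiRNA-3
  require end = L exactly.  Error-free synthetic reads justify the strict
  default; real data may warrant tolerance, which is why the rules object
  exists.
* **tRF-2** requires overlap of the anticodon triplet itself; internal
  fragments that miss it are `unclassified` rather than guessed.

Composition summaries (type shares, length distribution) are computed under
both species weighting (each distinct tsRNA once) and abundance weighting
(summed counts); abundance weighting is the default, since a >90% tRF-5c
share over a 586-species catalog with heavy-tailed expression is only
meaningful in abundance terms.

## Expression statistics

CPM is the only normalization: counts scaled to 10⁶ per sample.  "Expressed
in a group" means total group count ≥ 1 (configurable); the Venn partition
(normal-only / IUGR-only / shared) is taken over the detected catalog.
`top_share(k, group)` is the fraction of the group's mean CPM carried by its
k most expressed tsRNAs.

Differential expression is Welch's two-sample *t* on log2(CPM + 1), BH-FDR
across all tested tsRNAs, with log2FC computed on group-mean CPM with
pseudocount 1 (positive = higher in IUGR).  A call requires FDR < 0.05 and
|log2FC| ≥ 1, boundary inclusive — "fold change > 2" at a floating-point
boundary is declared inclusive rather than left ambiguous.  Rows with zero
counts everywhere are excluded; rows with zero variance in both groups get
p = 0 when the means separate and p = 1 otherwise (the *t* statistic is
undefined there, and those are the only defensible limits).  The statistic
is deliberately simple and isolated in one function; a count-model GLM can
be slotted in without touching the interface.  With n = 3 per group the
Welch variance estimate is itself noisy (2 df per group), so even strong
spikes occasionally produce p-values near the BH threshold; exact recovery
of every spike in every run is not a statistically achievable guarantee,
and the validation suite asserts recovery up to that small-sample miss
rate.

## Seed-based target prediction

The seed is positions 2–8 of the tsRNA (7-mer).  Candidate sites are exact
reverse-complement matches in the UTR — no wobble in the seed, overlapping
occurrences all reported.  Each site is scored by the minimum free energy
of the intermolecular duplex between the *full* tsRNA and the site plus
±15 nt of UTR context (windowing caps the DP size and mirrors the local
nature of miRNA-style hybridization).

The energy model is a reduced nearest-neighbor parameterization embedded as
plain data: ten Watson–Crick stack energies (expanded to all pair steps by
strand symmetry), a flat −1.2 kcal/mol term for steps involving G·U, an
affine loop penalty 3.0 + 0.45·(unpaired nt) for bulges and internal loops
(bounded at 15 unpaired nt per strand), and a 2.5 kcal/mol duplex
initiation charged once.  The initiation term is deliberately smaller than
the strongest stack so that even a minimal two-pair duplex is reportable.
These are package parameters, not measured constants: swap the table to
change the model.  The dynamic program minimizes over all antiparallel pair
sets with bounded loops, allows no intramolecular structure or pseudoknots,
returns (0, empty) when nothing scores below zero, and produces a traceback
that re-scores exactly to the reported energy.  It is validated against an
independent exhaustive enumerator on random sequence pairs.

The default reporting cutoff is −15 kcal/mol.  Under this model a bare
7-mer seed duplex scores about −8 kcal/mol, so the cutoff demands pairing
beyond the seed — which is what the planted sites (22-nt complements)
provide and what a biologically plausible site should provide.

Pearson correlation (phenotype vs expression) uses the *t* transform with
n − 2 df, two-sided.  Gene-set enrichment is an upper-tail hypergeometric
test of target genes against user-supplied GMT sets intersected with a
user-supplied universe, BH-adjusted across sets; no bundled GO/KEGG data.

## The synthetic-data generator

The generator's defaults are the study conditions the pipeline is validated
against: 586 distinct fragments, 103 normal-only and 38 IUGR-only members,
221 distinct seeds, tRF-5c carrying 0.92 of abundance, 0.80 of abundance at
31–32 nt, a normal-group top-ten share of 0.8916 (with the top two
fragments above 0.75 and the top four near 0.8146), 19 down / 9 up spiked
8-fold changes, 3 replicates per group, 2×10⁶ reads per sample.  Depth is
not reported per sample by typical studies; 2×10⁶ is a realistic small-RNA
library size and makes the floor abundance (3×10⁻⁵) correspond to ~60
expected reads, so detection of every planted fragment is essentially
certain.

Construction facts the defaults exploit:

* Every 5′-anchored fragment of one parent shares the parent's positions
  2–8, so the seed-group count is (# parents with 5′-anchored fragments) +
  (# non-5′ fragments, whose seeds are rejection-sampled to be unique).
  The default solves 221 = 121 parents + 100 non-5′ species.  Generated
  references keep positions 2–8 pairwise distinct, which also makes 40-nt
  5′ prefixes distinct and parent assignment unambiguous.
* The 31–32 nt mass is carried entirely by tRF-5c fragments; other classes
  draw lengths outside 31–32.  Type mixture and length mass can then both
  hold exactly by rescaling within (type × length-band) cells.  When a
  top-share target is set, a final cell-preserving rescale makes the
  normal-group top-ten share exact while leaving cell masses — hence the
  type and length composition — essentially untouched.
* References are drawn 70–80 nt with the anticodon at 36–38, inside the
  canonical ranges, so that 25–34 nt tRF-5, 33–40 nt halves and all other
  classes are constructible on every parent.
* Spiked fragments are shared members placed where multinomial counting
  noise is negligible against the replicate jitter on both sides of an
  8-fold change (down-spikes near 1.2×10⁻³ baseline, up-spikes near
  3.5×10⁻⁴), with the released and gained mass roughly balancing so the
  IUGR profile keeps the planted composition.
* Group-exclusive members are taken from the lowest-abundance tail — they
  exist to be detected, not to carry mass.

Replicate noise is lognormal on abundance with `noise_sigma` the standard
deviation of per-replicate **log2** abundance (default 0.1), the same scale
the DE statistic operates on; per-sample counts are a single multinomial
draw of the configured depth over the jittered, renormalized profile.
Reads are exact fragment sequences with constant quality ("I"); a
configurable substitution rate exists but defaults to 0.

Planted UTRs carry the reverse complement of the tsRNA's 5′ prefix (22 nt
by default), which contains the seed's reverse complement exactly once;
background UTRs are rejection-sampled to contain no listed seed complement
at all.  Planting a full prefix rather than a bare 7-mer makes the planted
site clear the −15 kcal/mol cutoff, so planted-target recovery is exact by
construction.

What the generator does **not** emulate: sequencing error profiles and
quality variation, adapter contamination, RNA modifications and the
ligation/RT biases they cause, non-tRNA background reads, overdispersion
beyond lognormal jitter, and batch structure.  Passing recovery tests on
this data therefore demonstrates the pipeline's correctness on clean,
in-model input — not robustness to the artifacts of real libraries, where
modification-driven mismatches and truncations in particular would require
mismatch-tolerant placement.

## Validation protocol and problem sizes

The acceptance workflow runs two studies end to end (simulate → FASTQ →
collapse → place → classify → count → summarize): the full composition
(586 fragments, 6 samples × 2×10⁶ reads) for catalog/Venn/composition/
seed/top-share recovery, and a spike-recovery variant without
group-exclusive members — with both subsets planted, the group-exclusive
fragments are genuinely differentially expressed (present in one group
only) and would dominate the call set, so spike recovery is measured
without them.  Property suites cover the classification partition
(exhaustive sweep over all placements of a 76-nt fixture against an
independently coded oracle), DP-vs-enumeration equality for the duplex
model, placement against a brute-force scan, BH/Pearson/hypergeometric
hand oracles, and seeded determinism of every generator output.

## Known limitations

* Exact-match placement (default) will miss modified or edited fragments;
  one-mismatch mode exists but is O(reference × length) per sequence.
* The DE statistic ignores count overdispersion structure; with 3
  replicates per group its power is limited by the Welch variance estimate
  (see above).
* The energy model is reduced: no dangling ends, no terminal AU penalty,
  no length-dependent loop asymmetry; MFE values are comparable within this
  model but not to full Turner-model tools.
* Seed matching is exact 7-mer complement only; wobble seeds, 6-mer and
  offset sites are not considered.
* tRF-1 detection requires trailer sequences in the annotation table;
  references without trailers yield no tRF-1 calls.
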
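# Methods

This note records the models, conventions and parameter defaults behind
`clampkit`, and the rationale for each choice. Everything stated here about
numbers is computed by the package itself; nothing is an external empirical
claim.

## Sequence model and coordinates

Sequences are IUPAC-degenerate DNA strings (`DegenerateSequence`), validated
and upper-cased on construction; gaps (`-`) are admitted only for explicitly
aligned inputs. Two symbols are *compatible* when their expansion sets
intersect (W vs A matches; R vs Y does not); a *mismatch* between equal-length
strings is a column whose expansion sets are disjoint. This is the correct
semantics for both degenerate primers and degenerate consensus clamps: a W in
the clamp genuinely pairs with either A or T templates.

All internal coordinates are 0-based half-open on the plus strand
(`PrimerSite(start, end, strand)`); a minus-strand site's 3'-end position is
`start`. Human-readable reports are 1-based inclusive and say so in a
`# coord_system` header line.

## Clamp window geometry

Candidate clamp windows are anchored on the template position paired with the
primer's 3'-terminal base. `offset_upstream` counts bases strictly 5' of that
position (on the primer's strand); the 3'-end base itself opens the
`offset_downstream` run, so `length = offset_upstream + offset_downstream`.
Field descriptions often count the 3'-end base as upstream; `describe_candidate`
prints both idioms (a 10+6 window is described as "11 bp upstream / 6 bp
downstream"). The scanned search region defaults to 27 bases upstream and 6
downstream of the anchor; window lengths default to 14–18 with downstream
offsets 0–10.

## Selection criteria

For each window the package records four flags (all evaluated even when one
fails):

1. **host_conserved** — the degenerate consensus over all host search regions
   has zero mismatches against every host and at most `max_degeneracy`
   (default 2) degenerate columns. Degeneracy absorbs host polymorphism; an
   N-only column (missing data) is flagged as a wildcard but not counted as
   polymorphism.
2. **exclusion_divergent** — minimum mismatch count against every exclusion
   sequence is at least `min_exclusion_mismatch` (default 3). An empty
   exclusion set leaves the flag `None` (not evaluable), which prevents a
   candidate from "passing" vacuously.
3. **tm** — the selected Tm estimate (default the PNA estimate) exceeds
   `tm_min` (default 70 °C). For degenerate sequences the default policy is
   `min`: the worst expansion governs the threshold (conservative).
4. **selfcomp** — self-complementarity score ≤ 8 and hairpin stem ≤ 4.

Ranking: passing candidates first; within each block by descending exclusion
mismatch, descending Tm margin, ascending self-complementarity, ascending
degeneracy, most-upstream first; ties keep input order (stable sort).

When locating the primer in *exclusion* sequences the mismatch allowance is
`primer_max_mismatch + min_exclusion_mismatch` (default 2 + 3 = 5), because
the clamp window overlaps the primer footprint and exclusion taxa are
expected to diverge exactly there while remaining amplifiable.

## Thermodynamics

- **DNA/DNA Tm** (`tm_nearest_neighbor`): nearest-neighbor model with the
  unified parameter set (ΔH in kcal/mol, ΔS in cal/(mol·K), ten dimer terms
  plus A/T and G/C initiation and a symmetry term), transcribed by hand into
  `DNA_NN_UNIFIED`. Salt correction adds 0.368·(N−1)·ln[Na+] to ΔS;
  Tm = 1000·ΔH / (ΔS + R·ln(CT/x)) − 273.15 with R = 1.9872 cal/(mol·K) and
  x = 4 for non-self-complementary duplexes (x = 1 plus the symmetry term for
  palindromes). Defaults: [Na+] = 1.0 M, CT = 2 µM — high-salt hybridization
  conditions under which clamp Tm values are customarily quoted. The
  implementation agrees with biopython's independent `Tm_NN` (DNA_NN3,
  saltcorr 5) to better than 0.05 °C on random sequences; this cross-check is
  part of the test suite.
- **PNA Tm** (`tm_pna_estimate`): the empirical linear regression
  `Tm_PNA = 20.79 + 0.83·Tm_NN − 26.13·f_pyr + 0.44·L`, where `f_pyr` is the
  pyrimidine fraction and `L` the length. PNA duplexes are insensitive to
  ionic strength, hence a regression on the DNA NN value rather than a salt
  model.
- **LNA Tm** (`tm_lna_estimate`): the DNA NN value plus a per-substitution
  increment (defaults +3.0 °C for A/T, +5.0 °C for C/G positions, mid-range
  of published increment tables). The substitution pattern of a synthesized
  LNA oligo is a vendor design choice, so positions are an explicit argument.
- **Self-structure**: `self_complementarity` is the maximum number of
  Watson–Crick pairings over all antiparallel alignments of the sequence with
  itself (a base never pairs with itself at the same index);
  `hairpin_score` is the longest contiguous self-pairing stem with a loop of
  at least 3 nt.

All constants live in a frozen `ThermoParams` dataclass with JSON round-trip
(`to_file`/`from_file`), so non-default conventions are reproducible.

### Known limitation: published clamps vs. the 70 °C default

Published clamp oligos are sometimes reported with Tm values from proprietary
vendor calculators. Under this package's documented defaults, the packaged
16-mer tick clamp (`primers.TICKB`) computes Tm(DNA) = 55.2 °C and
Tm(PNA) = 63.9 °C — below the 70 °C default threshold. The package reports
such numbers as computed rather than adjusting coefficients to flatter any
particular oligo; users comparing against vendor values should load the
vendor's constants into `ThermoParams`.

## In-silico PCR and blocking

`insilico_pcr` pairs every plus-strand forward site with every minus-strand
reverse site 3' of it, within `max_len`; the amplicon span includes both
primer footprints. `nested_pcr` restricts inner-primer matching to
first-round amplicon spans (nesting can only remove predictions, never add).
`blocking_prediction` scans both strands of an amplicon for the clamp's
best-matching window and flags the amplicon blocked when the minimum mismatch
count is ≤ `max_block_mismatch` (default 1 — clamps tolerate roughly one
mismatch before losing suppression). `community_coverage` partitions each
taxon's sequences into amplifiable / blocked / no-site fractions. Primers
longer than 25 nt trigger an adapter-tail warning in the CLI (`--trim-tail`
keeps only the 3' bases).

## Count-table statistics

- **Non-host proportion**: fraction of reads whose lineage string does not
  start with the host prefix; NaN for empty samples.
- **Enrichment**: the method sample's non-host proportion divided by its
  matched same-individual control's. A zero or undefined control proportion
  makes enrichment undefined; such samples are flagged `excluded` with a
  reason and dropped from summaries instead of raising.
- **Pairwise proportion tests**: per-pair 2×2 chi-square with Yates
  continuity correction (via `scipy.stats.chi2_contingency`), Bonferroni
  multiplied by the number of pairs — the convention of R's
  `pairwise.prop.test`. Degenerate margins give p = 1; zero-total groups NaN.
- **Alpha diversity**: Shannon with natural log over nonzero taxa; observed
  variants; Faith's PD as the branch length of the minimal subtree connecting
  the present tips to the root (rooted by default, the convention of the
  common amplicon pipelines; `include_root=False` drops the MRCA-to-root
  chain).
- **Blocking-assay fluorescence**: per-trial normalisation to the no-blocker
  control (control ≡ 1.0), then per-dose mean/SD/n; trials with a zero or
  missing control reading are flagged and dropped.
- **Detection grids**: sample × method cells hold sets of taxon codes (the
  packaged grid covers seven apicomplexan codes over 17 tick samples and six
  methods); `detection_summary` counts, per code, the samples with at least
  one detection under any method.

## Synthetic-data generator

`fixtures` emulates the *input structure* of a clamp-design study — not any
particular organism's sequence:

- A host family shares one backbone (random insert between concretized
  universal primers at a configurable GC content) with `n_haplotypes`
  haplotypes realised by planted alleles at configured clamp-window columns
  (default: one A/T column at window index 6, the analogue of a W-absorbed
  polymorphism).
- The exclusion sequence is the backbone with substitutions at exactly the
  configured window positions (default 8, 9, 15), each chosen incompatible
  with every host allele at that column; inside the primer footprint the
  substitution must remain primer-compatible, because a real exclusion taxon
  is still an amplification target.
- The backbone is rejection-sampled (≤ 5000 draws within the single seeded
  stream) until the planted window is admissible under the default design
  thresholds and each haplotype carries exactly one forward and one reverse
  primer site. The generator's contract is "exactly one designed site with
  known truth"; rejection sampling enforces the contract without altering any
  threshold.
- Count tables place per-method non-host read counts by rounding target
  proportions to the nearest read (targets are exact multiples of
  1/total_reads, so recovery is exact), split reads uniformly across host and
  non-host lineages, and optionally add one individual whose control library
  holds only host reads — exercising the zero-control exclusion rule.
- All randomness flows from one integer seed through
  `numpy.random.default_rng` / `SeedSequence` spawns; identical specs yield
  byte-identical files.

## Numerical and testing choices

Every non-trivial computation has an independent oracle in the test suite:
naive expansion-intersection mismatch counting, exhaustive both-strand primer
scanning, exhaustive antiparallel-offset self-complementarity, closed-form
window enumeration, exhaustive PCR site pairing, an independent
edge-subtending traversal for Faith's PD, the literal textbook Yates formula
(with the correction clamped at zero, matching scipy), and biopython's Tm
implementation. Property-based tests (hypothesis) cover involutions,
symmetries and count conservation. Determinism is asserted byte-for-byte on
generator outputs.
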
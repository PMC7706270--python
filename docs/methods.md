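# Methods

`otscan` implements the computational side of amplification-free,
Cas9-enrichment long-read off-target sequencing: an enzyme loaded with a
guide RNA digests randomly sheared genomic DNA in vitro, cleaved molecules
are preferentially ligated/captured and sequenced, and the cut sites are
recovered from the alignment pattern they leave — many reads starting or
ending at the same reference coordinate.

## Cleavage-peak detection

Reads are reduced to `(ref_start, ref_end)` endpoint events; every primary
alignment contributes exactly one start and one end. Random shearing makes
background endpoints approximately uniform, so the count of endpoints at a
single position is well modelled as Poisson with a local rate.

For each position `p` with combined count `c(p) = starts(p) + ends(p)` the
caller requires both

1. `c(p) >= min_support`, and
2. `P[X >= c(p)]  <  p_threshold` for `X ~ Poisson(lambda(p))`, with
   `lambda(p) = max(lambda_floor, (endpoints within +-flank of p, excluding p) / (2 * flank))`.

Starts and ends are pooled into one statistic because adapter ligation is
less efficient on the 5' side of the guide (the enzyme stays bound after
cleavage), so either side alone may carry most of the signal.
Significant positions within `merge_distance` of each other are
single-linkage merged — nanopore cut calls can be fuzzy over a 10–20 bp
interval — with the representative position at the member with the largest
combined count (leftmost on ties). The peak height is the number of
distinct reads with an endpoint inside the merged interval, and the strand
balance is the fraction of those reads lying 3' of the cut.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `min_support` | 4 | At 30x coverage of 8 kb fragments the per-position endpoint rate is ~0.0075, so `P[X >= 3] ~ 7e-8` per position — about 0.07 expected false candidates per Mb and a ~7% chance per Mb run of at least one false peak. Requiring 4 pushes this to ~1e-4 per Mb while real cut sites carry 15+ coincident ends. |
| `p_threshold` | 1e-5 | Genome-scale multiplicity: ~3e9 tested positions x 1e-5 would still be large were it not for the `min_support` conjunction; the two together control the false-peak rate. |
| `flank` | 2000 bp | Wide enough to estimate the local shear rate stably, narrow enough to track coverage fluctuations. |
| `lambda_floor` | 0.02 | Guards the Poisson test against near-zero local rates in sparsely covered regions. |
| `merge_distance` | 20 bp | Covers the observed nanopore positional fuzz. |
| `min_mapq` | 10 | No mapping-quality filter is inherent to the assay; a modest one suppresses multi-mapping noise while keeping "dark region" sites where long reads align uniquely. |

Optional pre-smoothing (`smooth`, default off) pools counts over
`[p - w, p + w]` before testing, scaling `lambda` by the window width.
Peaks within 100 bp of a contig edge are flagged, not dropped.
Downsampling draws a uniform sample without replacement over reads sorted
by `(ref_start, read_id, ref_end)`, so the selection is independent of
file order and reproducible per seed.

## Guide assignment

The reference sequence is extracted in a +-40 bp window around each cut
(`[pos - 40, pos + 41)`, 81 bp). Windows containing any `N` are dropped
(`contains_N`), as are windows truncated by a contig edge (`edge`): only
high-quality, gap-free reference is searched for guide similarity.

Each guide is aligned against both strands of the window by global
Needleman–Wunsch with free end gaps, using the classic DNA defaults of the
EMBOSS-Needle aligner: match +5, mismatch −4, affine gaps with
`cost(L) = gap_open + L * gap_extend` = `10 + 0.5 L` (the opening move
costs 10.5, each extension 0.5), terminal gaps free. Alignments scoring
**strictly above 55** are kept.

The query is the 20-nt spacer plus its 3-nt PAM pattern with `N` scored as
a +5 wildcard (23 informative positions). With this query, `k` internal
substitutions score `115 − 9k`, so up to six substitutions pass the
threshold. A bare 20-mer query would score exactly 55 at five
substitutions and fail the strict rule — yet five-mismatch off-targets are
real, detectable sites — which is why spacer+PAM is the default
(`--query-mode spacer` preserves the alternative). Among co-optimal
alignments the traceback prefers diagonal moves, then gaps in the window,
then gaps in the query; the score, not the path, is the tested contract.

Mismatches are decomposed over spacer columns only: substitutions
(aligned, unequal, non-`N`), insertions (guide base opposite a gap — the
genome lacks that base) and deletions (window base opposite a gap internal
to the spacer — the genome has an extra base). Sites are classed `exact`,
`snv_1_3` (1–3 substitutions), `snv_ge4` (>= 4, no indels) or
`indel_mismatch` (any indel). The observed PAM is matched against the
guide's IUPAC pattern; when it fails, the +1-shifted triplet is also
tested and reported as a rescue (non-canonical PAMs with a canonical
triplet at the next position occur at real sites). Nothing is ever
filtered on PAM status. The predicted blunt cut is placed `cut_offset`
(default 3) bp 5' of the PAM, strand-aware; all cut coordinates are the
boundary index — the first base 3' of the cut on the forward strand — in
0-based half-open convention throughout.

## Catalogue comparison

Two catalogues are matched one-to-one, greedily by ascending distance,
with candidates restricted to same-contig pairs within `tolerance`
(default 30 bp: the nanopore fuzz of up to ~20 bp plus slack). When both
sides carry guide labels a match also requires label agreement. Matching
is symmetric in its counts, monotone in the tolerance, and `A` vs `A` is
the identity. Combined per-site read counts (sum of the two peak heights
for matched pairs, single height otherwise) are reported in descending
order. External predicted catalogues are consumed as BED only; the same
matcher partitions detected and predicted sites with explicit
numerators/denominators.

## Editing analysis

Around each investigated site, the per-position percentage of covering
reads with an indel **starting** there is computed in a +-2 kb window,
separately for the edited and the unedited sample, and subtracted
(edited − wild-type). Anchors follow pileup semantics: an insertion is
anchored to the base immediately left of the inserted sequence, a deletion
to its leftmost deleted base; a multi-base deletion contributes only at
its start. Positions with zero coverage are NaN, never interpolated. The
per-read definition was chosen over a per-pileup-base alternative because
it is the quantity the delta plots actually show; both were defensible.

Editing efficiency is **this package's own estimator** (published
experiments report ranges without a formula): the fraction of
edited-sample reads carrying >= 1 indel starting within +-`core`
(default 20) bp of the cut, minus the same fraction in the wild-type
sample. Only reads spanning the full +-`core` window count, preventing
edge-truncation bias in amplicons. The estimator has a small negative
multiplicative bias of order `rate x P(error indel in the core window)`
(~2–4% relative at HiFi error rates) because a read edited *and* hit by a
background error is counted once in both samples' numerators.

Read-level large indels (length >= `min_len`, default 50; use 51 for a
strict "longer than 50 bp" rule) inside the window are clustered by kind,
position within +-10 bp and length within +-10%; the clustering tolerances
are this package's choice — dedicated SV callers are deliberately not
reproduced.

Allele-specific cleavage is tested with the exact two-sided binomial test
(minimum-likelihood definition, `scipy.stats.binomtest`) of the observed
alt-read count against the genomic alt fraction, flagged at `alpha = 0.01`
with Benjamini–Hochberg correction when several sites are tested at once.

## Simulator

The generator emulates the enrichment assay end to end at desk scale and
is itself first-class, tested code:

- **Genome**: i.i.d. bases at a configurable GC fraction (default 0.41,
  human-like), with protospacer+PAM sequences planted at exact, recorded
  loci on either strand, carrying declared substitution / insertion /
  deletion counts. Mutations are placed at spaced interior spacer
  positions and re-verified against the aligner in their actual genomic
  context, with redraws until the optimal alignment reports exactly the
  declared decomposition — a mismatch at the spacer's 5' edge, clusters of
  edge mismatches, or mutations near a repeat can otherwise be absorbed
  into free terminal gaps or an alternative gap placement, making the
  planted truth ill-defined.
- **Shearing**: fragments are independent draws (uniform start, lognormal
  length; presets 8 kb SMRT-like and 20 kb Nano-like, log-sd 0.35), not a
  partition of the genome — a partition would plant a coincident
  start/end pair at every shear breakpoint, which sparse single-molecule
  sampling does not produce.
- **Cleavage and capture**: a fragment spanning a planted cut is split
  there with the site's cleavage efficiency (allele-aware when a
  heterozygous SNV modulates binding: the fragment's allele is drawn at
  the genomic alt fraction and the allele-specific efficiency applies).
  The 3'-side piece is retained with probability `side_bias` (default
  0.8) and the 5'-side piece with the complement, reproducing the
  one-sided read distributions seen at real cut sites; pieces between two
  cuts are always retained; uncleaved fragments leak through capture with
  `p_background_retained` (default 0.05). Capture chemistry is reduced to
  this single leak probability, deliberately not modelled mechanistically.
- **Errors**: CIGAR-level indel events only (per-bp rates; HiFi-like
  0.2% indels, nanopore-like 3%; amplicon CCS-like 0.03% ins / 0.07% del),
  geometric lengths, no base-quality model and no substitution CIGAR
  effect (substitutions do not move alignment endpoints). Overlapping
  events are sanitized so every read has a single consistent CIGAR.
- **Amplicons**: edited reads carry one repair outcome per molecule — a
  cut-anchored NHEJ indel with probability `edit_rate` (geometric length,
  mean 5 bp, anchor jitter +-3 bp) or, when configured, a vector-like
  large insertion at its own rate, which pre-empts the small indel.
  Wild-type reads carry only error indels.

Reads are emitted as coordinate-true SAM (no re-alignment step), with a
per-read truth table (origin site, endpoint-at-cut, allele). All
randomness flows through a single `numpy` generator per call, seeded
explicitly; identical (config, seed) gives byte-identical output files.

### What the simulator does not emulate

Base qualities and raw signal; basecaller-specific artefacts; alignment
ambiguity in repeats (reads are coordinate-true by construction, so
peak-caller results on simulated data bound what a perfect aligner would
allow, not what a real aligner achieves in dark regions); chromatin or
concentration effects on cleavage; PCR bias (the assay is
amplification-free, but the amplicon module's long-range PCR step is also
not given a bias model). Passing tests therefore demonstrate the
correctness and calibration of the statistics under the stated generative
model, not end-to-end performance on real sequencing runs.

## Study conditions used by the test suite and acceptance script

Chosen once as desk-scale versions of the assay's conditions: null
calibration on 20 x 1 Mb runs at 30x with full background retention;
recovery of 10 planted sites (substitution counts 0–6, indel mixes,
cleavage efficiencies 0.5–1.0, both strands) per run over 20 seeds on
200 kb genomes at 30x enriched coverage; editing recovery at
`edit_rate ∈ {0.1, 0.3, 0.6}` with 500 reads per sample over 20 seeds;
allele-specific preset with efficiencies 0.1/0.9 at alt fraction 0.5 and
60x coverage. The alignment oracle is an independently coded
gap-length-enumeration (Waterman–Smith–Beyer style) full-matrix DP.

## Known limitations

- The detection statistic of the original in-house peak caller is
  unpublished; this package's Poisson rule is calibrated on the simulator
  and makes no claim of call-for-call agreement with that tool.
- Reported editing-efficiency values are estimator-specific and cannot be
  compared to published ranges computed by unknown formulas.
- Mismatch decomposition of real off-target sites adjacent to repeats or
  G-runs can be non-identifiable (several co-optimal explanations); the
  reported decomposition then follows the documented traceback preference.
- BED output truncates peak heights at 1000 for format validity; the TSV
  report keeps full values.
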
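# Methods

## Model and rationale

Plant pri-miRNAs are mostly RNA polymerase II transcripts: polyadenylated,
hence present in assembled transcriptomes and — crucially — visible to
degradome sequencing, which captures the 5' ends of 3' cleavage remnants of
poly(A)⁺ RNA. Dicer-like maturation cuts the pri-miRNA at the boundaries of
the miRNA/miRNA* duplex, so the remnants' 5' ends fall at four predictable
positions: the 5' ends of the 5p and 3p matures and 1 nt downstream of each
mature's 3' end. `plantmir` predicts hairpin candidates from sRNA read
patterns and secondary structure, then uses degradome tags at those four
positions as independent processing evidence.

All coordinates are 1-based with inclusive intervals. All sequences are
handled in the RNA alphabet (T→U at ingest); reads containing N are dropped
because every downstream comparison is exact-match.

## Pre-treatment

* sRNA reads are collapsed to unique sequences and filtered to 15–40 nt,
  both bounds inclusive. The RPM denominator is the number of reads
  retained after this filter, which makes the per-library identity
  Σ RPM = 10⁶ exact and testable.
* Degradome reads keep only their 5' 20-nt tag (adjustable); reads shorter
  than the tag length are discarded, reads of exactly the tag length are
  kept. Tag RPM is recomputed over retained tags. Whether degradome
  libraries should be re-normalized after truncation is a genuinely open
  choice; normalizing over retained tags keeps the Σ RPM identity uniform
  across library roles.

## Conservation

The conserved-read scan uses exact sequence identity against the registry —
the conservative, reproducible reading of a registry lookup; length-variant
isomiRs of a registered mature therefore do not count as conserved.
Predicted matures are additionally classified by minimum global edit
distance (unit costs, computed with edlib and cross-checked in tests
against a dynamic-programming oracle): identical (0), similar but not
identical (1..3), novel (>3). The threshold 3 captures close variants of a
known family while excluding unrelated 21-mers (two random 21-mers are
essentially never within distance 3). Family labels are parsed from
miRBase-style identifiers by stripping the species prefix, letter suffix,
paralog number and arm designation; unparseable identifiers keep their full
id and are flagged. Ties among equally near references resolve to the
lexicographically smallest family label for determinism. The packaged plant
species allowlist covers the Viridiplantae prefixes of the mature registry
and is user-overridable.

## Discovery

**Mapping** is exact and ungapped on both strands; antisense hits are kept
and candidates evaluated in the mapped (read) orientation, since an
assembled transcript may be antisense to the miRNA gene. Multi-mapping
reads contribute their full count at every locus — no fractional
allocation — which is conservative for peak calling on the transcript
scale this pipeline works at.

**Excision.** Expression peaks are read start positions whose summed count
is maximal within a 25-nt neighbourhood, accepted most-abundant-first with
a minimum separation of 50 nt per strand. Each peak emits two window
hypotheses — the peak read on the 5p arm (`[start−20, read_end+230]`) or on
the 3p arm (`[start−230, read_end+20]`) — clipped to the transcript. The
flank of 230 nt plus edge of 20 nt covers the plant precursor length range
up to the 500-nt cap while keeping folds local.

**Folding** delegates to the ViennaRNA minimum-free-energy model; the
contract used downstream is only: balanced dot-bracket of the same length,
MFE ≤ 0.

**Star derivation.** From the pair table of the folded window, the star of
a mature `[s, e]` follows the canonical Dicer geometry in which each
strand's 3' end extends 2 nt beyond the last base paired to the other
strand: `star_end = partner(first paired position ≥ s) + 2` and
`star_start = partner(last paired position ≤ e−2)`, with nearest-paired
fallbacks across mismatches and clipping to the precursor. The star is
absent when fewer than half the mature positions are paired, when the
mature spans the terminal loop (its bracket run changes direction), or when
the derived interval would overlap the mature.

**Rule set.** The hairpin verdict is the conjunction of seven explicit
rules (each user-adjustable, each recorded by identifier on failure):
mature length 20–24 (r1); star derivable (r2); ≤ 5 unpaired mature
positions within the duplex, the 2-nt 3' overhang excluded (r3); bulge
asymmetry — the difference between unpaired counts on the two duplex
strands — ≤ 3 (r4); precursor ≤ 500 nt (r5); MFE < 0, so a pairless window
fails (r6); and ≥ 75 % of window-mapped read abundance inside mature ± 3,
star ± 3, or the loop between them (r7). The mature is the most abundant
read stack in the window (ties: 5'-most, then lexicographic). An explicit
rule set was chosen over a probabilistic score so that every rejection is
inspectable and every threshold is a config key.

Overlapping windows that localise the same read-supported mature collapse
to one locus; among them the kept candidate is the one whose derived star
interval itself carries the most read support (then the widest window).
This resolves the ±1-nt star wobble that different fold contexts can
produce.

**pri-miRNA assembly** lifts a passing candidate back to its host
transcript and extends it 20 nt (adjustable) on the 3' side *in read
orientation* — downstream for sense candidates, toward lower transcript
coordinates for antisense ones. The extension exists so that degradome
tags starting at `after_end3p` have transcript sequence to map onto; the
structure track is padded with unpaired positions over the extension.

## Degradome validation

Tags are mapped to the sense strand of the pri-miRNA only: degradome reads
are fragments of the pri transcript itself, so antisense hits carry no
meaning here. A site is supported when a tag's 5' end lies within
`tolerance` nt of it (default 0 — site coincidence is treated as exact; ±1
is exposed as a config key) and the summed RPM exceeds `min_rpm` (default
0). Distinct tags at one site aggregate by summing counts and RPM.
Single-arm candidates get a two-site set rather than being excluded:
partial evidence is labelled, not hidden. A site's signal is not required
to be a local maximum along the pri; any exact-position tag supports.

## Synthetic scenarios

The generator emulates the features the pipeline keys on, from the duplex
outward: a random 5p mature (21 nt default), a 3p arm that is the reverse
complement of the 5p duplex core with a configurable mismatch count
(default 1), both placed with the 2-nt 3' overhang geometry, an A/C-only
loop (15 nt default; A and C cannot pair with each other, keeping the loop
open), random 30-nt flanks, and random transcript context of 40–80 nt per
side. Every draw is *confirmed*: the construct is folded and the star
re-derived, and at scenario level the discovery stage is run on clean reads
twice — once with each arm dominant, because the dominant arm decides which
windows are excised — requiring exact recovery of both planted intervals.
Draws that fail are redrawn (bounded at 50 attempts), so the truth manifest
is guaranteed rather than merely intended.

sRNA libraries draw signal reads from the planted matures (per-hairpin
5p:3p ratio uniform in 0.25–0.75, start jitter ±1 nt with probability 0.1)
and background reads as random 15–40-nt transcript substrings, multinomial
at the requested depth (default 50 000, signal fraction 0.8). Degradome
libraries place tag 5' ends exactly at a per-scenario choice of
`sites_per_pri` of the four expected sites; the choice is drawn once per
scenario so that multiple libraries reinforce the same sites. Background
degradome reads are rejection-sampled away from all planted sites, so a
scenario that plants k sites yields exactly k supported sites — the
property the closed-loop tests assert.

What the simulation does *not* model: sequencing errors, adapters,
expression-level realism, isomiR distributions, RNA editing, or hairpins
overlapping each other. Passing tests therefore demonstrate the pipeline's
internal consistency and geometric correctness, not its false-negative
rate on real tissue libraries.

## Problem sizes and determinism

The default test and acceptance conditions use 10 planted hairpins, 2 decoy
transcripts, 3 libraries × 50 000 sRNA reads (80 % signal), and 2 000
degradome reads per library at 3 of 4 sites — enough for every arm stack to
dominate its window by a wide margin while keeping a full run around ten
seconds. All randomness flows from explicit seeds through per-purpose
streams; tables are sorted (sequences lexicographically, coordinates
ascending) and floats written with fixed formats, so repeated runs are
byte-identical in every TSV/JSON output. Figures are presentation only;
tests and downstream tooling read the JSON sidecars.

## Known limitations

* Exact-match mapping means a single SNP between library and assembly
  silences a locus; mismatched mapping is deliberately out of scope.
* Candidates without a derivable star (single-arm evidence) are rejected
  (r2), which undercounts loci where the star decayed — the trade-off for
  requiring duplex geometry.
* The conserved scan's exact-identity rule misses isomiR-shifted copies of
  registered matures.
* Degradome support is necessary-style evidence, not proof: a tag can
  coincide with a site by chance, and decoy loci occasionally pass the
  hairpin rules with weak site support (the summary's 0–4 grading is the
  intended readout, not a binary verdict).
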
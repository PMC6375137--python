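# plantmir

Discovery and degradome-based validation of plant microRNAs from assembled
transcripts and small-RNA sequencing data — no reference genome required.

## The problem

Plant miRNA prediction from sRNA-seq rests on two signals: a precursor that
folds into a stem-loop, and reads that pile up on the miRNA-5p/miRNA-3p arms
of that stem. Both signals can be mimicked by other loci, especially for
young or species-specific miRNAs. Because most pri-miRNAs are RNA polymerase
II transcripts with poly(A) tails, their Dicer-like processing intermediates
are visible to degradome sequencing (PARE): each cut leaves a remnant whose
5' end sits at a predictable position. `plantmir` uses this third, orthogonal
signal to check predictions. On a pri-miRNA carrying both mature arms, four
**processing sites** are expected:

```
start5p      = mature5p start          after_end5p = mature5p end + 1
start3p      = mature3p start          after_end3p = mature3p end + 1
```

A degradome tag whose 5' end coincides with one of these positions is a
processing signature; the count of supported sites (0–4) grades the
reliability of each candidate.

## What the pipeline does

1. **Preprocess** — collapse FASTA/FASTQ reads to unique sequences, keep
   sRNAs of 15–40 nt (inclusive, adjustable), normalize to RPM
   (reads per million retained reads, so each library sums to 10⁶). Degradome
   reads are reduced to their 20-nt 5' tag; shorter reads are discarded.
2. **Conservation** — scan reads for exact identity to a plant mature-miRNA
   registry (miRBase mature-FASTA dialect, filtered by a packaged plant
   species allowlist), and classify predicted matures by minimum global edit
   distance *d*: identical (*d* = 0), similar but not identical
   (1 ≤ *d* ≤ 3), or novel.
3. **Discovery** — map reads exactly to both strands of the transcripts,
   excise candidate windows around expression peaks, fold each window to its
   minimum-free-energy structure (ViennaRNA), and apply an explicit plant
   hairpin rule set: mature length 20–24 nt, a star arm derivable under the
   canonical 2-nt 3' overhang duplex geometry, ≤ 5 unpaired mature positions,
   bulge asymmetry ≤ 3, precursor ≤ 500 nt, negative folding energy, and
   ≥ 75 % of the window's read abundance on the arms. Passing candidates
   become pri-miRNAs with a 3' 20-nt host-transcript extension (so tags at
   the 3'-most site have sequence to map onto).
4. **Validation** — map degradome tags (exact, sense strand) onto each
   pri-miRNA and call which expected sites have tag support.
5. **Reporting** — a summary table of mature arms with conservation and
   per-library RPM; per-position coverage histograms with the dot-bracket
   track and yellow mature bands; structure drawings with green (5p) and red
   (3p) arms and blue circles at supported sites. Every plotted series is
   duplicated in a JSON sidecar.

A seeded synthetic-scenario generator (`plantmir.simulate`) plants hairpins
with known coordinates into random transcripts and simulates sRNA and
degradome libraries, so the full loop is testable without downloads.

## Worked example

```bash
python examples/degradome_validation.py
```

simulates two planted hairpins with degradome signal at 3 of 4 sites each,
rediscovers them, and validates:

```
degradome library: 400 tags of 20 nt after pre-treatment

tc001:1-231+: 3/4 sites supported
       start5p @   96  supported
   after_end5p @  117  supported
       start3p @  132  supported
   after_end3p @  153  no signal
```

`start5p @ 96` means a degradome tag's 5' end coincides exactly with the
predicted 5' end of the mature-5p arm at transcript position 96 — evidence
that Dicer-like processing really occurs there. The one unsupported site is
the one the simulation deliberately left silent. The other examples show
discovery (`simulate_and_discover.py`), conservation calls
(`conservation_scan.py`), and the config-driven end-to-end run
(`full_pipeline.py`), which prints a per-arm summary such as:

```
          mature_id              sequence conservation  rpm_flower  rpm_leaf
Demo_tc_syn-miR1-5p GCUAAAGACAAUUACAUAACA            -     88950.0  124800.0
Demo_tc_syn-miR1-3p UUAUGUAAUUGUCUUUAGUCA            -     92400.0   55600.0
```

From the shell, the same flow is:

```bash
plantmir simulate --seed 7 --n-hairpins 4 --out demo
plantmir run --config demo/config.yaml
```

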
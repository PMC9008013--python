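# cenfuse

Toolkit for analysing the architecture of centromeric satellite DNA arrays
and inferring the donor chromosomes of Robertsonian (centric-fusion)
chromosomes from sequence alone.

Given a reference satellite monomer and one or more array sequences,
`cenfuse`:

1. **scans** for full-length monomer copies (affine-gap local alignment with
   greedy iterative masking, both strands),
2. **decomposes** the monomer array into higher-order-repeat-like **blocks**
   (runs of same-orientation, mutually similar monomers) and reports
   interspersed insertions,
3. **infers provenance** of each block of a fused array by strand-aware
   consensus homology against two candidate donor arrays,
4. **scans degenerate motifs** (CENP-B box and relatives, IUPAC semantics
   with per-position transition/transversion classification of mismatches),
5. computes **substitution spectra**, p-distances, a slope-ratio
   **saturation** assessment, and **neighbor-joining** trees of monomers,
6. selects **candidate fusion scaffolds** from gene-anchor tables and splits
   their anchors into syntenic segments,
7. ships a fully seeded **simulator** of satellite arrays, donor
   chromosomes and fusion chromosomes with complete ground truth, used
   throughout the test suite.

## CLI

One subcommand per stage plus `full`:

```sh
cenfuse simulate --seed 42 --monomer-length 1400 \
    --block 4:-:0.10 --block 4:+:0.12 --block 4:-:0.14 --out-dir sim/

cenfuse scan  --ref sim/ancestor.fasta --in sim/array.fasta \
    --min-identity 0.7 --min-coverage 0.9 --out-prefix monomers
cenfuse blocks --ref sim/ancestor.fasta --in sim/array.fasta --out-prefix blocks
cenfuse provenance --ref ref.fa --fused fused.fa --donor-a a.fa --donor-b b.fa --out prov.tsv
cenfuse motifs --in consensus.fasta --motif cenpb_consensus --max-mismatch 4 --out hits.tsv
cenfuse spectrum --in consensus.fasta --out spectrum.tsv
cenfuse saturation --in monomers.fasta --out pairs.tsv
cenfuse tree --in monomers.fasta --out tree.nwk
cenfuse candidates --anchors anchors.tsv --chrom-a BTA2 --chrom-b BTA28 --out cand.tsv

cenfuse full --in fused.fa --ref ref.fa --donor-a a.fa --donor-b b.fa --out-dir run/
```

`full` writes per-stage tables plus a single `summary.json` validated
against the schema in `src/cenfuse/data/summary_schema.json`; output is
byte-identical across reruns with the same config. A YAML config file
(`--config run.yaml`) mirrors the flags, with CLI values taking precedence.

Coordinates are 1-based inclusive in tables, 0-based half-open in BED.

## Conventions and defaults

- Alignment identity = matching columns / all alignment columns (gap columns
  included). `N` matches nothing; IUPAC ambiguity codes (used at consensus
  tie columns) match their constituent bases.
- Default scoring: match +1, mismatch −1, gap open −2, gap extend −1.
  The monomer scanner uses a stiffer profile (−4/−2) because tandem monomer
  copies diverge mostly by substitution and cheap gaps blur copy boundaries.
- "Full-length" monomer = ≥ 90 % reference coverage (configurable); the
  identity floor is 70 %. The search thresholds behind published monomer
  counts are generally unstated, so counts on real data are
  parameter-dependent.
- Block membership: identity to the running block consensus ≥ 85 %, same
  strand, gap ≤ 100 bp; larger gaps become insertion records.
- p-distance and spectra use pairwise deletion (gap columns excluded);
  percentages are rounded half-up to two decimals.
- Saturation is a slope-ratio heuristic (upper- vs lower-half of the
  p-distance range, flag when ratio < 0.5), not an entropy-based test.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes brute-force dynamic-programming and window-enumeration
oracles, hypothesis property tests, seeded planted-truth recovery
experiments (50-seed monomer/block recovery, 100-fusion provenance
recovery) and `tests/test_acceptance.py` with one test per acceptance
criterion. Everything is generated programmatically; there are no binary
fixtures.

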
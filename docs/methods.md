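# Methods

## Model and assumptions

`aptamotif` treats a sequenced SELEX round as a multiset of primer-flanked
inserts and asks for fixed-length degenerate motifs — tuples of base sets
over {A,C,G,T} — occurring in at least a chosen fraction of the read mass.
The core data structure is a generalized suffix trie truncated at the
maximal motif length *r*: every suffix of every distinct insert is walked
into the trie, and each node stores the serial numbers of the sequences
containing its path string, deduplicated. Because motif length is bounded
(7–11 by default), truncation keeps construction at *O(n·l·r)* without
suffix links or online construction; at these depths a plain trie is
smaller and simpler than a linear-time suffix tree and lookup cost is
identical.

Degeneracy is *not* stored in the tree. The search realizes it by
progressive node merging: a pattern is extended one composite character at
a time, the children of the current node set under any base of that
character are collected, and their member lists unioned. The merged list is
exactly the set of sequences containing the extended pattern, so member
queries never rescan sequence text.

### Termination and filtering

Three conditions cut a branch during the depth-first search:

1. depth = maximal motif length;
2. coverage below the threshold — coverage is anti-monotone under
   extension, so this is lossless (the invariant is asserted during the
   search and cross-checked by brute-force enumeration in the tests);
3. loss of formal integrity: at some position a base of the degenerate
   character is absent from every actual occurrence, meaning a stricter
   pattern covers the same branch. Occurrence support only shrinks under
   extension, so this cut is lossless too.

Surviving patterns of sufficient length become hits if the per-position
total information *E = log₂4 − H* of the occurrence-derived PSSM meets the
per-position minimum (1.8 bits by default) and the average minimum
(0 by default, i.e. off). When a gap band is configured (off by default), a
position failing the minimum but at or below the gap ceiling is tolerated —
exempt from both the information and the integrity test — as long as the
motif neither starts nor ends with such a position; integrity cutting is
then deferred from the search to emission, since gap status needs the PSSM.

### Coverage basis and PSSM tallying

Coverage is read-multiplicity weighted by default (`READS`): a motif's
coverage is the summed count of its matching distinct inserts divided by
the total retained count. A `DISTINCT` basis (each insert weighing 1) is
available. PSSMs follow the same basis. In full-sequence mode each node of
the merged set is one concrete occurring string whose per-sequence
occurrence multiplicities were recorded at construction; the PSSM is the
weighted tally over these strings, which is identical to rescanning the raw
inserts (the test suite verifies this equality hit by hit against an
independent rescan). In loop mode the tree deduplicates loop substrings per
sequence, so each loop-located string counts once per sequence containing
it.

## Structure-aware mode

Folding is delegated to an external suboptimal-structure predictor; the
package parses its text output (sequence line, then dot-bracket/energy
lines). Energies are converted to Boltzmann probabilities
P(x) = exp(−β·E(x)/(k_B·T))/Z with k_B = 0.0019872 kcal·mol⁻¹·K⁻¹
(matching kcal/mol energies), T = 310 K and β = 1 by default; β = 0 gives
uniform weighting, larger β sharpens towards the minimum-energy structure.
The exponentials are computed with the maximum factor subtracted, so
arbitrarily large |E|/(k_B·T) cannot overflow.

Because the constant primers fold together with the insert, ensembles are
expected over the primer-flanked sequence; maximal unpaired runs are
clipped to the insert window and shifted to insert coordinates before
insertion. Per structure *x*, every clipped run and its depth-limited
suffixes are inserted, and every touched node gains P(x) of weight for that
sequence — at most once per structure, so overlapping runs within one
structure cannot push a node's weight above P(x), and weights never exceed
1 or grow down the tree. A sequence whose ensemble exposes no unpaired
insert position is skipped with a warning.

Coverage in loop mode remains read-count based; structure weights surface
only as the *loop propensity* of a hit — the count-weighted mean, over
matched sequences, of the merged node weight, i.e. the Boltzmann mass of
structures placing that concrete motif string on a loop. This matches the
observation that a strict coverage threshold can be met by motifs whose
loop propensity is well below it.

## Synthetic data

The generator emulates an enriched sequencing round as a *clone pool*: a
limited number of distinct candidate inserts whose read counts follow a
Zipf-like (1/rank) distribution, reflecting that late SELEX rounds contain
tens of reads per distinct sequence. A configurable fraction of clones
carries one instance of the planted degenerate motif (default
`[AG]G[AG]TGGTCCGGG`, the variable positions sampled uniformly) at a
uniform offset in the 49-nt insert; reads attach the library primers and
apply i.i.d. substitutions at rate 0.005 with clipped-normal Phred scores
(mean 35, sd 4, clipped to [2, 41]). Across rounds the planted fraction
rises geometrically to its final value and the pool shrinks geometrically
towards its final size, so diversity indices decrease round by round.

The companion ensemble generator fabricates RNAsubopt-style files: 1–5
structures per sequence built from randomly placed, properly nested
hairpin helices, energies uniform in [−10, −1] kcal/mol, with the
minimum-energy structure keeping the planted-motif window unpaired. It is a
synthetic stand-in exercising the parsing, weighting and loop-extraction
machinery — it contains no thermodynamics, so passing tests demonstrate the
correctness of the pipeline given an ensemble, not the quality of any
folding model. Likewise the clone-pool model omits PCR bias,
platform-specific error profiles and indels; conclusions about real
libraries still require real ensembles and reads.

## Numerical and design choices

- Coordinates are 0-based half-open; FASTQ is Phred+33 only, scores
  outside [0, 60] are rejected as a wrong-encoding symptom.
- Primer matching is exact: full primer anywhere, or an end-anchored
  fragment of ≥ 8 nt (configurable); mismatch tolerance is out of scope.
- Quality filter: mean Phred ≥ 20; abundance filter: count ≥ 2 —
  singleton sequences in an enriched round are treated as artefacts, which
  also removes most sequencing-error variants.
- Serial numbers are assigned count-descending with lexicographic
  tie-break, making top-k selection and all downstream output
  deterministic. Hits are ordered by (length desc, coverage desc,
  consensus); consensus ties resolve by the fixed order A<C<G<T.
- Composite alphabet order: singletons, then subsets by size and
  lexicographically — fixing the depth-first visit order.
- Diversity uses the Gini–Simpson form (1 − Σp², higher = more diverse)
  and natural-log Shannon–Weaver; the raw-Simpson and log₂ variants are
  selectable.
- Probability normalization tolerance is 1e-9; PSSM columns sum to 1 by
  construction.
- The 200-instance search-vs-brute-force equivalence check uses instances
  of up to 14 sequences × 24 nt × length-5 patterns; the planted-motif
  demonstrations use one simulated round of 2,000 reads over a 200-clone
  pool. These sizes keep each worked example in the seconds-to-minutes
  range while leaving all qualitative behaviour (coverage cutting,
  integrity explosion into consensus groups, loop restriction) intact.

## Known limitations

- No mismatch model and no variable-length gaps between motif elements;
  variability is per-position character sets only.
- No statistical significance (E-values) for hits; coverage and
  information thresholds are the only filters.
- Loop-mode PSSMs weight each distinct loop string once per sequence;
  multiple occurrences of the same string within one insert are not
  distinguished there (they are in full mode).
- Overlapping maximal consensi are reported as fusion candidates (best
  suffix–prefix overlap ≥ 4) but never merged automatically.
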
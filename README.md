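# aptamotif

Discovery of degenerate sequence motifs in NGS-sequenced SELEX rounds using
a depth-limited generalized suffix tree, with optional restriction of the
search space to unpaired (loop) regions of predicted secondary structures.

## Who this is for

SELEX experiments evolve a random oligonucleotide library towards aptamers
binding a chosen target. Sequencing the enriched rounds produces reads of
the form *5′ primer – N₄₉ insert – 3′ primer*; the question is which short,
possibly variable motif the selection converged on, and whether that motif
sits on unpaired loop nucleotides, where binding sites stay chemically
available. `aptamotif` answers both, and can additionally quantify
per-round library diversity and emit a motif-enriched starting library for
a follow-up SELEX run.

## Method in brief

1. **Preprocessing** — primer stripping (exact full or end-anchored
   fragment matches), mean-Phred and ambiguity filtering, deduplication to
   distinct inserts with read counts and dense serial numbers.
2. **Tree construction** — every suffix of every insert is walked into a
   trie truncated at the maximal motif length *r*; a node reached by path
   *p* stores the serials of all sequences containing *p* (no duplicates).
   Construction is *O(n·l·r)*.
3. **Structure-aware mode** — suboptimal secondary structures (RNAsubopt-
   style dot-bracket + energy text) are weighted by Boltzmann probabilities

       P(x) = exp(−β·E(x)/(k_B·T)) / Z,   Z = Σ_x exp(−β·E(x)/(k_B·T)),

   and only maximal unpaired runs are inserted into the tree, each node
   accumulating per-sequence structure probability mass. β = 0 weights all
   structures equally; larger β concentrates on low-energy folds.
4. **Search** — exhaustive depth-first enumeration over a composite
   alphabet Σ\* (all subsets of {A,C,G,T} up to a degeneracy limit) by
   *progressive node merging*: one step per composite character, unioning
   the member lists of all matching children. Branches are cut at the
   length bound, when read-weighted coverage falls below the threshold
   (coverage is anti-monotone), or when *formal integrity* fails — some
   base of a degenerate position is never actually observed. Surviving
   patterns are filtered by per-position total information
   *E = 2 − H(column)* bits of the occurrence-derived PSSM.
5. **Aggregation** — hits are grouped by consensus (per-column majority)
   and arranged in a substring-relation digraph; its sources are the
   maximal motifs. Loop-mode hits additionally carry a *loop propensity*:
   the mean Boltzmann mass of structures placing the motif on a loop.
6. **Diversity & library generation** — Gini–Simpson (1 − Σp²) and
   Shannon–Weaver (−Σp·ln p) indices per round; PSSM-driven generation of
   motif-enriched starting libraries (constrained-random or
   post-randomized).

## Worked example

The package ships a synthetic SELEX round generator (clone pool with
Zipf-skewed read counts, planted degenerate motif `[AG]G[AG]TGGTCCGGG`,
substitution errors, primer-flanked FASTQ):

```
$ aptamotif simulate --out-dir sim --seed 7
wrote 1 round(s) to sim
$ aptamotif preprocess sim/round_0.fastq --out-dir pre
152 distinct inserts -> pre/records.tsv
$ aptamotif search pre/records.tsv --out-dir hits
106137 motif hits -> hits/hits.tsv
$ aptamotif aggregate hits/hits.json --out-dir groups
6 consensus groups -> groups/groups.tsv
$ aptamotif diversity pre/records.tsv --out-dir div
records: distinct=152 simpson=0.9528 shannon=4.0263
```

`groups/groups.tsv` then reads:

```
consensus	size	best_coverage	best_loop_propensity
TGGTCCGGG	53816	0.9985
GGTCCGGG	20220	0.9985
TGGTCCGG	20123	0.9985
GGTCCGG	4108	0.9985
GTCCGGG	3339	0.9969
TGGTCCG	4531	0.9985
```

Read this as: the ~106k raw hits (degenerate variants vacillating around
one true motif) collapse into 6 consensus groups; the substring digraph has
a single source, `TGGTCCGGG` — the invariant core of the planted motif —
covering 99.85% of the retained reads. The planted variable positions
(`[AG]`, split ~50/50 across clones) carry ~1 bit of information and are
correctly excluded by the 1.8-bit per-position default. With
`aptamotif search-loops` and a structure ensemble file, the same table
gains loop-propensity values. `aptamotif genlib hits/hits.json ...` turns
the top PSSM into a new starting library.

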
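# Methods

## Model and assumptions

`exomotif` searches a set of m ChIP-exo narrow-peak sequences for an
over-represented, ungapped DNA motif of unknown width, scanning both
strands. Its central assumption is that per-base sequencing coverage
inside a peak is informative about where the protein bound: positions
under the coverage apex are more likely to lie inside the true binding
site, so alignment evidence collected there deserves more weight.
Nothing else is assumed about the coverage profile — it enters only
through two monotone transforms (a per-peak log-ratio normalisation and
per-row max-normalisation), so the method is invariant to the scale and
units of the raw track.

Coverage is normalised per peak as
`x_i <- log(1+x_i)/max_j log(1+x_j)`; the log base cancels. A peak with
an all-zero track keeps zero weights rather than erroring. In basic
(sequence-only) mode every weight is 1.0, which collapses the stage-1
weight `f·(w_a + w_b)` to the pure similarity score `2f`; basic mode is
therefore a special case of the weighted pipeline, not a separate code
path.

The pairwise segment statistic is the upper-tail binomial probability
of observing at least k identical positions among l under a uniform
0.25 match probability, reported as `f = -log10 P`. Positions holding N
never count as identical. The tail is computed in log space
(`gammaln` + `logsumexp`), so f stays finite and accurate for any l; a
test verifies agreement with an exact rational enumeration to 1e-12
for l ≤ 8. The default threshold f > 3 accepts pairs whose similarity
has tail probability below 10⁻³.

Sequences may have unequal lengths; all loops run per-row to that row's
own length, and the mean peak length stands in for n in the bookend
null. A peak is never aligned against itself or its own reverse
complement; all four strand combinations of two distinct peaks are
compared, each unordered row pair once (the scores are symmetric in the
pair, so the ordered and unordered readings coincide).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| l | 14 | bp | seed segment width of the alignment stages; optionally swept over an inclusive range |
| f_threshold | 3 | -log10 probability | unconditional support increment when the similarity tail is below 10⁻³ |
| alpha | 5 | rank | per-row-pair rank cutoff on the weighted score f' (ties at the cutoff included) |
| beta | 3 | rank | per-row-pair rank cutoff for graph edges |
| min_clique_size | 3 | instances | smallest clique accepted as a potential motif |
| max_motifs | 10 | motifs | cap on finally reported motifs (all cliques feed the bookend stage) |
| d | 25 | bp | bookend co-occurrence window; also caps how wide a merged motif can grow |
| p_cutoff | 0.05 | probability | significance level of the bookend binomial test |
| t | 2 | bp | flank width of the two coverage windows in the match score |
| expand_iterations | 1 | rounds | instance-expansion sweeps (fixed point detection stops early) |
| bookend_rounds | 1 | rounds | pairwise merge passes over the potential motifs |

Zero-score pairs (f' = 0, e.g. when stage-1 support is empty) never
qualify under the rank rule: a rank among worthless scores is not
evidence. This makes the degenerate all-zero-support case behave
sensibly — the second stage then returns exactly the row-normalised
coverage floor.

## Stage notes and numerical choices

**Two-stage alignment.** Identity counts for all segment pairs of a row
pair are built from l shifted slice-adds of the base-equality matrix
(O(l·n²) per pair) and cached across the two stages and the graph pass.
The ±2 bp neighbourhood maximum of stage 2 is a zero-padded maximum
filter, which equals the truncated-window maximum because support
counts are non-negative. After stage 2, both the support matrix and the
coverage matrix are divided by their row maxima (all-zero rows stay
zero) and the coverage floor is added over valid segment starts.

**Graph and cliques.** The exact clique heuristic used by earlier
closed-form motif finders is not published in detail; the
reconstruction here is the largest single design choice. It is greedy
and deterministic: seed at the highest-degree vertex (ties: incident
weight sum, then lexicographic position), grow by the candidate
adjacent to every member with the largest summed edge weight into the
clique, reject candidates on an already-represented peak (either strand
row — one binding site yields one strand-resolved instance), and
consume accepted cliques' vertices so the output is disjoint. Cliques
are maximal with respect to the vertices still free when they were
grown; a property test checks this against exhaustive enumeration on
random graphs. Seeds whose clique falls below `min_clique_size` are
retired from seeding but stay available as growth candidates.

**Bookend width optimisation.** Instance pairs are mapped to
forward-strand coordinates and matched one-to-one nearest-first so a
dense cluster cannot inflate the co-occurrence count o_ij. The null
probability `p = d·n_i/(m·n)` is clamped to 1. Zero or negative
overlaps count toward o_ij (the test concerns co-occurrence) but only
strictly positive overlaps vote for the modal overlap l_o (ties prefer
the larger overlap, i.e. the conservative narrower width); if no
positive overlap exists the pair stays unmerged. Merges apply greedily
in ascending p-value order, each motif participating at most once per
round, and a merge is only applied when the modal-overlap instance set
retains at least three instances — otherwise a well-supported motif
would be replaced by a near-empty one on the strength of one or two
windowed coincidences. Merging generalises to unequal widths
(`l_x = w_i + w_j − l_o`), which also lets strand or shift twins of one
motif pool their instances without widening. A single round is the
default: experiments with iterated rounds showed widths can assemble
stepwise from a ladder of partially overlapping fragments, but each
round keeps only the modal-overlap pairs, eroding instance support
faster than width is gained.

**PWM and expansion.** Column frequencies use one Laplace pseudocount
split 0.25 per base, so log-odds (base 2, against the mononucleotide
background of the genome when provided, else of the peaks) are always
finite; the base only rescales scores and never changes rankings. N
bases contribute 0.25 to each count and score the column-mean log-odds.
The match score multiplies the log-odds sum by the mean of two coverage
window maxima, `[j'−t, j']` and `[j', j'+l_o+t]`, truncated at row
bounds; for seeds that never merged, l_o is taken as the full width so
the second window covers the whole segment. Expansion admits segments
scoring strictly above the weakest current instance, processes
candidates in descending score order, and skips candidates overlapping
a kept same-row instance by more than half the width; original
instances are never removed. Score-ordered processing keeps the result
invariant under reverse-complementing the whole input (the row
enumeration order is not). Final motifs are ranked by the summed match
score of their instances rather than instance count alone, because a
washed-out PWM sets a permissive expansion threshold and would
otherwise win on volume.

**Evaluation.** A sequence's classifier score is its best plain
log-odds window on either strand; the coverage factor is excluded
because negative sequences carry no coverage. ROC curves use the
standard tie treatment (tied scores collapse to one diagonal segment);
the restricted areas are integrated segment-by-segment with the band
edges interpolated linearly. Both pAUC variants are standardised in the
McClish sense, `0.5·(1 + (A − A_random)/(A_perfect − A_random))`, so an
uninformative classifier scores 0.5 and a perfect one 1.0 regardless of
the band; this makes the metrics invariant to monotone transforms of
the scores. The sensitivity variant integrates specificity (1 − FPR)
over TPR ∈ (0.8, 1.0); the specificity variant integrates TPR over
FPR ∈ (0, 0.2).

## Synthetic data

The generator plants one instance of a known PWM (uniform position,
uniform strand) in a chosen fraction of i.i.d.-background peaks and
overlays a triangular coverage bump (baseline 1, default height 9,
half-width 20 bp) centred on each planted site, then applies the
standard normalisation. The triangular shape was chosen over a Gaussian
for exact, integer-friendly fixtures. Defaults — 20 peaks of 200 bp,
plant rate 0.9, 14-bp motif with dominant-base probability 0.97 (about
1.8 bits per column) — represent a small, clean prokaryotic ChIP-exo
experiment with a well-conserved motif. The split-motif variant plants
a 22-bp motif so that two overlapping 14-mers tile it with a 6-bp
overlap, the scenario the bookend stage exists for.

What the generator does not emulate: 5'-border exonuclease footprints
(coverage is a symmetric bump, not paired strand-specific borders),
composition bias and repeats of real genomes, multiple sites per peak,
or motif variants with indels. Passing tests therefore demonstrate that
the machinery is correct and well calibrated under idealised
conditions, not that it matches any particular published benchmark on
real data.

Ground-truth metrics: a planted site counts as recovered when a
reported instance on the same peak overlaps at least half of it; PWM
recovery is the best Pearson correlation between the planted and
recovered frequency matrices over relative shifts (within 4 columns),
both orientations — discovery may legitimately report the motif a few
columns shifted or reverse-complemented.

## Known limitations

- Discovery on a uniformly conserved wide motif (wider than l) yields a
  ladder of shifted potential motifs concentrated on central offsets;
  single-round pairwise merging then widens the reported motif only a
  few bp toward the true width. The bookend model itself recovers the
  planted width when the potential motifs are the two tiling halves;
  the gap is a property of the clique stage's preference for
  central-frame vertices.
- The binomial co-occurrence null treats instance placements as
  independent uniform positions; on real data with clustered sites it
  is anticonservative.
- Expansion can admit the same genomic site on both strand rows,
  so instance counts may exceed the number of distinct sites.
- The one-vertex-per-peak clique rule means multiple true sites in one
  peak are found only through expansion, not clique detection.
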
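# Methods

## The analysis model

A yeast two-hybrid screen with an antibody bait against a random-primed
cDNA fragment library yields a set of retained prey clones, each a
nucleotide interval on some transcript. The analysis rests on three ideas.

**Residue mapping.** Reading frame is defined relative to the source ORF: a
fragment whose first base inside the CDS is not on a codon boundary cannot
encode the target's residues downstream of the activation-domain fusion, so
it is out of frame; antisense inserts are out of frame by definition. The
activation-domain linker is assumed frame-neutral. Fragments reaching into
the 5′ UTR are clamped to the first codon, fragments past the stop codon
are clamped to the CDS, and partial codons at the ends are dropped (floor),
never padded — only fully encoded residues can contribute to an epitope.
All coordinates are 1-based inclusive ("residues 13–174" = 162 residues);
BED export is the single place converted to 0-based half-open.

**Selected interacting domain.** In-frame fragments of one gene that
overlap (share at least one residue, transitively) form a cluster. Every
retained fragment binds the bait, so the binding region must lie in the
intersection of all cluster members: that intersection is the SID. Small
SIDs indicate a linear epitope; SIDs spanning a protein's whole folding
core indicate a conformational epitope (the fragment must fold — and, for
GTPase sensors, load nucleotide — before it can bind). When chained
fragments share no single residue the intersection is empty; this case is
not observed in real screens of this kind, and rather than failing the
package returns the leftmost deepest-coverage plateau flagged
`complete=False`. A complete SID is deliberately brittle: a single
mis-retained in-frame fragment of the target that misses the epitope
shrinks it below the true binding region. This is the correct reading of
"shared by all fragments" and is surfaced, not patched (see *Limitations*).

**Confidence score.** Retention competition means an unspecific gene
collects clones roughly in proportion to its length. The score combines two
independent departures from that null. With `N` retained clones, `G` genes
and length weights `w_g`:

- *count evidence*: `p_count = P(X ≥ n_d)` for `X ~ Binomial(N, w_g)`,
  where `n_d` is the number of distinct fragment 5′ starts. Random priming
  makes identical 5′ starts likely replication/PCR duplicates of one cDNA
  event, so duplicates add no evidence.
- *position evidence*: `p_overlap`, the probability that `n_d` fragments of
  the observed lengths (longest per distinct start), placed independently
  and uniformly on the protein, share at least one residue.

`evalue = G · p_count · p_overlap` (Bonferroni over genes). Categories:
A/B/C at e-value ≤ 1e-10 / 1e-5 / 1e-2, D otherwise or whenever `n_d = 1`
(multiplicity is required evidence), E when the gene recurs in ≥ τ = 0.25
of registered screens (promiscuous prey), F when it is on the experimental
artifact registry. E and F take precedence over the e-value. The
thresholds are conventional order-of-magnitude cuts, configurable; the
ranking, not the absolute values, carries the information.

`p_overlap` is enumerated exactly when the start-tuple space is ≤ 10⁶
(e.g. two length-3 fragments on a 10-residue protein: 34/64) and otherwise
estimated by Monte Carlo (default 20,000 draws, seeded); the estimate is
floored at 1/draws so downstream e-values stay positive. `p_count` uses the
regularized-beta binomial tail, checked in the tests against direct
summation.

## Tiling deconvolution

Gap-repair tiling tests overlapping sub-fragments of a positive clone
individually. The narrowed domain is the intersection of all positive
tiles minus every residue covered by a negative tile, keeping the longest
contiguous run (leftmost on ties). The subtraction rule encodes: a region
wholly presented by a non-binding fragment cannot be the binding site.
Consequently a tile that covers only *part* of the epitope must not be fed
in as a negative — it genuinely fails to bind, but subtracting its residues
would erase true epitope residues. The call simulator therefore scores a
tile positive iff it contains the whole epitope, negative iff disjoint from
it, and omits partial overlaps as equivocal, mirroring how ambiguous
reporter spots are treated in practice. Under that model the narrowed
domain provably contains the epitope and avoids all negatives.

`design_tiling` spreads `n_tiles` starts evenly over the region, draws tile
lengths ≥ `min_len` (seeded), forces the first/last tiles to the region
ends and extends tiles over any gap, so the union always equals the
region. A tile is guaranteed to contain an epitope of length `e` whenever
`min_len ≥ e + step` with `step = (region − min_len)/(n_tiles − 1)`.

## Homologue SID comparison

Pairwise global alignment (match +1, mismatch −1, gap −2; configurable)
with identity = matches / aligned columns excluding dual gaps, reported to
one decimal. For more than two sequences a center-star multiple alignment
is assembled from the pairwise alignments around the most central sequence
— adequate for the short, highly similar SID peptides this is meant for;
it is not a general MSA engine. The common SID is the interval
intersection of the per-homologue SIDs in shared alignment coordinates.

## The screen simulator

The simulator emulates a saturated screen of a random-primed library:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 100 | transcriptome size (scaled-down stand-in for a full library) |
| `gene_length_range` | 120–600 aa | uniform ORF lengths, random codons, no internal stops |
| `insert_len_mean_nt` | 750 | lognormal insert mean; real libraries of this kind average 700–800 bp |
| `insert_len_sigma` | 0.5 | lognormal shape (chosen once as a realistic spread) |
| `insert_len_bounds` | 150–3000 nt | truncation by resampling |
| `n_clones_retained` | 30 | clones emitted per screen |
| `background_rate` β | 0.05 | fraction of retained clones that are unselected |
| `mode` | linear | `conformational` requires containment of the whole `core` |

Gene choice is length-weighted, starts are uniform, and retention is a hard
containment rule: an on-target clone must be in-frame, sense, and contain
the epitope (linear) or the full core (conformational); background clones
are arbitrary fragments of arbitrary genes in either orientation. On-target
draws are rejection-sampled conditioned on the target gene, which is
distributionally identical to rejecting from the full library because start
and length are independent of gene identity. The lognormal uses
`mu = ln(mean) − σ²/2` so its untruncated mean equals the printed mean; the
default truncation trims < 0.3% of mass, so the realized mean stays within
a few percent.

Not modeled: mating efficiency and colony counts, binding affinity,
sequencing error, and biologically structured background (real E/F-category
prey are sticky for reasons the length-weighted null does not capture).
Passing recovery tests therefore shows the *analysis logic* is sound under
the assumed sampling structure, not that real screens meet those
assumptions.

## Synthetic figure-shaped screens

`epimap.datasets` rebuilds screens of published shape (clone totals,
per-gene counts, SID bounds) from printed figure values because the
original per-clone tables are not publicly deposited. Reference sequences
are random-codon ORFs of the real proteins' lengths and clone nucleotide
coordinates are derived so that the mapping arithmetic — not the stored
table — produces the expected residue intervals. These are labelled
synthetic throughout; they validate the coordinate arithmetic and the
report plumbing, not the original laboratory data.

## Numerical and degenerate-case choices

- Percent-of-screen is rounded half-up to integers (2/3 → 67%).
- Cluster and report ordering is fully deterministic (sorted by gene and
  position; stable sorts), so repeated runs are byte-identical.
- Deepest-plateau fallback merges contiguous equal-depth segments and takes
  the leftmost maximal run.
- A clone entirely outside the CDS is an error; a clone with no complete
  codon after clamping is a degenerate fragment, skipped during screen-level
  mapping but fatal when converted individually.
- Sequence placement uses 15-nt exact seeds with per-diagonal
  deduplication; `exact_match` extends seeds maximally without mismatches,
  `seeded_match` extends ungapped with +1/−1 scoring and an X-drop of 12.
  Ties are broken by matched length, then lowest ORF id, then lowest start.
  Placements shorter than `min_match_nt` (default 30) are unmapped.

## Limitations

- The confidence score is a self-contained surrogate built from the stated
  ingredients (length-weighted count tail × common-overlap probability);
  it reproduces category *semantics* and ranking behavior, not any
  particular published score's numeric values.
- The complete-intersection SID can be broken by a rare background clone
  that lands in-frame on the target without containing the epitope
  (~1% of simulated screens at β = 0.05 with 30 clones). The
  `--pbs-min` / `pbs_min` filter and the `sid_complete`/`sid_support`
  columns exist to surface and handle such cases; the SID definition itself
  is kept faithful.
- The MSA is center-star over short peptides; use a dedicated aligner for
  long or divergent sequences.
- OOF and antisense clones are reported and counted but never contribute to
  SIDs; whether real screens ever derived SIDs from such clones cannot be
  settled here, and the default errs on the side of interpretable residue
  intervals.
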
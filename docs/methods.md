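# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the synthetic benchmarks do and do not show
about real data.

## Synthetic data: what is emulated

The generator produces the conditions a pogo / Tc1/mariner survey faces:

* **Host tree.** A dated ultrametric binary tree (default root age
  110 Myr, the average divergence of the bee families the survey spans),
  built coalescent-style: internal nodes at uniform ages, the last merge
  at exactly the root age.  Real trees can be supplied as newick.
* **Genomes.** I.i.d. nucleotides at a configurable GC (default 0.35,
  AT-rich as in bee genomes).  One contig per species by default.
* **Elements.** Each family's progenitor follows the canonical anatomy:
  left TIR (10–30 bp, beginning with the family signature
  pentanucleotide where one exists), a spacer, an in-frame stop, the
  back-translated transposase (340–480 aa with the DDE/D triad at the
  family's canonical spacing), a stop, a spacer, and the reverse
  complement of the left TIR.  Bounding in-frame stops make the longest
  stop-free reading span equal the transposase exactly.  Insertion
  duplicates the `TA` target site on both flanks.
* **Mutation model.** Kimura two-parameter with transition/transversion
  rate ratio kappa = 2 (configurable).  Two samplers: an exact-count
  sampler (applies `round(P*L)` transitions and `round(Q*L)`
  transversions, so the realized divergence of a planted copy matches its
  target within +-0.02 at kilobase scale) and a per-site stochastic
  sampler for branch-wise evolution.  Mutations that would create an
  in-frame stop inside the transposase of an intact copy are reverted;
  triad codons, the bounding stops and the signature pentanucleotide are
  protected — the structural features the classifier keys on are treated
  as under purifying selection.
* **Two planting modes.**  *Star mode* mutates every copy independently
  from the progenitor at a controlled divergence — the right geometry for
  recall, census and classification experiments.  *Tree mode* evolves a
  functional master lineage along the host tree (0.002 subs/site/Myr by
  default, a typical neutral insect rate) whose TIR arms mutate
  *mirrored* (reverse complementarity is a functional constraint on a
  transposition-competent element) and drops recently amplified copies
  (default 0.01–0.015 divergence from the species master) in each host —
  the geometry of a vertically inherited family, whose cross-species
  element distances track the host tree.  Without the mirrored master,
  arm-vs-arm identity decays at twice the lineage divergence and old
  vertical families would have no recognizable TIRs at all.
* **Defective copies.** A configurable fraction get either a 1-bp
  frameshift or a 3' 60% truncation.  The frameshift position is uniform
  on the *middle third* of the ORF: a shift in the terminal ~12% of a
  340-aa ORF would leave a >=300-aa stop-free span, i.e. a "defective"
  copy that still satisfies the intact-copy rule, which would make the
  ground-truth flag dishonest.
* **Control genes.** Clock-like orthologs (default 20 genes x 1.5 kb at
  0.002 subs/site/Myr) so the expected pairwise distance is
  2 x rate x divergence time.  Conserved host genes in reality evolve
  more slowly and unevenly; using the same rate as the elements makes the
  vertical null *harder* (element and gene distances are then drawn from
  the same distribution), which is the conservative direction for the
  specificity claims.
* **Horizontal transfer.** A recipient genome gains one copy derived
  from the donor's current master state plus a small residual divergence
  (the mutations accumulated since the transfer), so donor and recipient
  elements are near-identical regardless of host divergence.

What the generator does **not** emulate: insertion-site preference,
nested insertions, segmental duplications, assembly gaps/errors, indels
within copies (optional, off by default), rate variation across sites and
lineages, and base-compositional heterogeneity.  Passing benchmarks here
therefore demonstrates algorithmic correctness under the stated model,
not performance on the full messiness of real assemblies.

## Mining

Six-frame translation; exact protein 4-mer seeds shared across all query
transposases; a two-hit rule on diagonal bands (within 8 diagonals and
120 aa); Smith–Waterman extension with BLOSUM62 and affine gaps (open 11,
extend 1).  Reporting is by raw alignment score (default floor 75, chosen
so random megabase genomes yield ~0 hits while true copies at 20%
nucleotide divergence score in the hundreds); an 80% amino-acid identity
post-filter is available but off by default, since recall experiments and
diverged vertical families need the laxer setting.  Same-strand hits
within 500 bp merge into loci (shorter than the shortest family
consensus, so neighbouring copies rarely merge); loci are extracted with
2 kb flanks, clipped silently at contig ends.

## Element reconstruction

TIR arms are sought by locally aligning a window anchored at the locus's
5' edge against the reverse complement of a window at its 3' edge
(+2/−2, gaps 6/3; the gentle mismatch penalty lets a long diverged arm
outscore the short perfect inverted repeats that kilobases of flank offer
by chance).  Windows reach 800 bp beyond the locus — the 5'/3' non-coding
regions of these families are a few hundred bp — and 100 bp into it.
Because a maximal local alignment routinely over-extends through noisy
tails (and always through the TA duplication, which is its own reverse
complement), each alignment is trimmed to its best sub-run under harsher
penalties, and several candidate pairs are collected across
mask-and-realign rounds.

Boundary calling is a deterministic replacement for manual curation:
candidates are ranked by arm score plus a bounded bonus for TSD
consistency (walking the alignment columns inward until the flanking
dinucleotides read `TA`/`TA`); arms below a floor of ~15 bp-equivalent
score, or below the arm-identity floor (default 85%), are accepted only
with that TSD corroboration.  When nothing credible remains the model is
kept as "ORF-only" — the behaviour real surveys report for old copies
whose boundaries cannot be determined.  Two quantified limitations: at
copy divergence d the two arms have diverged 2d from each other, so short
(26–28 bp) arms hit the identity floor near d ≈ 0.05–0.08 and boundary
recovery degrades from ~100% (d <= 0.02) to ~85–90% (d = 0.05); and on
genuinely TIR-less elements a chance short arm with a lucky TA context
still yields a false boundary in a minority (~20%) of cases —
indistinguishable in principle from a true 10-bp TIR.

The ORF rule is the longest stop-free reading span across six frames
(>=300 aa for the intact rule), not an ATG-anchored ORF: the criterion
concerns transposase integrity, not start-codon annotation.  Consensus
building is per-column majority (MAFFT alignment first when copies have
unequal lengths; gap-majority columns dropped, ties alphabetical).

## Classification

The query protein is aligned (local, BLOSUM62) to every annotated
reference; the best reference's triad positions are carried through the
alignment; spacing is the *index difference* between the 2nd and 3rd
residues (the intervening-residue convention would differ by one; an
offset toggle exists).  Ties between references break by family name, so
reference order never matters.  Overlapping spacing ranges (DD35D fits
Fot and Tigger; DD34D fits mariner and the Tigger range) resolve by the
best reference's family, then superfamily.  Labels outside every range
but within +-2 of the best reference's range are assigned there and
flagged "drifted" — the bumblebee DD41D->DD40D and stingless-bee
DD33D->DD33E cases; anything else is `novel:DD{n}{letter}`.  Frameshifted
copies cannot present a complete triad in any single reading span; the
pipeline then falls back to best-reference homology ("homology-only"),
which is how a census effectively attributes defective copies.  The
shipped reference set is synthetic (random proteins with planted triads);
classification only uses the annotated triad geometry, so swapping in
curated exemplars is a drop-in change.

## Census and landscapes

`count_copies` runs NCBI `blastn` (task blastn, dust off) of the family
consensus against the genome, chains same-strand HSPs within 1.5 kb (a
diverged copy often fragments into several HSPs; counting them separately
would inflate the census), applies the 80% identity / 40% coverage rule
to the chained records, and collapses overlaps to the best score.
Identity is match columns over aligned columns (internal gaps count as
mismatches); coverage is the union of consensus spans over consensus
length.  K2P distances come from the chained aligned segments under
pairwise deletion; saturated pairs (non-positive log argument) are
flagged and excluded from averages.  The landscape assigns each copy's
aligned bp to a 1%-wide K bin and normalises by genome length, so bin
heights are genome percentages and recent bursts pile up at low K.

## Phylogenetics and horizontal transfer

Distances: p-distance, K2P (nucleotide) or Poisson-corrected (protein),
all pairwise-deletion.  Trees: neighbor joining with negative branch
lengths clamped to zero and ties broken to the lowest label pair —
deterministic, exact on additive matrices (verified against exhaustive
least-squares topology search for n <= 6), and adequate for the
topology-incongruence question; likelihood inference is deliberately out
of scope.  Ordinary column bootstrap (default 100 replicates) provides
split supports.  Robinson–Foulds distances are unrooted symmetric
differences of non-trivial bipartitions (dendropy).

Candidate clusters are seeded by element pairs from hosts diverged beyond
the age threshold (default 100 Myr) with identity at or above the
threshold (default 80%) — the configuration vertical inheritance cannot
produce — and expanded with same-lineage companions by identity
adjacency.  The verdict requires all three classic conditions plus a
significant distance test.  Condition 2 compares the NJ tree of *all*
surveyed family elements with the host topology induced on their species
(multiple copies per species become a tip group).  Condition 3 asks the
census for a surveyed species without the family inside the members'
smallest containing host clade.  The distance test uses only member pairs
whose host divergence exceeds the age threshold: shallow companion pairs
have element distances that legitimately match gene distances and merely
dilute the ANOVA.  With a single qualifying pair the genes are pooled
into one factor level (the per-gene grouping has no residual degrees of
freedom there); both groupings are available explicitly.

Two classes of transfer are undetectable *by construction* under these
conditions and are excluded from the packaged power scenarios as
event-class definitions rather than tuning: transfers between topological
sister species (no incongruence is possible), and family-absence gaps
placed where pruning makes donor and recipient adjacent in the induced
unrooted topology (the gap erases the incongruence along with itself).
On the packaged scenario set (6 species, root 110 Myr, 20 control genes,
1 kb elements) power is ~100% at residual divergence <= 0.05 across
hosts diverged >= 100 Myr, with a false-positive rate of ~0% on
vertical-only simulations at the same thresholds.

## Numerical and formatting conventions

Coordinates are 0-based half-open internally and 1-based inclusive in all
written tables.  All randomness flows from a single master seed through
independently derived per-stage streams, so adding a stage does not shift
the others and every pipeline run is byte-reproducible.  Problem sizes in
the test-suite and acceptance runs (two to five genomes of 0.25–1 Mb,
100 replicates or seeds per stochastic claim) were chosen as the smallest
sizes at which the measured quantities are stable; all thresholds keep
the survey protocol's published defaults (2 kb flanks, 80/40 census,
>300 aa intact rule, TA TSD, p < 0.05).
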
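# Methods

`hgtscan` reimplements, as a tested pipeline, the phylogenomic procedure for
detecting, validating, and dating host-to-parasite horizontal gene transfer
(HGT) in plant organellar genomes, together with a synthetic-data generator
so that every stage can be exercised end to end without any sequence
downloads. This note records the models, the defaults and why they were
chosen, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## The detection model

Each gene is analysed as an aligned nucleotide matrix over a taxon panel in
which every species carries a declared role: outgroup taxa (used only for
rooting), autotrophic reference species, the parasites' closest autotrophic
relative (the *vertical sister*), the host family, the current host genus,
and the parasites themselves. The decision procedure is:

1. Fit a maximum-likelihood (ML) gene tree under GTR+Γ and measure clade
   support by nonparametric bootstrap.
2. Root the tree on the outgroup. Walk rootward from each parasite sequence
   to the first ancestor whose descendants include a non-parasite leaf — the
   *placement clade* — and read off its bootstrap percentage (BP).
3. Below the BP threshold the sequence is **unassigned**. At or above it,
   placement with the vertical sister is a **VGT** (vertical) call; any
   other placement is an **HGT** call whose donor is the narrowest named
   lineage covering the non-parasite leaves of the placement clade —
   current-host genus, then host family, then a single reference lineage,
   else a composite name ("A+B"). Co-placed parasite sequences are treated
   as co-recipients, never as donors, so a whole parasite clade sister to
   the vertical sister scores as VGT.

Two thresholds are exposed (`PipelineConfig`): a strict 70 BP and a relaxed
50 BP, the two operating points used in this literature. Raising the
threshold can only shrink HGT counts (tested monotonicity).

## Likelihood engine

GTR+Γ with empirical base frequencies; the rate matrix is normalised to one
expected substitution per site so branch lengths are in substitutions/site.
Among-site rate variation uses the discrete-gamma approximation with four
equal-probability categories represented by their category means. Site
patterns are compressed once per alignment; gaps and `N` are missing data
(an all-gap row is an error naming the row).

Likelihood evaluation is Felsenstein pruning written around *directional
partials*: for any edge the likelihood is a cheap function of the two
subtree partials flanking it, so one branch length can be optimised (Brent,
bounded to [1e-8, 10], `xatol` 1e-6) after a single O(n) traversal.
Topology search alternates branch-length sweeps with
nearest-neighbour-interchange (NNI) hill climbing until no interchange
improves the log-likelihood by more than 1e-4. Model parameters (five free
exchangeabilities and the gamma shape, Nelder–Mead on the fixed
neighbour-joining starting tree) are estimated once and then held fixed
during search — the standard economical scheme. The starting tree is NJ on
Jukes–Cantor distances (scikit-bio).

**NNI candidate scoring.** Scoring an interchange by re-optimising only the
focal branch, with all other lengths inherited from the current topology,
systematically favours the current arrangement: a cross-check against an
independent slow bootstrap (explicit column resampling plus exhaustive
topology refit per replicate) showed support inflation of roughly ten
points on weak splits. Candidates are therefore scored with their local
five-branch neighbourhood re-optimised by short coordinate descent, behind
a cheap focal-only pre-screen at a 10 log-likelihood-unit margin (wide
enough that, in instrumented runs, no screened-out candidate would have
won). After this change the fast bootstrap agrees with the slow oracle
within binomial noise; one frozen weak-signal case is kept as a regression
test.

**Bootstrap.** Column resampling is implemented as multinomial reweighting
of the compressed patterns (equivalent in distribution, and no re-parsing
per replicate). Each replicate starts from the full-data ML tree,
re-optimises branch lengths, and runs up to two NNI passes; a full search
per replicate is available behind a flag. Support of an internal edge is
the percentage of replicates containing its bipartition. Starting
replicates from the ML tree is a deliberate rapid-bootstrap-style
simplification: in near-zero-signal regimes it can still slightly favour
the ML tree's own splits.

**Constrained search** (for the topology test) restricts NNI to trees in
which a given taxon set remains a clade, starting from an NJ skeleton with
the constraint grafted in; the constrained optimum can never exceed the
unconstrained one (tested, and cross-checked against exhaustive enumeration
at five taxa).

## AU topology test

The vertical hypothesis is the constrained tree (parasites + vertical
sister monophyletic); the alternative is the unconstrained ML tree. Both
trees' per-site log-likelihoods are computed under the unconstrained fit's
model parameters and compared by multiscale RELL bootstrap: ten scales
r ∈ {0.5, …, 1.4}, 1,000 resamples per scale, resampled totals compared
with ties counting one half. The bootstrap probabilities are clamped to
[1/2B, 1−1/2B], probit-transformed, and fitted by weighted least squares
(binomial weights) to z(r) = d·√r + c/√r; the p-value is 1 − Φ(d − c).
Fewer than three informative scales yields a flagged degenerate result
(p = 0 when the constrained tree essentially never wins, p = 1 when it
always does). Only this canonical two-parameter fit is implemented; no
model-family selection is attempted.

## Corroborating evidence streams

* **Copy number** — reads are cut into non-overlapping 25-mers, each mapped
  with zero mismatches against the supplied gene set on both strands and
  counted only if it matches exactly one location; per-gene counts are
  normalised to reads per base pair and compartments compared with Welch's
  unequal-variance t test. Uniqueness is evaluated against the supplied
  gene set, not a whole genome.
* **Expression** — RPKM = count·10⁹/(total·length), with the denominator
  the total library read count (flag-switchable to mapped reads).
* **Reading frame** — standard genetic code; internal stop or a length not
  divisible by three marks a pseudogene (ψ); a trailing stop is allowed. A
  pre-edited (cDNA) sequence can be supplied to avoid false ψ calls at
  editable sites.
* **C-to-U editing** — positions where the genomic sequence has C and the
  cDNA has T, reported 1-based on the genomic coordinate; other mismatches
  are reported separately as non-canonical.
* **Contamination screen** — uncorrected p-distance (gap/N positions
  excluded) between each transgene and its current-host homolog, compared
  with host–host distances by Welch's t; zero-distance transgenes are
  flagged as possible contamination.

## Timing and synteny

A gene's transfers are dated qualitatively from the transgene clade
structure: transgenes from both parasite genera forming a clade with ≥50 BP
(the relaxed threshold; the ancient-clade claims in this literature are
asserted without a stated support floor) are **ancient**; transgenes
confined to one genus are **recent**; transgenes from two genera — or
multiple copies within one species — that fail to form a clade are
**repeated independent** transfers. Contig gene orders are compared to
donor- and recipient-side references by unordered adjacency (strand
agreement optional), the signature used to argue displacement of native
genes by homologous recombination. Breakpoints in chimeric genes are
localised at region level: each labelled region (≥100 columns) is
classified by its own ML tree, and every junction between differing
assigned classes is a candidate breakpoint; unassigned regions between
differing classes widen the reported interval rather than suppressing it.
Column-level scanning is deliberately out of scope.

## Homolog clustering

All-against-all Smith–Waterman local alignment (match +1, mismatch −1, gap
open −2, extend −1, both strands; Biopython's aligner) builds a similarity
graph whose threshold, when not supplied, is calibrated as the 99th
percentile of scores between composition-preserving shuffled pairs.
Markov clustering (expansion 2, inflation 2, tolerance 1e-6, ≤200
iterations, max-weight self-loops) partitions the graph; clusters are
retained only if they span outgroup, parasite, vertical sister, and host
clade — the rooting-and-contrast requirement for downstream detection.
Cluster boundaries are not claimed to match any particular external tool's.

## The synthetic-data generator

The generator emulates the *structure* of a host/parasite organellar
study, not any particular dataset:

* **Species trees** — a packaged ultrametric 33-taxon seed-plant panel with
  family structure, and a 15-taxon reduced panel used by default. Node ages
  (in My-like units; root 300) are spaced ≥7 My at the family level so
  internal edges are informative at 1,000 sites; the parasite stem is long
  (18 My after a 90-My split from the vertical sister), the host genus
  young. Clock rate 1e-3 substitutions/site/My — inside the range implied
  by published parasite–host mitochondrial distances (~0.04 over tens of
  My).
* **Transfers** — prune-and-regraft of the recipient clade onto a donor
  branch at a stated depth, preserving elapsed time (ultrametricity is
  preserved and tested). Recipients may displace the native copy (default)
  or retain it, yielding dual-homolog genes with `|hgt`-suffixed leaves.
  The default schedule rotates ancient (whole-family onto the host-family
  stem at 110), recent single-genus (onto host branches at 25–35), and
  repeated independent (two events for one gene) histories; the default
  scenario is 15 taxa, 20 genes of 1,000 sites, 40% transferred.
* **Sequences** — GTR+Γ simulation (α = 0.5, base frequencies
  0.28/0.21/0.23/0.28, transition-rich exchangeabilities) — plausible
  plant-mitochondrial values, config-exposed, not claimed to match any
  study's estimates. Pseudogenisation injects 1–3 internal stops; editing
  flips selected genomic C to cDNA T only. No indel evolution: gaps arise
  only through splicing or truncation.
* **Reads** — uniform-position substrings from both strands with per-base
  error (default 0.2%), Poisson counts at depth·length/read-length;
  organellar depth 150×, nuclear 2× (the two-copies-per-cell baseline),
  a 75:1 contrast.
* **Chimeras** — two same-length alignments (vertical and transferred
  histories) spliced at region boundaries, emulating partial displacement
  by homologous recombination with the breakpoint at the junction.

Every gene's history, events, pseudogene status, editing sites, and
expected depth/expression are recorded in a JSON truth table.

What passing on this generator shows: the pipeline recovers the signal its
own model family generated, at study-shaped sizes, with calibrated error
rates. What it does not show: robustness to alignment error, indels,
recombination within regions, rate heterotachy, model misspecification, or
compositional bias — all present in real organellar data. The published
call-table checks are exact fixture arithmetic, not a re-analysis of raw
reads.

## Synthetic experiment sizes (workflows)

The acceptance script and heavy tests run: (i) classification recovery on
the default scenario (20 genes × 1,000 sites, 100 bootstrap replicates,
threshold 70); (ii) AU calibration and power on a 9-taxon sub-panel (100
genes × 1,000 sites each condition; power is measured on a host-nested
transfer at 30 — piloting showed the host-family-stem transfer leaves a
long unbroken parasite branch whose placement the AU test often cannot
reject, matching the field's observation that host-nested transgenes give
the strongest rejections); (iii) the 75:1 copy-number contrast (2 × 20
genes of 2 kb); (iv) breakpoint localisation on 20 chimeras (three
600-site regions each — the ~1.8 kb scale of the real two-exon-plus-intron
gene this emulates — on the 9-taxon sub-panel); (v) timing concordance on
30 histories (10 taxa, 1,000 sites). Sub-panels always include both
outgroup taxa (single-outgroup rooting is fragile when a gene tree
misplaces that one leaf) and keep per-gene ML fits to a few seconds;
region and gene lengths follow the study's scales.

## Known limitations

* NNI-only search (no SPR/TBR); a poor NJ start on pathological data could
  trap the hill climb. Five-taxon exhaustive checks bound this at small n.
* Replicate searches start from the ML topology (rapid-bootstrap-style);
  residual support inflation is possible at near-zero signal.
* The AU implementation fits only the canonical (d, c) model.
* Donor naming reports a composite ("A+B") rather than forcing a named
  lineage when the placement clade spans unrelated references.
* Breakpoints are region-level; k-mer mapping is gene-set-relative; RPKM is
  the only expression normalisation offered.
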
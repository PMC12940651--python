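# Methods

## Scope and model

`famscan` implements the computational core of a gene-family survey for plant
MADS-box transcription factors. The family's defining structure drives every
design choice: a conserved ~57-aa DNA-binding MADS domain shared by all
members; a keratin-like K domain of three 29-aa helical segments (K1/K2/K3)
present only in Type II (MIKC) proteins; single- or two-exon gene models for
Type I (M-type) versus multi-exon models for Type II; and a tendency to
expand by tandem and segmental duplication.

Two stages are deliberate simplifications of heavier standard tools, chosen
because the quantities they feed are robust to the simplification:

* **Ungapped PSSM scan instead of a profile HMM.** The MADS domain and K
  segments are fixed-length blocks; for such blocks a log-odds
  position-specific scoring matrix scanned over all windows captures the
  same signal as a profile-HMM Viterbi pass, while keeping scores exactly
  invertible for calibration. Gapped domain variants will score lower and
  can fall below threshold; the architecture caller therefore treats a
  missing or lone K segment as a *reannotation flag*, not a negative.
* **Best-hit nearest-neighbor classification instead of maximum-likelihood
  tree placement.** Subfamily labels are taken from the highest-scoring
  member of a labeled reference panel. This mirrors how published family
  inventories report a per-gene best ortholog, and the reported margin
  (best score minus best other-label score) exposes ambiguous calls that a
  tree would have shown as short internal branches.

## E-value calibration

Scores of the best window in a random sequence follow an extreme-value law.
`calibrate_evalue` samples `n_shuffles` sequences (default 1000; length 300)
i.i.d. from the profile's background composition, records each sequence's
maximal window score, and fits a Gumbel(μ, λ). The expected number of
background sequences at score ≥ s in a database of N sequences is

    E(s, N) = N · (1 − exp(−exp(−λ(s − μ)))).

The fit is tail-weighted: for a Gumbel, log(−log F(x)) is linear in x, so μ
and λ come from a least-squares line through that transform of the empirical
CDF over the upper half of the sample (top five order statistics excluded as
noise). A plain maximum-likelihood fit lets the bulk of the distribution
distort the significance tail — in our checks it over-estimated tail mass by
an order of magnitude at p = 1e-3, while the tail fit keeps the empirical
exceedance of the 1e-3 threshold within three binomial standard errors.

Default significance threshold `E < 1e-3` with N equal to the database
actually searched. Residue `X` scores zero in every column. Overlapping hits
are resolved greedily by descending score.

## Profiles

Packaged profiles are built from fixed, synthetic seed alignments: a
consensus string per domain (57 aa MADS, 29 aa each K segment; see
`profiles.py`) plus seven variants substituted at 5% of sites. They are not
Pfam-derived; they give the scanner, the architecture caller and the data
generator one self-consistent domain vocabulary, and users with curated
alignments can build replacements with `build_profile` (additive pseudocount
0.5; background Robinson–Robinson frequencies, overridable; columns with
>50% gaps dropped). The 57-aa MADS length is configurable — counts of 56 and
57 both circulate in the literature for this domain.

## Duplication inference

Pairwise similarity is Smith–Waterman local alignment (Biopython
`PairwiseAligner`, BLOSUM62, affine gaps where a gap of length L costs
`open + L·extend`, defaults 10 + L·1), computed lazily and cached so
genome-scale inputs only pay for pairs an analysis touches.

*Tandem*: two family genes on one chromosome with consecutive gene ranks —
strict adjacency, strand-agnostic.

*Segmental*: for a candidate paralog pair, the `window` (default 20)
annotated genes on each side of both loci are collected and matched by
reciprocal best hit; the anchor support is the number of RBH pairs, and the
call requires support strictly greater than `threshold` (default 5, i.e.
≥6 anchors). Two numerical details matter:

* RBH ties break to the lexicographically smallest id, making output
  deterministic and independent of input order.
* Anchor RBHs require an alignment score ≥ `min_anchor_score` (default 60).
  Between two sets of unrelated proteins every query still has *some* best
  hit, so unfiltered RBH produces ~1 spurious anchor per comparison; the
  score floor emulates the significance cutoff of an all-vs-all BLASTP,
  under which unrelated pairs simply report no hit. Random ~80–160-aa
  proteins score well below 60, genuinely duplicated neighbors far above it.

A locus near a chromosome end uses the flanks it has; the effective window
is recorded on the event. Tandem and segmental calls may overlap. Default
candidate pairs are family pairs above the median family-pair similarity.

## Physicochemistry

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da). Net charge at pH is Henderson–Hasselbalch over side chains
(D, E, C, Y acidic; H, K, R basic) and both termini; pKa defaults to the
Bjellqvist set used by ProtParam (EMBOSS set available), so values computed
from real sequences are comparable with published inventories. Net charge is
strictly decreasing in pH, so the isoelectric point is the unique zero,
found by bisection on (0, 14) to |ΔpH| < 1e-3 (cross-checked in tests
against a 1e-4-step grid scan of an independently constructed charge curve).
The packaged inventory's pI/MW columns are treated as curated data, not
recomputed — the underlying protein sequences are not distributed with it.

## Expression

`TPM = FPKM / Σ FPKM(sample) × 1e6` per column, refusing all-zero columns
rather than dividing by zero. Zero-expression genes are retained (biological
absences), NaNs rejected. Exports are raw or log2(x+1); row scaling is left
to plotting tools.

## Synthetic data: what it emulates, what it does not

The generator plants, under one seeded stream: Type II proteins (MADS + K1 +
K2 + K3, 5–8 exons) and Type I proteins (MADS only, 1–2 exons); tandem
arrays as adjacent paralog copies; segmental blocks as a duplicated family
gene plus exactly `anchors_per_block` copied flanking genes (split evenly
left/right, within the flank window); and an FPKM matrix with log-normal
baselines (median ~20), group×tissue fold changes (default: MIKC ×10 in
flower) and log-scale Gaussian noise. Planted feature sites are spaced so
flank windows never overlap, which is what makes recovered anchor counts
exactly equal planted counts at mutation 0.

Background genes are i.i.d. Robinson–Robinson sequences. The generator does
**not** emulate codon usage, intron sequence content, pseudogenes, assembly
gaps, partial gene models, or homology between background genes. Passing
recovery tests on this data therefore demonstrates correctness of the
detectors' logic under their stated definitions — not robustness to the
annotation noise of a real assembly, where the reannotation flags and the
configurable thresholds are the intended handles.

Default study conditions for the duplication-recovery check: 5 chromosomes ×
200 genes, 20 family genes, tandem arrays of 2/3/5, segmental blocks with
4/6/8/12 anchors, mutation 0. These sizes keep a full run in seconds while
leaving every planted count unambiguous; the unit suite uses a 3×120
genome with a 10-gene flank window for the same reason.

## Curated inventory conventions

The packaged 87-gene table keeps the source's two row markers as boolean
columns: `corrected` (annotation was manually fixed) and `partial`
(incomplete gene model; one gene, TgMADS79). Only `partial` affects
statistics, and every statistic takes an explicit `exclude_partial` flag
because published aggregates are inconsistent about it: brute-force checks
of the table show the MIKC^C mean pI *includes* the partial record while the
MIKC^C mean mass and the exon range *exclude* it. The published
acidic/neutral/basic partition (59/6/27) does not sum to 87; the package
asserts the partition property (classes sum to table size — the fixture
gives 60/5/22) rather than the printed triple. The printed M-type mean pI of
7.43 corresponds to a computed 7.436.

## Known limitations

* Ungapped scanning under-scores indel-containing domains (flagged, not
  recovered); no de-novo motif discovery.
* Segmental calling tests local flank conservation only — no genome-wide
  collinearity chains, no Ka/Ks dating.
* Classification cannot place a query into a subgroup absent from the panel
  (it reports the nearest present label or `unclassified`).
* pI assumes free side chains in solution; post-translational modification
  and structural effects are out of scope, as for all ProtParam-style tools.
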
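# Methods

This note documents the synthetic-locus model, the annotation pipeline's
parameters and their defaults, the numerical choices made throughout, and the
known limitations. All quantitative behaviour stated here is exercised by
the test suite; nothing below is an empirical claim about real genomes.

## 1. The synthetic locus model

`generate_locus(LocusConfig)` builds one scaffold containing a TCR-like
locus and returns the genome together with every planted coordinate
(`SyntheticTruth`), so annotation accuracy can be scored exactly.

### Cassette anatomy

Coordinates are 0-based, half-open, plus-strand internally; GFF3 conversion
(1-based, inclusive) happens only in the I/O layer.

- **V cassette** (5'→3'): leader exon L-PART1 (`ATG` + 10 codons = 33 nt,
  ending in a `GT` splice donor), an intron of ≥ 20 nt, the V exon
  (90–116 codons, phase-0 `AG` acceptor immediately before it), then a
  23-RSS whose heptamer abuts the exon end. The exon carries the V
  hallmarks: first conserved Cys at codon 21, conserved Trp at codon 40, the
  CDR3-anchoring Cys at codon *n*−2, and no stop codons.
- **J gene**: a 12-RSS whose heptamer abuts the 5' end of the coding region
  (45–75 nt), a `[FW]-G-x-G` motif 9–19 codons in, two tail codons, and a
  `GT` splice donor immediately after the 3' end.
- **D gene**: 9–12 bp of coding flanked by a 12-RSS on the left and a 23-RSS
  on the right (both heptamers facing the coding region), following the
  12/23 rule for V–D–J loci.
- **C gene**: four exons (EX1–EX4) separated by introns; the generator
  records the exon structure and exposes the spliced cDNA via
  `c_references()`, which is what the annotator aligns back.
- **Pre-joined V–J cassette** (optional): one germline-fused exon — V codons,
  a two-codon linker, the `[FW]-G-x-G` motif, a tail codon and a `GT`
  donor — with its own leader exon and **no RSS**. It models germline-joined
  V–J genes that cannot be found by RSS anchoring.

V genes can be grouped into clusters of either orientation relative to the
locus, and the whole scaffold can be reverse-complemented
(`scaffold_orientation="REV"`); planted coordinates are reflected exactly.

### Unambiguous-boundary construction

The generator is designed so that a correct annotator has exactly one valid
reading — recovered coordinates either match the truth or are wrong, never
"off by a plausible alternative":

- all splice junctions are phase 0;
- intergenic sequence and introns are scrubbed of `ATG` on both strands
  (no spurious leader starts), introns carry no `AG` within their final
  13 nt (no alternative acceptors), and the first 26 V-exon codons contain
  no codon ending in `AG` (no downstream in-frame acceptor shift can
  satisfy the Cys-21 window);
- V-exon codons contain Cys only at codon 21 and *n*−2 and Trp only at 40;
  J codons exclude stops, Val, Phe and Trp outside the planted motif;
- RSS spacers are regenerated until they contain neither `CAC` nor `GTG`,
  so no pseudo-heptamer inside a spacer can pair with a planted nonamer.

### Families and defects

`family_plan` plants V families: each family has a founder (kept ≤ the
planned between-family identity from all other founders) and members mutated
from the founder to the planned within-family identity, with the three
hallmark codons held fixed. Member–member identity is therefore lower than
founder–member identity; single-linkage clustering still recovers the family
through the founder.

`defect_plan` plants one defect per chosen segment and records the expected
functionality class: `internal_stop` → P (pseudogene); `broken_rss`,
`broken_splice`, `missing_motif` → ORF (intact frame, broken regulatory
element). Coding defects dominate regulatory ones when both are present.

### Simulators

- `simulate_clonotypes` draws reads i.i.d. from a V–J usage table (default:
  uniform over functional pairs), with uniform exonuclease trimming (0–3 nt
  per side, never into the anchor codons) and 0–6 random N-insertions,
  then aggregates identical recombination records. `clonotype_length_pmf`
  computes the exact CDR3-length distribution implied by the same model, used
  as the oracle for spectratype estimates.
- `merge_truths` concatenates two labelled loci with a scrubbed spacer so a
  single repertoire can span two loci (cross-locus V–J pairing).
- `simulate_depth` draws per-window (default 100 bp) Poisson read depth,
  halved inside an optional interval — the retained-haplotig scenario.

## 2. Annotation pipeline parameters

RSS scanning scores candidate windows by mismatch count against the
consensus heptamer/nonamer with an obligatory `CAC` heptamer prefix.
Two thresholds are deliberately distinct:

- **Discovery threshold 4** (`DEFAULT_MAX_SCORE`): permissive, so degraded
  but real signals still anchor candidates.
- **Evidence/classification threshold 2** (`DEFAULT_FUNCTIONAL_SCORE`):
  strict. Planted (functional) RSSs are consensus-exact; chance anchors in
  random sequence almost always carry 3–4 mismatches, so the strict
  threshold is what separates evidence from noise.

A candidate V or J is retained only if **two of three** evidence criteria
hold: ≥ 60% global identity to another same-kind candidate, an RSS scoring
≤ 2, and read-or-leader support (a discovered leader for V; externally
supplied read evidence otherwise). Measured on this generator's background,
alignment identity between unrelated J-length sequences almost never reaches
60%, so a chance RSS anchor rarely collects two criteria.

Other defaults (`AnnotParams`), all mirroring the generator's construction
ranges with no slack hidden elsewhere:

| parameter | default | rationale |
| --- | --- | --- |
| `v_len_range` | 270–348 nt | generator's V-exon codon range × 3 |
| `v_min_content` | 3 of 4 hallmarks | emission floor: every single planted defect leaves 3 hallmarks intact, while junk ORFs near chance RSSs score ≤ 2 |
| `first_cys_window` | codons 18–25 | tolerant window around the planted Cys-21 |
| `j_len_range` | 45–75 nt | generator's J range |
| `d_rss_score` | 2 | both D flanks must be near-consensus; a planted heptamer re-read with the wrong spacer class plus a chance nonamer otherwise fabricates D calls |
| `leader_window` | 800 bp | upstream search distance for L-PART1 |
| `c_min_identity` / `c_min_coverage` | 80% / 0.8 | C placement works from spliced cDNA references |

The V-exon search is **shortest-valid-first**: with the scrubbing guarantees
above, the shortest in-frame `AG`-to-RSS reading satisfying the hallmarks is
provably the planted one, whereas longest-first can absorb intronic codons
when a chance intronic Cys lands in the first-Cys window.

Two structural de-overlap rules resolve genuinely ambiguous readings:

- a J candidate overlapping a D candidate is dropped — a D's left 12-RSS is
  geometrically identical to a J anchor, but the D interpretation rests on
  two near-consensus flanking RSSs, which is categorically stronger
  evidence;
- a J candidate overlapping an admitted pre-joined cassette is dropped — the
  fused exon contains J-derived sequence, so a partial J-shaped reading of
  the same span is subsumed by the full-cassette interpretation.

Functionality classification follows IMGT semantics: broken reading frame or
internal stop → **P**; intact frame with a defective RSS, splice site or
motif → **ORF**; otherwise **F**. Coding defects dominate. Pre-joined V
genes are classified from leader splice, fused-exon structure and anchors,
with no RSS requirement.

Families cluster V genes by single linkage at ≥ 75% global identity
(inclusive: a pair at exactly 75.0% co-clusters). Identity is percent
matches in a global alignment excluding terminal-gap columns
(match +1, mismatch −1, gap open −2, extend −0.5); the argument order is
canonicalized because optimal-alignment tie-breaking is otherwise
order-dependent. Naming is positional from the locus 5' end, with the
J/D/C sets numbered per duplicated C unit when more than one C gene is
present; locus orientation follows the C gene's strand.

## 3. Numerical choices

- FPKM is computed in double precision directly from its definition
  (`count / (length/10³) / (library/10⁶)`); per-chain values are plain sums.
- The haplotig test uses **median** 10-kb window depth inside the locus vs
  the flanks (robust to isolated repeat windows), with verdict bands
  0.35–0.65 ("suspect haplotig") and 0.8–1.25 ("consistent with
  duplication"); anything else is inconclusive. The ratio is scale-invariant.
- Jukes–Cantor distance is `−(3/4)·ln(1 − (4/3)·p)` with pairwise deletion
  of gapped sites; saturation (`p ≥ 0.75`) is an error, never clamped.
- BIONJ follows the variance-weighted neighbor-joining reduction with the
  weight λ clamped to [0, 1]; Q-criterion ties break on the lowest index
  pair, making trees deterministic. Final three-taxon branch lengths come
  from the closed-form three-point formulas. Negative branch-length
  estimates are floored at 0.
- Midpoint rooting uses a double sweep to find the tree diameter and places
  the root exactly at half the diameter; re-rooting a midpoint-rooted tree
  is a fixed point within 1e-9.
- Subsampling uses numpy's multivariate hypergeometric sampler, so
  subsampled counts are exactly conserved and seed-deterministic.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the acceptance script derives all child seeds (each < 2³¹) from a
  single `--seed`.

## 4. What the generator does and does not emulate

Emulated: RSS-anchored V/D/J architecture with the 12/23 rule; leader/V
splicing; inverted V clusters and whole-locus inversions; multi-C loci with
per-unit J/D sets; V families with controlled identity structure; the four
planted defect classes; germline pre-joined V–J cassettes; cross-locus
repertoires; Poisson depth with a half-depth interval.

Not emulated: real intergenic composition (repeats, GC structure — the
background is uniform random, scrubbed as described); shared leader exons
between a pre-joined cassette and a neighbouring V (every cassette carries
its own leader); sequencing-read simulation (read evidence enters the
pipeline only as an externally supplied boolean per candidate); multi-exon
V genes; RSS spacer-length variability beyond the exact 12/23 classes;
somatic hypermutation; allelic variation.

## 5. Limitations

- Defects that destroy the discovery anchor itself (a broken V/J RSS, a
  broken V acceptor or J donor) are not de-novo discoverable at exact
  coordinates — there is nothing left to anchor on. They are classified
  correctly when coordinates are supplied (e.g. from synteny or references),
  which is how the defect grid is evaluated.
- A locus with a single J gene cannot satisfy the similarity criterion for
  J; retaining its J requires external read support.
- The evidence filter's 60% similarity criterion assumes at least two real
  same-kind segments per locus, which holds for the generator and for
  typical TCR loci.
- `pairwise_identity` depends on the alignment scoring scheme; gapped
  alignments can score slightly above the ungapped substitution identity of
  two constructed sequences, so family thresholds should be read as
  alignment identity, not Hamming identity.
- The haplotig test assumes depth windows are i.i.d. given locus state; it
  is a screen, not a proof of assembly status.
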
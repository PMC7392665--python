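# Methods

## The model

A protein-coding transcript with its stop codon in the last exon escapes
NMD even when splicing introduces a premature-looking termination signal,
provided the termination still happens in the last exon. Skipping the
penultimate exon exploits this: if the exon carries the stop codon, the
next in-frame stop must be found in the last exon; if the exon's length is
not a multiple of three, the last exon is read out of frame and the
canonical stop disappears from the reading frame. In both cases the
ribosome reads into sequence annotated as 3′UTR, appending a novel
C-terminus to an otherwise intact protein. The pipeline asks, for every
annotated transcript, whether this skip geometry exists and what protein it
would produce.

### Geometry and translation

Exon skipping is modelled one internal exon at a time (first and last exons
cannot be skipped; multi-exon skips are out of scope). Classes are purely
geometric where possible — `Ultimate`, `Penultimate`, `Penulti_fp`,
`Internal_fp`, `Internal_fs` — while `Penulti_short` (frameshifting skip
whose new stop lies 5′ of the annotated stop, yielding a shorter
C-terminus) is only decidable after translation and is therefore assigned
as a post-translation *outcome*, not by the classifier. Outcomes are
`extended`, `boundary` (new frame terminates at the annotated stop with no
residue encoded beyond it — a corner case reported as its own category
rather than silently merged), `short`, `nmd` (new stop
upstream of the last exon; such events would be degraded and are excluded),
and `non_stop` (no stop before the transcript end; excluded and flagged).

Translation uses the standard genetic code from the annotated start codon.
Codons containing N translate to `X` and never match a stop; candidates
whose novel C-terminus contains `X` carry an `has_ambiguous` flag so counts
remain auditable. The divergence point between canonical and skipped
proteins is computed at the protein level, because the hybrid codon spanning
the new junction can re-encode the canonical amino acid. "Gained" counts
residues from the divergence point to the new stop; "beyond the stop"
counts the subset whose first codon base lies strictly 3′ (in transcript
orientation, compared in genomic coordinates) of the last base of the
annotated stop codon — this is robust to junction codons straddling the
splice site. Both filter thresholds (≥ 20 gained, ≥ 10 beyond) are
inclusive. Deduplication keys on the five genomic anchors (upstream exon
end, exon start/end, downstream exon start, stop position) plus chromosome
and strand; the representative is the lexicographically smallest transcript
id, which makes output deterministic across runs.

Coordinates are 1-based inclusive in GTF input and output tables, 0-based
half-open everywhere in memory; the conversion happens only at the parser
boundary. Transcripts whose annotated ORF is not a multiple of three, whose
stop codon is non-canonical, or that lack a `stop_codon` feature are
dropped with a logged count rather than raised — real annotations contain
such records. A stop codon split across an exon junction is attributed to
the exon containing its first base.

## PSI estimation

MISO-style posterior inference is replaced by the deterministic
junction-count ratio estimator. Inclusion reads are halved because an
included exon contributes two informative junctions while an excluded one
contributes one; with junction counts generated per molecule (each included
molecule adds one read to *each* inclusion junction) the estimator is
unbiased, which the calibration test verifies at planted PSI 70 and depth
10⁴. "Supporting reads" is the plain sum `inc_up + inc_down + exc` — every
read informative about the event. Tissue cells average PSI over expressed
samples only; an event with no expressed sample in any tissue is "not
testable" rather than silently non-alternative. The tissue distance is
1 − weighted Pearson correlation between tissue PSI profiles, each event
weighted by the median absolute deviation of its PSI row, so variable exons
dominate tissue specificity; events with any missing cell are dropped from
the distance (the simplest deterministic rule). A t-SNE embedding of the
distance matrix is exposed as a convenience with a fixed default seed
(t-SNE is stochastic); rendering is left to the caller, so the package does
not depend on a plotting backend.

Target/background sets for external RBP motif discovery follow the
constitutive/regulated split: background = PSI > 90 in every stage or
PSI < 20 in every stage; target = range(PSI) > 50; the rules are provably
disjoint. The package emits the exon ± 50 bp intron FASTA pair; the motif
search itself (Homer/RBPmap) is external.

## Sequence features

Composition excludes `*` and `X` from numerator and denominator, so
fractions always sum to one; the 3′UTR side translates the first 100 codons
of all three frames after the stop *through* internal stops and averages
the three per-frame profiles unweighted. Motif scores use
`expected = p_motif · (L − m + 1)` per sequence, where `p_motif` multiplies
the summed background frequencies of each position's residue class
(wildcards contribute 1). Overlapping matches are counted — this only
affects multi-match sequences and is the natural reading of counting "at
every offset". The default background is the UniProtKB/Swiss-Prot average
amino-acid frequency table; a user proteome FASTA can replace it. The
hydrophobic class Φ in the class I/II motifs defaults to {A,V,I,L,M,F,W,Y,P}
(common SH3-ligand convention) and is a parameter, since no single
definition is universal. Proline-delta groups use strict inequalities at
±3 with the boundary values assigned to the middle (conservative) class.
The top-ΔP selection for disorder analysis defaults to n = 200 with ties
broken by candidate id, and prepends up to 10 upstream residues when
available; secondary-structure strings (e.g., SPIDER2 output) are an input,
and %coil = #C / length is the disorder proxy.

## Conservation

Last-exon ORFs are defined from the frame's first codon to the first stop
with no ATG requirement, because the scanned frames continue an upstream
CDS; frame labels are relative to the annotated frame (0), and the
highlight threshold (> 50 AA) is strict. Note that no nucleotide sequence
can terminate immediately in more than one forward frame (a stop's second
base is never T), so "all frames empty" is only achievable in the annotated
frame. The orthologue overlap test is the exact upper-tail hypergeometric
probability; the universe defaults to the number of 1:1 orthologue pairs
supplied and is configurable, since the appropriate universe depends on how
the orthologue table was built. Coordinate liftover is out of scope — the
module consumes mapped id pairs.

## Proteomics

The search database is canonical entries plus one frameshift record per
deduplicated candidate (canonical prefix to the divergence point + novel
C-terminus), accession-suffixed with the skipped-exon coordinates;
byte-identical fs sequences collapse. Digestion cleaves after K/R except
before P (the rule standard search engines default to), with ≤ 2 missed
cleavages and a minimum peptide length of 6, both configurable; peptide
m/z (charges 2–3, optional carbamidomethyl-C) supports targeted inclusion
lists. A peptide "maps to a frameshift C-terminus" only if at least one
residue lies at or past the divergence point — peptides wholly inside the
shared prefix are never fs evidence. Proteotypic = exactly one database
parent by substring search. IP-MS calls divide each replicate column by its
median (centring the bulk at 1) and require > 1.5 in every replicate;
tubulins and HSPs are excluded by configurable name patterns as habitual
false positives.

## Half-life analysis

Skipped candidates (PSI < 90 in the given cell line) are joined to measured
half-lives and partitioned by proline group; each group is compared with
all measured proteins. The default test is Welch's t-test on log
half-lives — the literature convention names Student's unpaired t-test, but
half-life distributions are right-skewed and group variances differ, so the
robust variant is the default with both toggles exposed and the choice
recorded in the report metadata. Raw p-values carry the significance calls
(matching asterisk conventions); a Benjamini–Hochberg column and a
Mann-Whitney p are reported alongside. Groups with n < 3 are reported
untested.

## Synthetic data

The generator is the package's test bed and defines its study conditions.
Toy genes are composed in transcript space: a 24-nt first exon (6-nt 5′UTR
+ ATG + five sense codons, keeping the downstream frame aligned), a
penultimate exon whose length mod 3 selects the class, and a last exon
written under *two* simultaneous frame constraints — the canonical frame
must stay open to a TAA placed at the exact position that yields the
planted `aa_beyond_stop`, while the skipped-isoform frame reads exactly
`aa_gained` sense codons (the first is TGG, guaranteeing divergence at the
junction) before its own stop. An off-frame TAA can never spell a stop in
the other frame (stops begin with T; TAA's interior is AA), which makes the
constraint-repair loop safe and convergent. Genes are laid on ≤ 100 kb
chromosomes with GT..AG introns, alternating strands; every `Ultimate` gene
carries a second isoform differing only in 5′UTR length, which must
collapse in deduplication. Frameshift-frame codons are sampled with
proline weight 0.20 versus 0.05 for canonical codons, planting the
proline/PxxP enrichment of the alternative C-termini.

Junction counts: per molecule, exclusion with probability 1 − PSI/100 (one
`exc` read) or inclusion (one read on each inclusion junction), binomial
at configurable depth. Per-tissue PSI baselines are 91–99 with zero to
three alternative tissues at 30–85 per gene.

Half-life tables mirror a 3T3 pulse-SILAC setting: 3573 measured genes,
log-normal half-lives with base 20 h and σ(ln) = 0.5 (≈ 1.65-fold geometric
spread, realistic for such data), skipped groups of 36/76/80
(P-decreased/P-unchanged/P-rich) plus 20 unskipped candidates the join must
exclude, and a planted multiplier of 0.7 confined to the P-rich block.
Under these conditions the pooled "Skipped" group is also significantly
destabilized (80 of its 192 members carry the effect) — a known difference
from real data, where the pooled effect is diluted below significance; the
planted pattern of interest is in the three subgroups. One integer seed
drives everything; outputs embed the seed and regenerate byte-identically.

### What the synthetic data does not emulate

Read-level sequencing (alignment, errors, coverage gradients), batch
effects between library protocols, annotation errors, overlapping genes,
alternative 3′/5′ splice sites, selenocysteine readthrough, and
inter-gene correlation of half-lives. Passing tests therefore demonstrate
correctness of the arithmetic and logic under the planted model, not
robustness to real-annotation pathology.

## Problem sizes and numerics

The default test suite uses 2–5 genes per class (16–40 genes) for unit
checks and 1000 genes for the oracle-equivalence sweep; the half-life
pattern is assessed over 100 seeded simulations per effect size. The full
suite runs in well under a minute on one CPU. Floating-point comparisons in
tests use relative tolerances via `pytest.approx`; the weighted-Pearson
distance is checked against a literal textbook formula, the hypergeometric
tail against exhaustive enumeration for N ≤ 12, and digestion against an
independent cleavage implementation (pyteomics) under the same rule.

## Known limitations

GFF3 input is not supported (Ensembl GTF only); multi-exon and alternative
splice-site events are out of scope (the conservation module's frame
scanner covers the cryptic-splice-site cases indirectly); the NMD model is
the last-exon geometry gate only, not the 50-nt rule; and the package does
not fetch any external resources — pinned annotations, orthologue maps,
secondary-structure predictions, and proteome backgrounds are all inputs.
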
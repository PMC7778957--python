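# Methods

## Data model and conventions

All genomic coordinates are 1-based inclusive (Ensembl/Biomart convention);
the GTF reader converts nothing at the boundary. CDS coordinates run in
transcription order, so on the `-` strand the CDS coordinate increases as
the genomic coordinate decreases. Protein coordinates are 1-based residue
positions. The stop codon belongs to the CDS — every valid isoform has CDS
length `3·L + 3` for protein length `L`, checked at load — but is excluded
from protein-coordinate arithmetic.

The internal gene key is the Entrez id. Ensembl gene and UniProt ids are
resolved through an explicit mapping table at ingest; in strict mode an
unmappable id aborts the load with all offenders listed rather than being
dropped silently.

### Residues at exon junctions

A codon can straddle an exon–exon junction. Annotation sources do not
prescribe how to attribute such a residue, so we map a residue (and a
domain) to **all** exons its codons overlap by at least one base: losing
either exon destroys the codon, so both are causally involved. The same
rule makes domain→exon and exon→domain lookups exact transposes of each
other, which the tests verify.

## Interaction sources

PPI and DDI pairs are stored under canonical (lexicographically sorted)
keys, making deduplication and lookup order-independent; homotypic domain
pairs and self-interacting proteins are legal. DOMINE-style tables are
filtered to {HC, MC} by default — low-confidence inferred pairs are noise
at the scale this tool works at — and the keep-set is configurable. Merging
DDI sets is a pure union over canonical keys with cumulative provenance;
once merged, 3did-style and DOMINE-style evidence rank equally. Conflicting
annotations beyond the pair itself are not reconciled (pure union).

## Joint graph

One node per (gene, Pfam family), not per domain copy: DDI evidence is
family-level, so a duplicated domain collapses onto a single node. This is
a documented limitation — a variant distinguished only by the *copy number*
of a domain (the duplicated-kinase pattern) is invisible to family-level
presence logic. Domain nodes are created only for genes that appear in the
PPI network. PPIs with no supporting DDI contribute no joint edges but are
kept in a side index; network-level analysis needs them for edges labelled
plain `PPI`. GraphML is the attribute-preserving round-trip format; an edge
list TSV is provided for spreadsheets.

## Structure-derived interface residues

* **Chain assignment is an input.** A table lists candidate proteins per
  (structure, chain); only those candidates are aligned. There is no
  proteome-wide search.
* **Alignment.** Global alignment with free end gaps (semi-global),
  BLOSUM62, gap open/extend −11/−1, via Biopython's `PairwiseAligner`.
  Free end gaps keep unresolved chain termini from penalising identity.
  Identity = identical aligned positions / alignment columns, where the
  column count excludes terminal free gaps but includes internal gaps.
  A mapping is accepted only above 0.95 identity, strictly — 0.95 exactly
  is rejected. Whether identity should be computed over chain length or
  alignment length is genuinely open; the alignment-length choice is the
  more conservative of the two and is pinned by tests.
* **Contacts.** A residue pair is an interface contact when the minimum
  over all non-hydrogen atom pairs of the Euclidean distance is strictly
  below 5.0 Å and the residues lie on different chains. "Minimum
  heavy-atom distance" is the most common interface convention; the
  vectorised scan (scipy `cdist`) is tested against a plain all-pairs
  loop, including the exact-5.0 Å boundary. Model 1 is used when a file
  holds several models; only the first alternate location of disordered
  atoms is read; insertion codes are preserved in residue identifiers.
* **Aggregation.** Contacts are lifted through the accepted alignments
  into isoform coordinates and unioned over structures per gene pair (no
  voting or weighting); the minimum distance and the contributing
  structure ids are kept. Residues without an alignment pair drop with a
  logged count. Interface residues resolve to exons through the same
  codon-footprint rule as domains.

## Scoring semantics

The denominator counts joint **edges** (domain pairs), not distinct
query-side domains: a PPI mediated by two DDIs from which one is lost
scores 0.5 regardless of how many families are involved. In isoform mode
the partner side is evaluated at gene level (its full domain complement);
only in network mode, where both endpoints are user-specified, are both
sides judged against the listed isoforms. For a self-interaction both
sides live on the query isoform, so an edge is retained only if both
families are present. A gene pair with no joint edges raises a typed
"no structural annotation" condition — deliberately distinct from a score
of 0.

Missing domains have two contexts: against an isoform (family absent from
the isoform, annotated on another isoform of the gene) and against an
input list (absent from *all* listed isoforms, present on some unlisted
one). The expression filter keeps transcripts with values strictly above
the threshold (default 1.0); a value of exactly 1.0 is not abundant.
Exon-coordinate queries resolve only against annotated exons — coordinates
overlapping zero or several exons of the gene are an error listing the
candidates; novel exons are not invented. Scores are descriptive
fractions; no multiple-testing machinery applies.

All report writers iterate in sorted order, so identical inputs produce
byte-identical outputs.

## Synthetic data generator

The generator emulates the *topology* of the problem: multi-exon genes on
both strands with 100-base introns, fully coding exons (the last three
bases of each transcript being the stop codon), alternative isoforms that
drop internal exons while preserving frame, Pfam intervals per isoform,
PPI/DDI tables in both dialects (including low-confidence rows that the
default load must drop), RSEM-like expression values, and two-chain toy
PDB files with one idealised CA atom per residue at 10 Å spacing, where
selected residue pairs are placed at an engineered distance below (or, for
boundary tests, exactly at) 5 Å.

It does **not** emulate: UTRs and non-coding exons, realistic intron/exon
length distributions, sequence composition, side-chain geometry or real
folds, unresolved loops, or noisy chain-to-protein assignments. Passing
tests therefore demonstrate the correctness of the coordinate arithmetic,
graph construction, filtering and scoring logic under valid inputs — not
robustness to the messiness of real annotation releases.

Every fixture ships a manifest of expected results — joint edges,
per-isoform scores, residue contacts, interface exons — computed inside
the generator by plain independent loops (cumulative-length walks,
all-pairs distance scans, counting) that share no code with the main
modules. The pipeline must reproduce the manifests exactly; this is the
regression baseline. All randomness (sequences, random-fixture topology)
flows from a single seed, and the same seed yields byte-identical files.

Named scenarios cover the canonical case studies: a sole mediating domain
lost with one exon (score 0 and a flagged edge), two mediating DDIs with
one lost (scores 0.5 vs 1.0), a homotypic self-interaction lost while a
heterotypic partner is retained, a hub gene whose kinase-domain exon
mediates 31 of 33 partner edges, and an exon outside every domain that
carries engineered interface residues.

Default problem sizes (8 genes, ≤ 3 isoforms/gene, ≤ 6 exons, ~40 % PPI
density, 2 structures per random fixture; property suites run 100 seeds)
keep each fixture small enough that exhaustive base-level and all-pairs
oracles remain practical while still exercising both strands,
junction-spanning codons, partial domain losses and unsupported PPIs.

## Known limitations

* Family-level presence logic cannot see duplicated-domain changes.
* Isoform-mode scores judge the query side only; a partner whose own
  domains are lost shows up only in network mode.
* No mmCIF input, no liftover between genome builds, no UTR modelling,
  no linear-motif annotation, and no detection of splicing events from
  raw reads — the tool consumes transcript lists and annotated events.
* The exact atom-level definition behind published "< 5 Å" interfaces
  varies between pipelines; results near the cutoff depend on it.
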
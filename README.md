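# spliceppi

Domain-resolved scoring of how alternative splicing rewires the
protein–protein interactome.

## The problem

Most protein–protein interaction (PPI) resources record interactions at the
gene level, but a gene's splice isoforms can differ in the protein domains
they retain. When a PPI is mediated by a domain–domain interaction (DDI)
between Pfam families, an isoform that loses the mediating domain likely
loses the interaction — while an isoform that loses one of *several*
mediating domains may only weaken it. `spliceppi` integrates PPIs, DDIs,
genomic annotation and experimentally resolved structures so that splicing
events (isoform choices, exon skipping, transcript lists from RNA-seq) can
be interpreted at domain and residue resolution.

It is a library plus a thin CLI, aimed at computational biologists who work
with splice-isoform or exon-level data and want structural context for
interaction changes.

## The model

**Joint PPI–DDI graph.** Nodes are (gene, Pfam family) units, written
`<entrez>/<pfam>`. An edge `(g₁, f₁) — (g₂, f₂)` exists iff `(f₁, f₂)` is a
known DDI *and* `(g₁, g₂)` is a PPI. DDIs come from a 3did-style pair list
unioned with a DOMINE-style table whose low-confidence (LC) rows are
dropped by default.

**Interaction score.** For an isoform *i* of gene *g* and a partner gene
*p*, let *E(g, p)* be the joint edges between the two genes and *R(i, p)* ⊆
*E* the edges whose *g*-side family is annotated on *i*. The score is

    score(i, p) = |R(i, p)| / |E(g, p)|   ∈ [0, 1]

1 = all structural evidence retained, 0 = all lost. Pairs with no joint
edges are reported as "no structural annotation", a distinct condition from
score 0. Scoring is fractional by design: an all-or-nothing rule cannot
express the case where one of two mediating domains is spliced out.

**Exon level.** Protein coordinates are converted codon-by-codon to genomic
coordinates (1-based, strand-aware), so domains and individual residues map
to exons. Any domain overlapping a skipped exon by ≥ 1 coding base is
treated as lost with it. Independently, inter-chain residue pairs within a
strict 5 Å minimum heavy-atom distance in a co-resolved structure — after
aligning isoform sequences to chains at > 95 % identity — are lifted to
exons, giving residue-level interface evidence even for exons outside every
annotated domain.

**Network level.** A list of gene/transcript/protein ids (optionally
filtered to transcripts with expression strictly above 1.0) becomes a
subnetwork whose edges are labelled `PPI-DDI` (with weight = retained
fraction over the listed isoforms) or plain `PPI` (no structural evidence).
Filtering at any minimal positive weight reproduces the classical
all-or-nothing behaviour.

## Worked example

```bash
spliceppi make-fixtures --scenario two_domain_partial_loss --seed 0 --out fixtures/
spliceppi isoform NCK2-202 --config fixtures/two_domain_partial_loss/config.yaml \
    --out nck2_202.tsv
```

prints

```
missing domains: PF00017
NCK2-202 -- 102: score 0.50 (1/2 DDIs retained)
report written to nck2_202.tsv
```

The fixture models an SH2/SH3 adaptor whose PPI with its partner (gene key
`102`) is mediated by two DDIs, one via the SH2-family domain PF00017 and
one via the SH3-family domain PF00018. Isoform NCK2-202 lacks the exon
coding for PF00017, so it retains 1 of the 2 mediating domain pairs and the
interaction scores 0.5; the full-length isoform NCK2-201 scores 1.0.

The exon mode answers "what breaks if this exon is skipped":

```bash
spliceppi make-fixtures --scenario hub_exon --seed 0 --out fixtures/
spliceppi exon 101:100470-100769 --config fixtures/hub_exon/config.yaml --out alk.tsv
# exon ENSE00000000003: domains PF07714; 31 of 33 partners affected
```

and the network mode builds a weighted subnetwork for a transcript list,
optionally expression-filtered (`--expression expr.tsv --threshold 1.0`,
strictly greater than).

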
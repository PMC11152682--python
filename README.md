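# adipoptm

Integrated analysis of proteome, acetylome and phosphoproteome time
courses in differentiating adipocytes: proteome-corrected PTM site
quantification, staged differential abundance, directional pathway
enrichment with cross-cell-line comparison, and weighted co-abundance
network inference with key-driver extraction — exercisable entirely on
synthetic data with planted ground truth.

## Who this is for

Proteomics analysts working with label-free (LFQ) or isobaric-tag (TMT)
quantification of a differentiation time course — here a three-stage
design (preadipocyte → immature → mature adipocyte, three replicates per
stage) measured on three layers: a global proteome, an enriched lysine
acetylome (AcK sites such as `FASN_K673`) and an enriched
phosphoproteome (PP sites such as `CD44_S161`).

## The analysis

**Site quantification.** A feature is quantifiable when observed in all
replicates of at least one stage. Raw intensities are median-aligned and
variance-stabilized with a generalized log (reported on the log2 scale).
Each PTM site is *proteome-corrected* per sample,

```
corrected(site, s) = log2 site(s) − log2 parent protein(s),
```

so site changes reflect modification stoichiometry rather than protein
amount. Whole-condition missing blocks are imputed from a downshifted
Gaussian (mean − 1.8·SD, width 0.3·SD per sample).

**Contrasts.** For the *early* (immature vs. preadipocyte), *late*
(mature vs. immature) and *complete* (mature vs. preadipocyte)
comparisons: log2FC = difference of group mean log2 intensities, a
two-sided pooled-variance Student t-test, Benjamini–Hochberg adjustment
per layer and contrast, significance at adjusted p < 0.01.

**Enrichment and direction.** Proteins carrying significant sites are
tested against GMT gene sets with the upper-tail hypergeometric test
over the layer's quantified-protein universe (retention: overlap ≥ 3,
≥ 4 % of the term, p < 0.05). Each retained set gets a *direction* — the
median log2FC of its significant sites — and two datasets' directions
are compared by Pearson correlation over shared sets.

**Co-abundance network.** Over the concatenated proteome + corrected
AcK + corrected PP feature space: signed adjacency
`a = ((1+r)/2)^β` with soft power β = 17, topological overlap
(TOM), average-linkage clustering of 1 − TOM with module size bounds
50/500, deepsplit 2 and eigengene merge cut 0.3, followed by a signed
kME membership pruning (≥ 0.9). Each module is summarized by its
eigengene (first principal component); modules correlate against the
ordinal differentiation time. Per feature, kME (module membership) and
GS (trait significance) combine into the key-driver score
`|kME| × |GS|`; the Top 30 drivers are exported with a TOM-derived
connectivity edge list (edges ≥ 0.5 emphasized).

## Worked example

Generate a synthetic study with planted truth and run the full
pipeline:

```bash
adipoptm simulate --out fixture --seed 1
adipoptm run --config run.yaml --out results --log-level INFO
```

where `run.yaml` points at the fixture files:

```yaml
proteome: fixture/proteome.tsv
acetylome: fixture/acetylome.tsv
phospho: fixture/phospho.tsv
design: fixture/design.tsv
genesets: fixture/genesets.gmt
seed: 1
```

The log reports the counts each stage produced:

```
proteome: 599 of 600 features pass the replicate-presence filter
acetylome: 523 sites corrected, 1 unmatched
acetylome complete: 201/523 significant (adj p < 0.01)
acetylome: 9 sets retained, 9 with direction
network: 4 modules (+grey), sizes {'blue': 121, 'brown': 79, 'turquoise': 121, 'yellow': 55}
key drivers of turquoise: 30 features
```

Reading this: one protein never reached three replicates in any stage;
one acetyl site had no quantified parent protein and is reported
unmatched rather than silently dropped; 38 % of corrected AcK sites
change significantly across the complete differentiation (the synthetic
truth plants strong module and gene-set effects); the network recovers
four co-abundance modules whose eigengenes correlate with the time
course (`results/module_trait.tsv`):

```
module      r        p
blue       -0.833    0.0053
brown      -0.836    0.0050
turquoise   0.816    0.0073
```

positively-correlated modules rise with maturation, negatively-
correlated ones fall — matching the planted signs. The Top-30
key-driver tables (`key_drivers_<module>_{nodes,edges}.tsv`) list each
driver's layer of origin, complete-process log2FC, kME, GS and score,
plus a [0, 1] connectivity edge list importable into any graph tool.

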
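# ldblocks

Perfect-LD block clustering and genome-browser track export for SNP
genotype panels.

Triangular correlation plots of pairwise linkage disequilibrium (LD)
become unreadable when a region is dense in SNPs or when perfectly linked
SNPs are scattered rather than adjacent.  `ldblocks` takes the alternative
view: it groups SNPs into **clusters** — blocks of markers in perfect LD
(r² = 1) — and renders each cluster as a single genome-browser track
record whose member SNPs are joined by a horizontal line.  Clusters are
then organised into **LD architectures** centered on a gene, a reference
SNP, the imported region, or a whole chromosome, with the tracks ordered
either by a hierarchical tree of the blocks or by decreasing r² to a
reference SNP.  The output is plain BED12, ready to load as a custom track
next to regulation, conservation or association annotation.  Intended
users are geneticists selecting tag SNPs or chasing causal variants behind
an association signal.

## Method

For two biallelic loci with unphased diploid genotypes, haplotype
frequencies p_AB, p_Ab, p_aB, p_ab are estimated by two-locus EM (only the
double-heterozygote class is phase-ambiguous), and

    D  = p_AB·p_ab − p_Ab·p_aB
    r² = D² / ( p_A(1−p_A) · p_B(1−p_B) )

with pairwise-complete deletion for missing genotypes.  Clusters are the
connected components of the graph joining markers with r² ≥ 1 − ε
(default ε = 1e−6); with complete data perfect LD is transitive, so
components are cliques (a verification pass warns otherwise).  Blocks are
ordered by average-linkage (UPGMA) hierarchical clustering of the distance
**1 − r²**, where the distance between two blocks is one minus the mean
r² over their cross-pairs.  SNP-centered architectures keep only variants
with r² ≥ 0.5 to the reference SNP and order tracks by decreasing r², with
the value embedded in the track name.  A minor-allele-frequency threshold
can exclude rare SNPs before clustering, and records can be colored by a
5-bin MAF ramp.

## Worked example

`examples/03_snp_centered.py` simulates a reference SNP plus five variants
at target r² values 0.95, 0.80, 0.60, 0.40, 0.20 (1,000 samples) and
builds the SNP-centered architecture:

```
track 'snp_names':  ['rs1', 'rs2', 'rs3', 'rs4']
track 'rs1':  r2=1.000  ['rs1']
track 'rs2':  r2=0.940  ['rs2']
track 'rs3':  r2=0.775  ['rs3']
track 'rs4':  r2=0.627  ['rs4']
```

The first track lists the retained SNPs; the second holds the reference
(and any perfectly linked SNPs); the remaining tracks descend in realized
r² to the reference — close to their simulation targets — while the
variants whose r² falls below the 0.5 inclusion threshold (targets 0.40
and 0.20) are excluded entirely.  `examples/02_region_architecture.py`
shows the same machinery region-centered, with two planted blocks
recovered exactly, ordered by their UPGMA tree, and written to a BED12
file that passes strict validation:

```
planted blocks: [('rs1', 'rs2', 'rs3'), ('rs4', 'rs5'), ('rs6',)]
track 'snp_names': ['rs1', 'rs2', 'rs3', 'rs4', 'rs5', 'rs6']
track 'rs1': ['rs1+rs2+rs3']
track 'rs4': ['rs4+rs5']
track 'singletons': ['rs6']
dendrogram: (rs1:0.2242910638,rs4:0.2242910638);
wrote region_example.bed: 9 BED12 records validate
```

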
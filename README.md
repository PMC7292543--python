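# fnlqtl

A QTL-discovery toolkit for a biparental cucumber cross segregating for
fruit neck length (FNL) — the distance from the distal pedicel end to the
endocarp, a key fresh-market quality trait. The package implements the full
computational chain used to clone a major-effect FNL locus, and ships a
synthetic-data generator so every stage can be exercised, tested and
benchmarked with known ground truth:

1. **QTL-seq (bulked segregant analysis).** Extreme long- and short-necked
   F2 plants are pooled and sequenced. At each site, with P the long-neck
   parent's allele and read counts `P_Ln, M_Ln` in the long bulk and
   `P_Sn, M_Sn` in the short bulk,

   ```
   SNP-index(Ln) = P_Ln / (P_Ln + M_Ln)
   SNP-index(Sn) = P_Sn / (P_Sn + M_Sn)
   Δ(SNP-index)  = SNP-index(Ln) − SNP-index(Sn)
   ```

   so Δ = +1 when the long bulk carries only the long parent's genome at a
   site and the short bulk only the short parent's, −1 with the bulks
   exchanged, and 0 when both bulks look alike. Δ is loess-smoothed along
   each chromosome and compared against a 99% confidence envelope obtained
   by Monte-Carlo simulation of unlinked bulks at the observed read depths.

2. **Interval-mapping cross-validation.** A Kosambi genetic map
   (`d = 25·ln((1+2r)/(1−2r))` cM) is built from EM maximum-likelihood
   recombination fractions, and a Haley–Knott regression scan on F2:3
   family means yields `LOD = (n/2)·log10(RSS0/RSS1)`, the explained
   variance `R² = 1 − 10^(−2·LOD/n)` and a 2.0-LOD support interval.

3. **Recombinant fine mapping.** Recombinants between flanking markers are
   progeny-tested (all-long → PP, all-short → MM, segregating → PM), and
   each recombinant's marker haplotype constrains where the causal locus
   can sit; intersecting the constraints delimits the candidate interval by
   its bounding markers.

4. **Expression analysis.** Relative expression by the Livak 2^−ΔΔCt method
   with technical-replicate averaging on the Ct scale and SD propagation.

5. **Phylogeography.** p-distance neighbour-joining trees (Saitou–Nei with
   the Studier–Keppler Q-criterion) over promoter variants in a natural
   accession panel, bootstrap bipartition supports, long/short
   classification at the panel-mean FNL, and tree-group × phenotype ×
   geography contingency tables.

## Worked example

`examples/02_linkage_scan.py` simulates 135 F2 plants typed at 30 markers,
derives 102 F2:3 families of 10 plants each (the QTL explains ≈30% of
phenotypic variance) and scans the family means:

```
map length        : 97.8 cM over 30 markers
peak LOD          : 7.3 at 59 cM (11.79 Mb)
R^2 at peak       : 0.28
2-LOD interval    : 47-66 cM (9.80-12.94 Mb)
true QTL          : 12.00 Mb
```

The scan recovers the simulated QTL: the LOD peak lands next to the true
position, the QTL explains 28% of the family-mean variance, and the 2.0-LOD
support interval brackets the truth. The other scripts in `examples/`
demonstrate the QTL-seq scan, fine mapping (which corners the causal locus
between its two flanking markers), qPCR fold-change recovery and the
accession-panel phylogeny.

The whole chain can also be run from the shell:

```sh
fnlqtl all --seed 1 --out runs/demo
```

which writes per-stage TSV/VCF/BED/Newick/JSON artifacts and a
`manifest.json` with checksums; reruns with the same seed reproduce the
checksums exactly.

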
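# splidkit

Tools for extracting **split-inducing indels** from multiple sequence
alignments and coding them as binary phylogenetic characters, together
with tree-distance evaluation and an indel-aware sequence simulator.

A split-inducing indel is a gap run with identical start/stop columns
shared by at least two taxa that does not conflict with other indels at
the same locus; each one defines an approximate bipartition of the
taxon set and becomes one presence/absence character (missing sequence
data coded `?`). Extraction applies three rules per indel locus:

1. keep indels present in ≥ 2 taxa with size within the configured
   bounds (default: size ≥ 2, unbounded above);
2. discard candidates that overlap another candidate (both members of
   an overlapping pair are dropped);
3. in *strict* mode (the default), additionally discard candidates
   overlapping a single-residue indel found in ≥ 2 taxa; *fuzzy* mode
   keeps them.

## Layout

| module               | contents |
|----------------------|----------|
| `splidkit.alignio`   | MAF / aligned-FASTA readers, terminal-gap masking, block filtering, concatenation with `?` padding |
| `splidkit.engine`    | gap runs → indels → loci → rules 1–3 → binary coding, summary statistics |
| `splidkit.matrix`    | binary matrices, invariant-column removal, FASTA/PHYLIP/NEXUS writers, TSV summary |
| `splidkit.treedist`  | Newick parsing, Robinson–Foulds and quartet distances with normalizations d/(2n−6) and d/C(n,4), split–tree compatibility, tree rescaling |
| `splidkit.sim`       | F81 evolution along a tree with Poisson-placed insertions/deletions (geometric or Lavalette lengths), true alignment + event log, block splitting |
| `splidkit.cli`       | `splidkit extract | concat | simulate | treedist | stats` |

## CLI examples

Extract characters from alignment blocks (strict mode, FASTA matrix):

```sh
splidkit extract blocks/*.fa --out matrix.fa --summary summary.tsv
splidkit extract genome.maf --out matrix.nex --out-format nexus \
    --mode fuzzy --min-size 2 --drop-invariant
```

Concatenate filtered blocks, compare trees, simulate:

```sh
splidkit concat blocks/*.fa --out concat.fa
splidkit treedist ref.nwk inferred.nwk      # prints: d_RF d'_RF d_Q d'_Q
splidkit simulate --tree guide.nwk --length 5000 --seed 1 \
    --rescale-height 2.0 --split-blocks --out-prefix out/sim
```

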
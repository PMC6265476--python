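# genelinker

Detect operon-like gene arrays in bacterial genomes by searching for a
single conserved "hit" gene with profile HMMs and then locating its
"partner" genes under rule-defined proximity, orientation and length
constraints.

The pipeline:

1. **Genome preparation** — six-frame translation of assembled genomes
   (FASTA), one candidate ORF per stop-to-stop segment anchored at the
   5'-most ATG (then TTG, then GTG). Optional GFF3 annotation is merged in
   to recover genes with non-canonical starts.
2. **Searching** — every candidate protein is scored against a profile-HMM
   library (HMMER 3 `hmmsearch`); hits need a full-sequence bit score of at
   least 20, optionally constrained by a per-profile expected-length table
   (±100 aa by default for the TA preset).
3. **Filtering** — partner genes are searched around each hit under
   structural requirements (orientation, hit/partner length bounds, maximum
   distance and overlap); partners with ≥8 consecutive ambiguous
   nucleotides are removed; hits without a qualifying partner are discarded
   with a recorded reason.
4. **Grouping** — hits, partners and discarded hits are clustered by
   sequence similarity networks (BLAST+ `blastp`, e-value ≤ 0.01, identity
   ≥ 30%, connected components); discarded clusters are mapped back to
   their nearest accepted hit cluster.
5. **Reporting** — per-genome copy-number matrices for hit clusters,
   partner clusters, operon types and discarded clusters; iTOL heatmap
   datasets keyed by genome id; a detailed per-operon TSV.

Built-in presets: `TA` (two-gene toxin/antitoxin arrays: partner on either
side, hit 30–200 aa, partner 50–150 aa, gap ≤ 50 bp, overlap ≤ 20 bp),
`RND` (efflux pumps: partner upstream, hit 700–1500 aa, partner
100–1000 aa, gap ≤ 500 bp, overlap ≤ 20 bp) and `flex` (nearest-neighbour
discovery). Every field can be overridden on the command line.

## Requirements

Python ≥ 3.10 with biopython, numpy, pandas, networkx and click, plus the
external executables `hmmsearch`/`hmmbuild` (HMMER 3) and
`blastp`/`makeblastdb` (NCBI BLAST+) on the PATH.

## CLI

Generate a deterministic synthetic dataset with planted gene arrays (all
violation classes), a truth table and a toy profile library:

```sh
genelinker fixtures --out demo --seed 1 --genomes 20
```

Run the search with the TA preset:

```sh
genelinker run --genomes demo/genomes \
    --hmms demo/profiles/library.hmm \
    --preset TA --out demo/results
```

Outputs in `demo/results/`: `{hits,partners,operons,discarded}_counts.csv`,
matching `itol_*.txt` heatmap datasets and a per-operon `operons.tsv`.
Structural requirements can be overridden with flags such as
`--orientation`, `--hit-min-length`, `--partner-max-length`,
`--max-distance`, `--max-overlap`; see `genelinker run --help`.

## Layout

```
src/genelinker/
  genome_io.py       FASTA/GFF3 input, six-frame ORF extraction, merging
  profile_search.py  hmmsearch wrapper, bit-score and length filters
  operon_filter.py   structural requirements, partner search, verdicts
  ssn_clustering.py  blastp similarity networks, components, labelling
  reporting.py       count matrices, iTOL datasets, operon table
  presets.py         TA/RND/flex presets, overrides, length tables
  fixtures.py        synthetic planted genomes + toy profile families
  pipeline.py        end-to-end orchestration
  cli.py             click command line
```
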
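# atlastax

Sample-specific taxonomic partitioning of marker-gene sequencing reads.

Database-search classifiers for 16S rRNA amplicons usually collapse an
ambiguous read to the most recent common ancestor (MRCA) of all of its
matches — genus at best, often family or phylum. `atlastax` keeps the
ambiguity visible and useful instead. For every query it separates the
reference hits that are *significantly* associated with it (the "outlier"
hits) from the merely similar ones, then clusters references that keep
being confused with one another — across the whole sample — into
**partitions**, and assigns each query to a partition labelled with the
MRCA and the full species list of its members. Because a partition is
typically a handful of species inside one genus, the answer becomes "one
of the three *Bacillus cereus*-group species" where a plain MRCA
classifier says "*Bacillus*" or worse. Queries without a clearly
supported neighborhood are left unclassified, by design.

It is aimed at microbiome researchers running amplicon surveys who want
sub-genus resolution and honest uncertainty from an ordinary BLAST
workflow, without the cost of phylogenetic placement.

## Method in brief

1. **Outlier detection.** The pairwise BLAST alignments of a query's hits
   (14-field tabular format with aligned strings) are projected into a
   query-anchored multiple alignment. Columns are scored with the
   Bayesian integral log-odds (BILD) score
   `S(c) = log2[Γ(A)/Γ(A+n) · Π_i Γ(α_i+c_i)/Γ(α_i)] − Σ_i c_i log2 p_i`
   (Dirichlet-multinomial vs i.i.d. background, Jeffreys prior by
   default). Every prefix cut of the bitscore-ranked hit list is scored
   by the column-local two-group gain
   `Δ(k) = Σ_cols max(0, S(top)+S(rest)−S(all))`; the cut maximising the
   per-member gain wins if it clears a significance gate (`--min-gain`,
   20 bits), otherwise the whole list is the outlier set when it is
   strongly associated as a family, or the set is empty.
2. **Confusion graph.** Edge weight w(u,v) counts the queries whose
   outlier set contains both references; edges below mean − 2·sd of all
   weights are pruned; Louvain modularity optimisation yields the
   partitions (singletons allowed).
3. **Assignment.** A query joins the unique partition holding at least
   50% (`--threshold`) of its outlier set; ties stay unclassified.
   OTU count tables can be filtered (abundance / prevalence) and
   aggregated by partition for downstream association analyses.

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

Simulate a small world of 3 reference clades (3 references each, one
genus per pair of clades) and 24 reads, then run the pipeline from the
bundled hermetic hit table:

```sh
atlastax simulate --n-groups 3 --refs-per-group 3 --ancestor-length 400 \
    --query-length 150 --queries-per-group 8 --seed 7 --out-dir world
atlastax run --queries world/queries.fasta --reference world/reference.fasta \
    --taxonomy world/taxonomy.tsv --hits world/hits.tsv --out-prefix demo
```

The run log reports each stage:

```
INFO atlastax: n_queries: 24
INFO atlastax: n_queries_with_outliers: 24
INFO atlastax: n_graph_nodes: 9
INFO atlastax: n_graph_edges_prefilter: 18
INFO atlastax: n_graph_edges_postfilter: 18
INFO atlastax: n_partitions: 3
INFO atlastax: n_singleton_partitions: 0
INFO atlastax: n_assigned: 23
INFO atlastax: n_unclassified: 1
```

All 9 references entered the confusion graph, the three true clades came
out as the three partitions, and 23 of 24 reads were assigned (one read's
outlier set straddled two partitions and was conservatively left
unclassified). `demo.partitions.tsv` shows each partition with its MRCA —
note partitions 0 and 1 share the genus label `Genus0`, i.e. they are
*sub-genus* groups the MRCA alone could not distinguish:

```
partition_id  members                     mrca                          mrca_rank  size
0             ref_g0_0,ref_g0_1,ref_g0_2  Bacteria;...;Genus0           genus      3
1             ref_g1_0,ref_g1_1,ref_g1_2  Bacteria;...;Genus0           genus      3
2             ref_g2_0,ref_g2_1,ref_g2_2  Bacteria;...;Genus1           genus      3
```

and `demo.assignments.tsv` gives per-read calls with the membership
fraction and the species list of the assigned partition:

```
query_id    partition  fraction  mrca                 species
query_g0_0  0          1.0000    Bacteria;...;Genus0  Species_g0r0;Species_g0r1;Species_g0r2
```

With real data, replace `--hits` by a blastn run (`atlastax search`, or
let `run` invoke blastn itself) against your reference FASTA + taxonomy
TSV. The library surface mirrors scikit-learn if you prefer Python:

```python
from atlastax import AtlasPartitioner, parse_blast_tabular, read_fasta, read_taxonomy_map

est = AtlasPartitioner(min_gain=20.0, assignment_threshold=0.5)
est.fit(read_fasta("queries.fasta"), parse_blast_tabular("hits.tsv"),
        taxonomy=read_taxonomy_map("taxonomy.tsv"))
est.labels_          # partition id per reference in est.reference_ids_
est.predict()        # per-query Assignment records
```

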
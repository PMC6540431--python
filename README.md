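# famseq

Gene-family annotation and expression profiling for de novo
transcriptomes, with a ground-truthed synthetic data generator.

Given a transcriptome assembly (nucleotide FASTA), curated reference
protein sets per gene family, and paired-end reads, the pipeline:

1. **`read_qc`** — removes read pairs with sequenced adaptors, more than
   5% unknown nucleotides, or more than 50% of bases below Phred 10
   (strict inequalities; pair-level removal keeps mates synchronized).
2. **`redundancy`** — collapses transcripts sharing ≥ 98% identity with a
   greedy longest-first pass (cd-hit-est-style, `-c 0.98 -n 8` defaults),
   retaining the largest sequence of each cluster.
3. **`orf_translate`** — six-frame translation, ORF enumeration, and
   completeness classification (complete / 5′-partial / 3′-partial /
   internal), with homology-based refinement of ambiguous start calls.
4. **`homology_search`** — an in-house translated homology search:
   full Smith–Waterman (BLOSUM62, affine gaps 11/1, numba-compiled)
   of protein queries against all six frames of every transcript, with
   Karlin–Altschul E-values (λ = 0.267, K = 0.041) and a 1e-5 cutoff.
5. **`family_annotation`** — the iterative annotation procedure: known
   references are matched to their top-hit gene clusters; candidate hits
   to unannotated clusters become novel genes if their best ORF exceeds
   half the family's average complete-ORF length (OR 406, GR 447, IR 676,
   OBP 178, CSP 132, CXE 563, CYP 510 aa), newly found peptides join the
   query set, and the search repeats to a fixpoint. Hits interrupted by
   in-frame stops without a qualifying ORF are flagged as pseudogenized;
   same-cluster records are merged via collapse proposals; novel genes
   are named sequentially after the existing inventory.
6. **`abundance`** — k-mer pseudo-alignment of read pairs, EM resolution
   of multi-mapping fragments, transcript/gene FPKM via the standard
   closed form, per-family expression shares, and `log2(FPKM+1)` heat-map
   matrices with per-sample breakpoints (min 1, 75th-percentile midpoint,
   sample maximum).
7. **`phylo`** — neighbor-joining family trees over p-distances with
   column-resampling bootstrap support (600 replicates by default,
   70% display threshold).

**`synthetic_data`** generates everything the pipeline consumes with known
ground truth: planted family members at controlled amino-acid divergence,
complete and truncated ORFs with UTRs, near-duplicate (≥ 98% identity)
isoforms, GC-matched decoys, and paired reads drawn from an abundance
vector with optional adaptor / N-content / low-quality contamination.
**`io_formats`** holds the strict FASTA/FASTQ/genes-trans-map parsers.

## CLI

All stages are exposed as subcommands of `famseq`:

```sh
famseq simulate --seed 1 --out sim/            # synthetic bundle (+--config YAML)
famseq qc --in1 r1.fastq --in2 r2.fastq --adaptors ad.fasta \
          --out1 k1.fastq --out2 k2.fastq --report qc.json
famseq collapse --in transcripts.fasta --c 0.98 --n 8 \
          --out-fasta reps.fasta --out-membership members.tsv
famseq orfs --in reps.fasta --out orfs.tsv --peptides peps.fasta
famseq search --queries OBP.fasta --transcripts reps.fasta --out hits.tsv
famseq annotate --transcripts reps.fasta --refs refs_dir/ \
          --out annotation.tsv --log rounds.json
famseq quant --transcripts reps.fasta --in1 k1.fastq --in2 k2.fastq \
          --map genes_trans_map.txt --out fpkm.tsv
famseq heatmap --fpkm fpkm.tsv --out-matrix matrix.tsv \
          --out-breakpoints bp.json [--render heat.png]
famseq tree --alignment aln.fasta --replicates 600 --seed 1 --out tree.nwk
```

## Notes

- E-values are computed without BLAST's effective-length corrections and
  are comparable only within this implementation.
- Trees use NJ + p-distance as a deterministic stand-in for
  maximum-likelihood inference; the supported surface is topology and
  clade support, not branch lengths.
- Clustering compares forward strands only and defines identity as
  identity columns in the optimal end-gap-free global alignment divided
  by the shorter sequence length.
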
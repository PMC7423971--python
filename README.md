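# tcrlens

TCR-beta repertoire case-control analysis: from FASTQ reads to annotated
clonotypes, diversity and usage statistics, group-exclusive V-J combination
detection, and a leave-one-out random-forest classifier — plus a V(D)J
cohort simulator that generates case/control repertoires with ground truth,
so the whole pipeline is testable without any external sequencing data.

## What it does

| Module | Role |
| --- | --- |
| `tcrlens.germline` | Germline V/J reference model, FASTA I/O (IMGT-style and a plain explicit-anchor dialect), deterministic synthetic mini-reference |
| `tcrlens.simulate` | Case/control cohort simulator: power-law clone abundances, clonal expansion in cases, group-exclusive spiked V-J combinations, sequencing errors, FASTQ + truth tables |
| `tcrlens.annotate` | Smith–Waterman (affine-gap, numba-accelerated) V/J assignment, CDR3 junction extraction between the conserved anchors, clonotype tables, AIRR TSV output |
| `tcrlens.repstats` | D50 diversity, four-bin abundance partition, CDR3 length / amino-acid composition / hydrophilicity (Hopp–Woods), shared CDR3s |
| `tcrlens.compare` | Samples × V-J matrix (reads per million), asymmetric-combination detection, Welch t / chi-square, PCA ordination, PERMANOVA (permutation and exhaustive) |
| `tcrlens.classify` | Random-forest leave-one-out CV, pooled ROC/AUC (prevalence-centered scores), stratified bootstrap CI, variable importance |
| `tcrlens.pipeline` | One-config orchestration of all stages with manifest, checksums and full seed-reproducibility |

Coordinates are 0-based half-open throughout. Clonotypes are keyed by
(V gene, J gene, junction nucleotide sequence); junctions include both
anchor residues (C…F/W). Gene-level labels strip the `*NN` allele suffix.

## CLI

```bash
tcrlens ref make-mini --n-v 20 --n-j 13 --seed 7 -o mini.fasta
tcrlens ref validate mini.fasta

tcrlens simulate --spec spec.json --ref mini.fasta -o sim/
tcrlens annotate --ref mini.fasta --in sim/case01.fastq \
    --out case01.airr.tsv --clonotypes case01.clonotypes.csv
tcrlens stats    --in 'ann/*.clonotypes.csv' --meta sim/metadata.csv -o stats/
tcrlens compare  --in 'ann/*.clonotypes.csv' --meta sim/metadata.csv \
    --min-positive 3 --n-perm 999 --seed 1 -o cmp/
tcrlens classify --matrix cmp/vj_matrix.csv --n-trees 500 --n-boot 2000 --seed 1 -o clf/

tcrlens run --config run.json    # full pipeline from one JSON config
tcrlens demo -o demo/ --seed 1   # simulate a 10-vs-10 cohort and run everything
```

`tcrlens demo` prints the case-vs-control D50 comparison, the PERMANOVA p
and the LOOCV AUC; rerunning with the same seed reproduces every
non-timing output byte-identically.

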
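# amps

Prediction of cytosine DNA methylation status in the CG, CHG and CHH
contexts, either from the DNA sequence around the cytosine (optionally
augmented with gene/repeat annotation channels) or from the methylation
levels of neighboring cytosines.

The package covers the full workflow:

* **`amps.methylome`** — FASTA and Bismark-style cytosine-report I/O,
  context assignment (H = A/C/T), and the calling rules (coverage must
  exceed 10 reads; level ≥ 0.5 ⇒ methylated).
* **`amps.tracks`** — per-chromosome annotation bit vectors (gene forward,
  gene reverse, repeat) from GFF3 / RepeatMasker `.out` / BED.
* **`amps.datasets`** — balanced training sets: one-hot `W_s × (4 + a)`
  sequence windows and length-`W_p` neighbor-level vectors, with an
  80/10/10 stratified split that deduplicates identical window sequences.
* **`amps.models`** — the classifiers: sequence CNN (16-channel conv with
  kernel `4 + a`, dense 128, dropout 0.5, sigmoid), neighbor MLP
  (20/16/8/1), a combined two-conv network, and a 50-tree random-forest
  baseline. Networks are implemented in NumPy (`amps.nn`) with plain SGD on
  binary cross-entropy; training is fully deterministic under a seed.
* **`amps.evaluation`** — accuracy/precision/recall/F1, cross-context and
  cross-species grids, window-size and dataset-size sweeps.
* **`amps.profiles`** — gene-body methylation metaprofiles: 15 bins
  (5 × 400 bp upstream, 5 body bins, 5 × 400 bp downstream), weighted mean
  `M(r) = Σ m·l / Σ l`, separately for template/nontemplate strands.
* **`amps.interpret`** — Grad-CAM importance maps over trained CNNs,
  selection of the top-scoring 50-mer per correctly classified example, and
  FASTA export for downstream motif discovery (e.g. MEME).
* **`amps.simulate`** — synthetic genomes/annotations/methylomes with known
  structure (planted motifs, annotation effects, AR(1) neighbor
  correlation, Poisson coverage, binomial reads) so everything is testable
  offline.

## CLI

```bash
amps simulate --profile motif_driven --seed 7 --out fixture/
amps tracks   --fasta fixture/genome.fa --gff fixture/genes.gff3 \
              --repeats fixture/repeats.bed --out tracks.npz
amps prepare  --fasta fixture/genome.fa --report fixture/cytosine_report.txt \
              --gff fixture/genes.gff3 --repeats fixture/repeats.bed \
              --context CG --kind sequence --n 6000 --window 400 \
              --out dataset.npz
amps train    --dataset dataset.npz --model amps_cnn --epochs 20 \
              --learning-rate 0.05 --seed 1 --out model.npz
amps evaluate --model model.npz --dataset dataset.npz
amps predict  --model model.npz --dataset dataset.npz --out calls.tsv
amps profile  --fasta fixture/genome.fa --report fixture/cytosine_report.txt \
              --gff fixture/genes.gff3 --out profiles.tsv
amps explain  --model model.npz --dataset dataset.npz --n 1000 \
              --out candidates.fa
amps crossgrid --dataset A=a.npz --dataset B=b.npz --model amps_cnn \
              --out grid.tsv
amps sweep    --axis window_size --values 100,200,400 --fasta ... --report ... \
              --out sweep.tsv
amps pipeline config.yaml        # staged run with manifest + skip-if-done
```

Paper-scale defaults (`W_s = 3200`, 500 000 sequences, 50 000 neighbor
vectors, batch 32, 20 epochs, lr 0.001) are the package defaults; the test
fixtures use smaller windows/datasets and a larger plain-SGD learning rate
so they converge within CPU budgets.

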
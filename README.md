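# ognet

Alignment-free protein orthologous-group assignment with a convolutional
network — a trainable, database-agnostic library and command-line tool.

## What problem this solves

Orthologous groups (OGs) — sets of proteins descended from a single ancestral
gene by speciation — are the standard unit of function transfer in genome
annotation. Assigning a new protein to an OG is classically done by alignment
(profile HMM search or fast protein aligners), which is accurate but becomes
the computational bottleneck at metagenome scale. `ognet` instead *classifies*
raw sequences: a convolutional network reads the residue string directly and
returns a probability for every group in the model, orders of magnitude less
work per query than alignment against a large database.

The core model is:

* a **learned amino-acid embedding**: each of the 26 extended IUPAC residue
  codes is mapped to a vector in R^D (D = 10), trained jointly with the
  classifier, so biochemically similar residues can end up close together;
* **1-D convolutions** with eight filter sizes K ∈ {8, 12, 16, 20, 24, 28,
  32, 36} (150 filters per size by default) and **SELU** activations — a
  self-normalizing network that needs no batch normalization;
* **masked adaptive max-pooling**: each filter keeps its maximum over the
  L − K + 1 valid windows of a length-L sequence, so inputs of *any* length
  yield a fixed-size motif-occurrence profile, and outputs are provably
  independent of padding and batch composition;
* a **softmax output layer directly after pooling** (no hidden layer):
  logistic regression on motif occurrences, giving calibrated-ish group
  probabilities;
* a **confidence threshold** (default 99%): a sequence is only assigned when
  the rank-1 probability reaches the threshold, so proteins from groups
  outside the model are left `unassigned` rather than mislabeled.

A fixed-length ReLU/batch-norm baseline with a hidden layer (`deepfam`
variant) is included for comparison, and a synthetic family generator
(implanted motifs, power-law group populations) makes the whole pipeline
testable without downloading any orthology database. Everything — forward
pass, backpropagation, Adam — is implemented in numpy; see
[docs/methods.md](docs/methods.md) for the full model description.

## Worked example

Simulate a small database of 5 synthetic families (60 members each), train,
assign, and score — all from the shell:

```bash
ognet simulate --groups 5 --base-population 60 --length-min 60 --length-max 150 \
      --seed 7 --out-fasta db.fa --out-labels db.tsv
# wrote 300 sequences / 5 groups

ognet train --fasta db.fa --labels db.tsv --filters-per-size 16 --epochs 6 \
      --seed 7 --out-model model.ognet --out-history history.tsv
# trained deepnog on 245 sequences / 5 groups; best epoch 3 (val acc 1.0000)

ognet infer --model model.ognet --fasta db.fa --confidence-threshold 0.5 --out pred.tsv
# assigned 300/300 sequences

ognet evaluate --predictions pred.tsv --labels db.tsv --out metrics.tsv
# accuracy 1.0000, macro precision 1.0000, macro recall 1.0000
```

The prediction table carries one row per input sequence — id, assigned group
(or `unassigned`), rank-1 confidence, model name:

```
id            group   confidence  model
OG0001_00000  OG0001  0.946711    model
OG0001_00001  OG0001  0.940090    model
OG0001_00002  OG0001  0.981288    model
```

Accuracy is the fraction of correct assignments; macro precision/recall
average the per-group values unweighted, so rare groups count as much as
large ones. At the strict default threshold of 0.99 this deliberately tiny
model assigns only its most confident queries (59/300) — the threshold
exists to reject sequences from groups the model does not know, and small
toy models rarely reach 99% confidence. Unassigned rows keep their rank-1
probability, so you can re-threshold without re-running inference.

The same pipeline is available as a library (`ognet.synthetic_data`,
`ognet.training`, `ognet.inference`, `ognet.evaluation`), including the
learned-embedding export (`evaluation.export_embeddings`) and the
in-model/out-model confidence analysis (`evaluation.in_out_model_analysis`).

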
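# splicevar

Convolutional splice-site classification and log-ratio scoring of
splice-region variants.

## The problem

RNA splicing removes introns at donor (exon|GT…intron) and acceptor
(intron…AG|exon) junctions. The GT/AG core dinucleotide is nearly
invariant but hopelessly non-specific: bulk genomic sequence is full of
GT/AG decoys that are never spliced. Recognising true splice sites from
their local sequence context is therefore a classification problem, and
single-nucleotide variants that weaken that context can cause
mis-splicing and disease.

`splicevar` is for computational genetics researchers who want to

1. train convolutional classifiers that distinguish true splice-site
   windows from decoy windows carrying the same core dinucleotide, and
2. score single-nucleotide variants near the junction by how much the
   alternative allele reduces the predicted splice probability.

## The model and the score

Windows are fixed-length nucleotide strings with the dimer pinned at a
convention position (40 nt: GT at 20–21 / AG at 19–20; 398 nt: GT at
201–202 / AG at 198–199), one-hot encoded as N × 4 binary matrices with
column order (A, C, G, T). Three architectures are provided — `CNN_3`
and `CNN_4` (three and four convolution layers) and `CNN_LSTM` (one
convolution plus a bidirectional LSTM) — each ending in a 2-way softmax,
trained with SGD (Nesterov momentum 0.9), categorical cross-entropy,
30 epochs, batch size 64, initial learning rate 0.05 decayed every
5 epochs. The networks are implemented in NumPy with explicit
forward/backward passes (gradients are verified against finite
differences in the test suite).

A variant *m* with reference allele `ref` and alternative allele `alt`
inside a window is scored with the fitted model *M*:

```
Score(m) = log10( PM(ref) / PM(alt) )
```

where `PM(·)` is the model's probability that the window is a true
splice site. `Score > 0` means the alternative allele lowers the
predicted splice probability; motif-disrupting (pathogenic-like)
variants score high, neutral (benign-like) ones score near zero.
Probabilities are clamped to `[1e-6, 1 - 1e-6]` so the score is finite
and antisymmetric under a ref/alt swap.

Because the original training corpora are not redistributable, the
package ships a position-weight-matrix simulator
(`splicevar.simulate`) that generates splice-site-like windows with a
controllable motif `strength` (0 = pure background, 1 = full canonical
consensus plus exon/intron flank composition) and variant sets split
into motif-disrupting and neutral classes.

## Worked example

```python
import splicevar as sv

# full-strength synthetic donor data, 40 nt windows
motif = sv.default_motif("donor", "DLAI40", strength=1.0)
pos = sv.sample_positive(motif, 2500, seed=11)
neg = sv.sample_negative(sv.GeneratorConfig("donor", "DLAI40", 0, 2500, seed=12))
train, hold = pos[:2000] + neg[:2000], pos[2000:] + neg[2000:]

clf = sv.SpliceSiteClassifier("CNN_4", epochs=5, random_state=0)
clf.fit(train, [r.label for r in train])
probs = clf.predict_proba_splice(hold)
print(round(sv.auprc(probs, [1] * 500 + [0] * 500), 3))
# 0.976

# score variants: disruptive (motif-hitting) vs neutral
vset = sv.generate_variants(pos[:2000], 200, 200, seed=13, motif=motif)
scores = sv.score_variants(clf, vset.records)
path = [s for s in scores if s.record.clinical_class.value == "pathogenic"]
ben = [s for s in scores if s.record.clinical_class.value == "benign"]
t, p, summaries = sv.compare_groups(path, ben)
print(f"{p:.2e}", round(summaries["pathogenic"]["mean"], 3),
      round(summaries["benign"]["mean"], 4))
# 1.75e-10 0.083 0.0008
```

The held-out area under the precision–recall curve (0.976) shows the
network recovers the planted motif; the one-sided Welch's t-test p-value
(≈ 2e-10) shows disruptive variants score significantly above neutral
ones, with group means ≈ 0.08 versus ≈ 0.001.

The same workflow is available from the shell:

```
splicevar pipeline --seed 3 --out-dir run/
splicevar simulate --site donor --n-positive 1000 --n-negative 7000 --out-dir sim/
splicevar train --input sim/dataset.tsv --model cnn4 --out-dir model/
splicevar score-variants --model-file model/model.npz --variants sim/variants.tsv --out-dir scored/
```

Every run writes a `manifest.json` (resolved configuration, seeds,
output digests) so artifacts can be reproduced exactly.

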
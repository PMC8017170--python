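"""Binary relevance, 2:1 under-sampling and the 64/16/20 split.

Builds a small imbalanced synthetic corpus, converts it into the AF binary
task, balances it and partitions it.
"""

from ecgfb import (SplitSpec, SyntheticConfig, binarize, generate_corpus,
                   kfold, split, undersample)

config = SyntheticConfig(class_mix={"AF": 0.15}, multilabel_rate=0.0,
                         duration_range=(6.0, 12.0), seed=4)
records = generate_corpus(200, config)

task = binarize(records, "AF")
print(f"raw task: {task.n_positive} positive / {task.n_negative} negative "
      f"(ratio {task.ratio:.1f}:1)")

balanced = undersample(task, ratio=2.0, seed=0)
print(f"balanced: {balanced.n_positive} positive / {balanced.n_negative} negative "
      f"(ratio {balanced.ratio:.1f}:1)")

tr, va, te = split(balanced, SplitSpec(seed=0))
print(f"split sizes: train {len(tr)}, validation {len(va)}, test {len(te)}")
folds = kfold(balanced, SplitSpec(k=5, seed=0))
print(f"5-fold validation sizes: {[len(v) for _, v in folds]}")
# Every minority record survives balancing; the split is stratified so the
# 2:1 ratio carries into each partition within one record per class.
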
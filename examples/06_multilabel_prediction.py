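"""Binary relevance in action: per-class models vote independently.

Trains tiny AF and RBBB classifiers on a toy corpus and predicts label
sets for a few held-out records, including a multi-label one.
"""

import numpy as np

from ecgfb import (ModelConfig, SyntheticConfig, binarize, build_model,
                   frame_block, generate_corpus, generate_record,
                   multilabel_predict, train, undersample)

config = SyntheticConfig(class_mix={"AF": 0.35, "RBBB": 0.35},
                         multilabel_rate=0.2, duration_range=(6.0, 10.0), seed=2)
records = generate_corpus(90, config)
blocks = {r.record_id: frame_block(r).data for r in records}

mcfg = ModelConfig(epochs=12, batch_size=8, seed=0).small()
models = {}
for cls in ("AF", "RBBB"):
    task = undersample(binarize(records, cls), 2.0, seed=0)
    x = np.stack([blocks[rid] for rid in task.record_ids])
    models[cls] = train(build_model(mcfg), x, task.labels, config=mcfg)

probes = [
    generate_record({"AF"}, 8.0, seed=100),
    generate_record({"RBBB"}, 8.0, seed=101),
    generate_record({"AF", "RBBB"}, 8.0, seed=102),
    generate_record({"Normal"}, 8.0, seed=103),
]
x_probe = np.stack([frame_block(r).data for r in probes])
for rec, predicted in zip(probes, multilabel_predict(models, x_probe)):
    print(f"true {sorted(rec.labels)!s:20s} predicted {sorted(predicted)}")
# A record's predicted set is the union of positive binary calls; the
# multi-label record should trigger both models, the normal one neither.
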
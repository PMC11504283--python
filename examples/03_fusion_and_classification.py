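"""Stage 2: cross-modal attention fusion and classification.

Fine-tunes the six directed attention blocks and the MLP head on top of a
frozen pre-trained encoder, then inspects the fusion output and metrics.
"""

from mercl import pipeline, synth, train

data = synth.generate(synth.SynthSpec(n_trials_per_class=5, trial_len_s=4.0,
                                      seed=0))
feats = pipeline.build_features(data.trials)
model = pipeline.MerclModel(feats.video.shape[-1],
                            pipeline.ModelConfig(width=32, proj_width=16,
                                                 hidden=32, seed=0))
cfg = train.TrainConfig(pretrain_epochs=10, finetune_epochs=60,
                        lr_finetune=1e-3, seed=0)
train.pretrain(feats, model, cfg)
before = model.encoder_checksum()
log = train.finetune(feats, model, cfg)
assert model.encoder_checksum() == before      # encoder frozen in stage 2
print(f"cross-entropy: {log[0]['cross_entropy']:.3f} -> "
      f"{log[-1]['cross_entropy']:.3f}")

model.eval()
h = model.encode(feats.as_dict())
fused = model.cma(h)
print("directed attention results:", ", ".join(fused.direction_labels))
print(f"fusion vector width: {fused.width} (6 directions x D={model.cfg.width})")

pred = train.predict(feats, model)
rep = train.compute_metrics(pred.labels, feats.labels, 4)
print(f"training-set accuracy {rep.accuracy:.3f}, macro F1 {rep.macro_f1:.3f}")
# accuracy is the fraction of blocks classified into the correct emotion
# quadrant; macro F1 averages per-class F1 over the four classes
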
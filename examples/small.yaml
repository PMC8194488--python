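# Scaled-down configuration for quick desk runs.
# Paper-scale defaults (128 kernels, 3 blocks, 128 LSTM units, 64 Mel
# bands) live in the library; this file shrinks the network so a full
# speaker-independent cross-validation finishes in well under a minute.
features:
  n_mels: 16
model:
  n_blocks: 2
  conv_channels: 12
  lstm_hidden: 24
  fc_hidden: 32
train:
  epochs: 8
  batch_size: 8
  lr: 0.001
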
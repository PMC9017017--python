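# Calibrated architecture manifests for the four shipped networks.
#
# The published totals (in millions: densenet 1.228, dcrn 1.228, r2unet 0.983,
# udnet 1.038) leave several structural details unstated — stem width,
# transition widths, the form of the recurrent kernel, the upsampling operator
# and the residual-projection policy.  The values below were calibrated once
# against those totals and are frozen; `nucleikit build --count-params`
# reports the resulting counts.
#
# weight_mode:  shared   = one recurrent kernel reused at every unrolled step
#               distinct = a separate recurrent kernel per unrolled step
# recurrent_kernel: full = dense 3x3 (out_channels -> out_channels)
#                   depthwise = per-channel 3x3

densenet:
  variant: densenet
  task: classification
  input_shape: [32, 32, 3]
  num_outputs: 4
  blocks: 4
  layers_per_block: 7
  growth_rate: 12
  time_steps: 0
  weight_mode: shared
  recurrent_kernel: full
  stem_channels: 160
  transition_channels: [256, 332, 300]
  head: softmax
  # trainable parameters: 1227996 (1.228 M)

dcrn:
  variant: dcrn
  task: classification
  input_shape: [32, 32, 3]
  num_outputs: 4
  blocks: 4
  layers_per_block: 7
  growth_rate: 12
  time_steps: 2
  weight_mode: shared
  recurrent_kernel: full
  stem_channels: 132
  transition_channels: [304, 284, 300]
  head: softmax
  # trainable parameters: 1227996 (1.228 M)

r2unet:
  variant: r2unet
  task: segmentation
  input_shape: [96, 96, 1]
  num_outputs: 1
  channel_schedule: [1, 32, 64, 128, 256, 128, 64, 32, 1]
  time_steps: 2
  weight_mode: distinct
  recurrent_kernel: depthwise
  upsample: nearest
  residual_projection: none
  head: softmax
  head_channels: 2
  # trainable parameters: 983268 (0.983 M)

udnet:
  variant: udnet
  task: detection
  input_shape: [96, 96, 1]
  num_outputs: 1
  channel_schedule: [1, 32, 64, 128, 256, 128, 64, 32, 1]
  time_steps: 3
  weight_mode: shared
  recurrent_kernel: depthwise
  upsample: tconv
  residual_projection: needed
  head: sigmoid-regression
  head_channels: 1
  # trainable parameters: 1041923 (1.042 M; published 1.038 M, +0.4%)
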
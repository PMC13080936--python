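# Full benchmark analysis: simulate the two-channel translation movie,
# correct photobleaching, detect/track both channels, extract traces,
# colocalize, and run the autocorrelation analysis on the nascent channel.
seed: 1
simulate:
  enabled: true        # defaults: 360 frames, 5 s, 512x512, 80 spots,
                       # ki 0.04 1/s, ke 5 codons/s, kb 0.001 1/s
bleach:
  enabled: true      # fits and corrects every channel
detect:
  enabled: true
  sigma_px: 1.3
  threshold: null      # automatic (elbow/plateau hybrid)
track:
  enabled: true
  max_disp_px: 5.0
  memory: 1
  min_track_len: 20
intensity:
  enabled: true
  method: bg_sub
colocalize:
  enabled: true
  d_max_px: 2.0
  min_fraction: 0.5
correlate:
  enabled: true
  channel: 1
  l_eff_codons: 1900
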
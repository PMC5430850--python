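# hairpinforge G-quadruplex (QGRS-style) scoring coefficients, version 1
# score(arrangement) = tetrad_weight * (t - 2)
#                      + max(0, loop_base - total_loop_length)
#                      - uneven_weight * (longest loop - shortest loop)
# clamped below at min_score whenever any legal arrangement exists.
# Calibrated so the thrombin-binding aptamer GGTTGGTGTGGTTGG scores 20.
tetrad_weight 10
loop_base 28
uneven_weight 1
min_score 1
max_span 30
min_run 2
max_zero_loops 1
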
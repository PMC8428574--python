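"""Package-wide numerical constants."""

# Clamp for log-domain operations on probabilities: S is clipped to [EPS, 1]
# before -log so cumulative hazards and log-losses stay finite.
EPS = 1e-15

# Floor for IPCW denominators G(t): weights are bounded above by 1/G_FLOOR.
G_FLOOR = 1e-3
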
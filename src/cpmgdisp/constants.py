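"""Physical constants shared across the package.

All unit conversions between ppm and angular frequency go through the
single gyromagnetic frequency-ratio constant defined here, so that the
forward models, sign determination and synthetic-data generator can never
disagree about what a ppm is worth at a given field.
"""

#: 13C/1H gyromagnetic (Larmor frequency) ratio.  A spectrometer whose 1H
#: frequency is ``B0`` MHz observes 13C at ``B0 * GAMMA_RATIO_C_H`` MHz.
GAMMA_RATIO_C_H = 0.251450

#: Default pseudo-random seed used wherever a routine draws random numbers
#: and the caller does not supply a seed of its own.
DEFAULT_SEED = 20220324
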
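"""Physical constants and shared defaults."""

#: Boltzmann constant in kJ mol^-1 K^-1 (Gromacs convention).
KB = 0.0083144621

#: Replica-ladder used in the original parallel-tempering study (K).
DEFAULT_LADDER = (
    278.0, 287.0, 295.0, 303.0, 312.0, 321.0, 329.0, 338.0,
    346.0, 355.0, 365.0, 375.0, 385.0, 396.0, 406.0, 416.0,
    427.0, 437.0, 448.0, 459.0, 470.0, 482.0, 493.0, 505.0,
    517.0, 528.0, 539.0, 551.0, 562.0, 573.0, 584.0, 595.0,
)
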
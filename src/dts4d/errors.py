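"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid user input: malformed trace files, bad parameters, short waveforms."""


class InfeasibleTechniqueError(RuntimeError):
    """The derived frame rate exceeds the hardware limit implied by the frame gap.

    A frame rate at or above 1/frame_gap leaves no time for the x-ray pulse
    (pulse duration = frame period - frame gap would be <= 0).
    """
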
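"""Exception hierarchy shared by the analysis modules."""


class VoxPhenoError(Exception):
    """Base class for all voxpheno-specific failures."""


class TooShortSegmentError(VoxPhenoError):
    """Central segment would be shorter than the minimum analyzable length."""


class InsufficientVoicingError(VoxPhenoError):
    """Too few voiced frames to estimate pitch or perturbation measures."""


class IncompleteSessionError(VoxPhenoError):
    """A subject-session lacks one of the three cardinal vowels."""
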
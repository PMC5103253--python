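"""Exception types shared across voxgraph modules."""


class VoxgraphError(Exception):
    """Base class for all voxgraph errors."""


class DimensionError(VoxgraphError):
    """Array shapes or lengths are inconsistent."""


class EmptyMaskError(VoxgraphError):
    """The brain mask selects no voxels."""


class DegenerateInputError(VoxgraphError):
    """Input is too small or too flat for the requested computation."""


class ConfigError(VoxgraphError):
    """A configuration value is outside its admissible range."""
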
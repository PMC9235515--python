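"""Exception hierarchy for alnzone."""


class AlnzoneError(Exception):
    """Base class for all alnzone errors."""


class AlphabetError(AlnzoneError):
    """A residue symbol could not be resolved under the active policy."""


class ModelError(AlnzoneError):
    """A substitution model or alignment machine failed validation."""


class FormatError(AlnzoneError):
    """Malformed input file or alignment string."""


class ConsistencyError(AlnzoneError):
    """Inputs that are individually valid but mutually inconsistent."""


class InferenceError(AlnzoneError):
    """Numerical inference (time estimation, sampling) could not proceed."""
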
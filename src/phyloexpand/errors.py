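"""Exception hierarchy shared by all modules."""


class PhyloExpandError(Exception):
    """Base class for all package errors."""


class TreeFormatError(PhyloExpandError):
    """Malformed tree input: bad Newick, duplicate leaf labels, ..."""


class TreeValidationError(PhyloExpandError):
    """Structurally valid input that violates a constraint (e.g. negative branch length)."""


class PutFileError(PhyloExpandError):
    """Malformed PUT list file."""


class MdccResolutionError(PhyloExpandError):
    """A PUT names an MDCC label that does not match any node of the tree."""


class SelectionError(PhyloExpandError):
    """An insertion-point selection that cannot be carried out (e.g. branch-based on a leaf MDCC)."""
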
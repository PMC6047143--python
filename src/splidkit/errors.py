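"""Exception types shared across the package."""


class SplidkitError(Exception):
    """Base class for all package errors."""


class FormatError(SplidkitError):
    """Malformed input file (FASTA/MAF/PHYLIP/NEXUS/Newick)."""


class TaxonMismatchError(SplidkitError):
    """Taxon sets of two objects are incompatible for the requested operation."""
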
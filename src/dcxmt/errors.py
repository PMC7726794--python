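"""Exception hierarchy shared across the package.

All errors derive from :class:`DcxmtError` so callers can catch the package's
failures with one clause; each subclass names the pipeline stage or contract
that was violated.
"""


class DcxmtError(Exception):
    """Base class for all dcxmt errors."""


class ParameterError(DcxmtError, ValueError):
    """An input parameter is out of its documented range.

    The message always names the offending field.
    """


class GeometryError(DcxmtError, ValueError):
    """Image/box geometry mismatch (shapes, pixel sizes, lattice vs box)."""


class FrequencyError(DcxmtError, ValueError):
    """A requested spatial frequency lies outside the sampled spectrum."""


class DegenerateSignalError(DcxmtError, ValueError):
    """No tubulin lattice signal detected (4 nm layer line empty)."""


class SubsetError(DcxmtError, ValueError):
    """Not enough segments to form the requested number of subsets."""


class SelectionError(DcxmtError, ValueError):
    """An atom/residue selection is empty or cannot be paired."""


class FormatError(DcxmtError, ValueError):
    """Unrecognised or inconsistent file content."""
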
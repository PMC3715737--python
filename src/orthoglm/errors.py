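"""Exception hierarchy.

All package errors derive from :class:`OrthoGLMError` so callers can catch
one base class; the concrete subclasses also derive from ``ValueError`` to
stay friendly to generic error handling.
"""


class OrthoGLMError(Exception):
    """Base class for all orthoglm errors."""


class DegenerateInputError(OrthoGLMError, ValueError):
    """An input is degenerate for the requested operation.

    Examples: z-scoring a constant series, orthogonalizing a regressor that
    lies in the span of its bases, information criteria on a zero-residual
    fit.
    """


class CollinearityError(OrthoGLMError, ValueError):
    """A design matrix is rank deficient; the message names the columns."""


class SchemaError(OrthoGLMError, ValueError):
    """A tabular input file does not match the expected schema."""
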
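"""Exception hierarchy for synroutes.

Every error raised by the toolkit derives from :class:`SynRoutesError` so
callers can catch the whole family with one clause; the facade relies on this
to isolate per-file failures in batch processing.
"""


class SynRoutesError(Exception):
    """Base class for all toolkit errors."""


# -- chemistry layer ---------------------------------------------------------

class InvalidStructureError(SynRoutesError):
    """A molecular input string could not be parsed."""


class MalformedReactionError(SynRoutesError):
    """A reaction string lacks reactants or products after role attribution."""


class TypeMismatchError(SynRoutesError):
    """Two chemical objects of different kinds were compared."""


# -- graph layer -------------------------------------------------------------

class EmptyGraphError(SynRoutesError):
    """Operation requires a non-empty graph."""


class ModelMismatchError(SynRoutesError):
    """Graphs with different data models cannot be combined or compared."""


class LossyConversionError(SynRoutesError):
    """Requested data-model conversion would have to invent information."""


class AmbiguousTargetError(SynRoutesError):
    """Route extraction needs a single target (root) molecule."""


class CyclicInputError(SynRoutesError):
    """Route extraction is defined on acyclic graphs only."""


class NotARouteError(SynRoutesError):
    """A SynRoute (single-root graph) was expected."""


# -- translation layer -------------------------------------------------------

class DialectError(SynRoutesError):
    """Document does not follow the declared dialect."""


class DanglingEdgeError(SynRoutesError):
    """A node/edge document references an unknown node uid."""


class UnknownFormatError(SynRoutesError):
    """Requested data format is not registered."""


# -- descriptors -------------------------------------------------------------

class UnknownDescriptorError(SynRoutesError):
    """Requested descriptor name is not registered."""


class UndefinedDescriptorError(SynRoutesError):
    """Descriptor is mathematically undefined for this route."""


# -- similarity / clustering -------------------------------------------------

class InsufficientInputError(SynRoutesError):
    """Too few routes for the requested operation."""


class InvalidMatrixError(SynRoutesError):
    """Distance matrix is not symmetric/non-negative/zero-diagonal."""


class AlignmentError(SynRoutesError):
    """Cluster labels and route list have mismatched lengths."""


# -- facade ------------------------------------------------------------------

class UnknownFunctionalityError(SynRoutesError):
    """Requested facade functionality is not registered."""


class EmptyBatchError(SynRoutesError):
    """All input files of a batch failed to load."""


# -- fixtures ----------------------------------------------------------------

class SpecError(SynRoutesError):
    """Invalid synthetic-route generation spec."""
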
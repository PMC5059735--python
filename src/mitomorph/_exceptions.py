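"""Exception taxonomy.

Every user-facing failure mode raises a distinct, named error so that batch
drivers can report precisely which precondition was violated.
"""


class MitomorphError(Exception):
    """Base class for all package-specific errors."""


class MissingFileError(MitomorphError, FileNotFoundError):
    """An input path does not exist or is not readable."""


class PlaneIndexError(MitomorphError, IndexError):
    """A channel map requests a plane index outside the TIFF's plane count."""


class DuplicateRoleError(MitomorphError, ValueError):
    """A channel map assigns the same plane to more than one role, or lists a role twice."""


class MissingChannelError(MitomorphError, KeyError):
    """An operation needs a channel role that the image does not carry."""


class NonIntegerMaskError(MitomorphError, ValueError):
    """A label-mask TIFF contains non-integer pixel values."""


class ConsistencyError(MitomorphError, ValueError):
    """Cross-table referential integrity violated (e.g. a particle's cell id is unknown)."""


class SchemaError(MitomorphError, ValueError):
    """A tabular input does not follow the documented column schema."""


class GroupTooSmallError(MitomorphError, ValueError):
    """A statistical comparison group has fewer observations than required."""


class EmptyInputError(MitomorphError, ValueError):
    """An operation received an empty collection where at least one element is required."""


class PlacementError(MitomorphError, RuntimeError):
    """The synthetic generator could not place the requested geometry without overlap."""
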
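"""Exception hierarchy.

Input problems (bad files, too few points, empty selections) and numerical
problems (ill-posed linear systems, infeasible transport) are kept distinct so
the command-line layer can map them to different exit codes.
"""


class TopopackError(Exception):
    """Base class for all package errors."""


class InputError(TopopackError):
    """Invalid or insufficient input data (CLI exit code 2)."""


class InsufficientPointsError(InputError):
    """Fewer points than a 3D tessellation requires."""


class DegenerateCloudError(InputError):
    """All points coplanar (or otherwise untessellatable) after jitter."""


class NoBulkPointsError(InputError):
    """Boundary exclusion removed every candidate motif center."""


class SaturatedPackingError(InputError):
    """Random sequential addition could not place the requested points."""


class NumericalError(TopopackError):
    """Ill-posed or infeasible numerical problem (CLI exit code 3)."""


class IllPosedError(NumericalError):
    """Transport between distributions with unbalanced mass across
    disconnected flip-graph components."""


class NonMetricTripleError(NumericalError):
    """Three distances violating the triangle inequality beyond tolerance."""
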
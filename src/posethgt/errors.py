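"""Exception hierarchy shared across the package.

Domain errors (inconsistent poset families, contradictory trees, malformed
input files) all derive from :class:`PosetHGTError` so that callers — the CLI
in particular — can distinguish them from programming errors.
"""

from __future__ import annotations


class PosetHGTError(Exception):
    """Base class for all domain errors raised by posethgt."""


class ParseError(PosetHGTError):
    """Malformed input file (poset TSV or Newick).

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AntisymmetryError(PosetHGTError):
    """A relation and its reverse are both asserted (directly or by closure)."""


class IncompleteFamilyError(PosetHGTError):
    """A poset family lacks a poset for some species in the species set."""


class InconsistentFamilyError(PosetHGTError):
    """The poset family carries conflicting closeness information.

    Raised when the sibling matrix is asymmetric or when a sibling merge
    finds disagreeing values; no compatible tree exists for such a family.
    """


class InvalidRefinementError(PosetHGTError):
    """A refinement step that would violate the outdegree-two requirement."""


class ContradictionError(PosetHGTError):
    """Two trees (or 2-partition sets) carry contradicting bipartitions."""

    def __init__(self, message: str, witness=None):
        self.witness = witness
        super().__init__(message)


class LabelCollisionError(PosetHGTError):
    """The reserved augmentation label collides with a real species label."""


class DegenerateMatrixError(PosetHGTError):
    """A sibling-matrix query that needs at least two labels got fewer."""
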
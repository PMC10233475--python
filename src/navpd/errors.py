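"""Exception hierarchy shared across the package."""


class NavpdError(Exception):
    """Base class for package errors."""


class PDBFormatError(NavpdError, ValueError):
    """Raised for unparseable or empty PDB content."""


class ECTableFormatError(NavpdError, ValueError):
    """Raised for malformed EC-score tables; message carries the row number."""


class DegenerateGeometryError(NavpdError, ValueError):
    """Raised when a geometric operation is underdetermined (too few or collinear points)."""


class MissingResidueError(NavpdError, KeyError):
    """Raised when a (domain_id, seq_index) lookup fails."""


class SelectionError(NavpdError, ValueError):
    """Raised when an atom selection resolves to nothing."""


class ConfigurationError(NavpdError, ValueError):
    """Raised on mismatched scopes, missing energies and similar wiring mistakes."""


class SyntheticSpecError(NavpdError, ValueError):
    """Raised when synthetic-data generation targets are infeasible or invalid."""
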
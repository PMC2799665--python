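"""Exception hierarchy shared across the package.

Every error raised on a documented contract violation derives from
:class:`LooplabError`, so callers can catch the package's own failures
without masking programming errors.
"""


class LooplabError(Exception):
    """Base class for all looplab errors."""


class ParameterError(LooplabError, ValueError):
    """A generator or analysis parameter violates its invariant."""


class ParseError(LooplabError, ValueError):
    """A file could not be parsed in its declared dialect."""


class TopologyError(LooplabError, ValueError):
    """Atom/residue bookkeeping is inconsistent (missing atoms, frame mismatch)."""


class GridError(LooplabError, ValueError):
    """A time series is not uniformly sampled."""


class SelectionError(LooplabError, ValueError):
    """An atom-group selection is empty or refers to missing atoms."""


class DegenerateSignalError(LooplabError, ValueError):
    """A signal has no usable fluctuation (e.g. zero mean for G(tau))."""


class LagError(LooplabError, ValueError):
    """A requested correlation lag falls outside the series."""


class NoRelaxationError(LooplabError, RuntimeError):
    """No statistically resolvable relaxation in the fit window.

    Signals the 'no detectable process' case: short chains may show no
    decay on the experimentally accessible (>= 6 ns) timescale.
    """


class FitError(LooplabError, RuntimeError):
    """A model fit failed to converge after multistart."""


class IntegrationError(LooplabError, RuntimeError):
    """Langevin integration produced non-finite coordinates."""


class GeometryError(LooplabError, ValueError):
    """A requested ideal geometry is unbuildable (e.g. self-intersecting)."""


class DegenerateProfileError(LooplabError, ValueError):
    """All samples identical: no free-energy profile can be built."""


class NoBarrierError(LooplabError, RuntimeError):
    """Free-energy profile has no interior barrier (single well / monotone)."""


class EmptyStateError(LooplabError, ValueError):
    """A state-conditioned statistic was requested but no frames qualify."""


class InputError(LooplabError, ValueError):
    """Generic invalid analysis input (too few points, empty matrix, ...)."""


class ConfigError(LooplabError, ValueError):
    """A pipeline run configuration failed validation."""
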
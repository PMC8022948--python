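"""Exception and warning types shared across the package."""


class NeiQTLError(Exception):
    """Base class for errors raised by neiqtl."""


class ParameterError(NeiQTLError, ValueError):
    """An argument is outside its documented domain."""


class CrossTypeError(NeiQTLError, ValueError):
    """Unknown or unsupported cross type."""


class SchemaError(NeiQTLError, ValueError):
    """An input file violates the declared dialect."""


class DegenerateGeometryError(NeiQTLError, ValueError):
    """Spatial configuration carries no usable distance information."""


class IsolatedIndividualsError(NeiQTLError, ValueError):
    """A spatial scale leaves at least one individual without neighbors."""

    def __init__(self, scale, isolated_ids):
        self.scale = scale
        self.isolated_ids = list(isolated_ids)
        super().__init__(
            f"scale s={scale:g} leaves {len(self.isolated_ids)} individual(s) "
            f"without neighbors: {', '.join(map(str, self.isolated_ids[:10]))}"
            + ("..." if len(self.isolated_ids) > 10 else "")
        )


class DegenerateTraitError(NeiQTLError, ValueError):
    """Trait vector is constant or otherwise unusable."""


class SimulationError(NeiQTLError, RuntimeError):
    """A simulation request cannot be satisfied (e.g. unattainable share)."""


class ProfileError(NeiQTLError, RuntimeError):
    """All variance-component fits across spatial scales failed."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped before reaching its tolerance."""


class RankWarning(UserWarning):
    """A scan position had a rank-deficient design matrix."""
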
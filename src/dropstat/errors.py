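"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument lies outside the domain an operation is defined on."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


class DropletTableError(ValueError):
    """A droplet count table violates the CSV schema or its row invariants."""
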
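"""Exception hierarchy shared across the pipeline."""


class ErvscanError(Exception):
    """Base class for all pipeline errors."""


class InputError(ErvscanError):
    """Malformed user input (sequences, alignments, tables)."""


class ConfigurationError(ErvscanError):
    """Inconsistent configuration (profiles, rule sets, tree labels)."""


class SimulationError(ErvscanError):
    """Synthetic-data generation could not satisfy its constraints."""
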
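"""Exception and warning types shared across the package."""


class InputError(ValueError):
    """A malformed or inconsistent input file or table.

    Raised by every reader on parse failures; the CLI maps it to exit code 2.
    """


class DegenerateStatisticsWarning(UserWarning):
    """A statistic was computed on degenerate data (zero variance, empty risk set...)."""


class MissingDataWarning(UserWarning):
    """Subjects or pairs were dropped because of missing genotypes/expression."""
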
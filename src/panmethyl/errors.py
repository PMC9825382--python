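"""Exception hierarchy shared across the pipeline."""


class PanmethylError(Exception):
    """Base class for all pipeline errors."""


class InvalidPeptideError(PanmethylError, ValueError):
    """A peptide violates the library geometry (length, central residue)."""


class InvalidWindowError(PanmethylError, ValueError):
    """A scoring window violates the 7-mer / central-K contract."""


class MissingDataError(PanmethylError, ValueError):
    """A feature has no replicate measurements."""


class DegenerateArrayError(PanmethylError, ValueError):
    """Normalization is undefined (all-zero array or zero column)."""


class IncompleteScanError(PanmethylError, ValueError):
    """An array scan lacks features required by the library manifest."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(
            f"scan is missing {len(self.missing)} library feature(s): "
            + ", ".join(self.missing[:10])
            + ("..." if len(self.missing) > 10 else "")
        )


class IncompleteProfileError(PanmethylError, ValueError):
    """A selectivity profile has unmeasured on-target cells."""


class InsufficientDataError(PanmethylError, ValueError):
    """Too few observations for the requested statistic."""
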
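"""Exception hierarchy shared across the package."""


class HerblikeError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(HerblikeError):
    """A SMILES or SDF structure could not be parsed.

    Carries the offending string so batch callers can report it.
    """

    def __init__(self, structure: str, detail: str = "") -> None:
        self.structure = structure
        msg = f"could not parse structure: {structure!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class DescriptorUnavailableError(HerblikeError):
    """The configured backend cannot compute a requested descriptor.

    Raised instead of silently substituting a default, e.g. when the
    ionisation model is disabled but the molecule carries an ionisable
    group, so the pH 7.4 fields would be wrong.
    """


class IncompleteDescriptorsError(HerblikeError):
    """A compound is missing one or more of the ten required descriptors."""

    def __init__(self, compound_id: str, missing) -> None:
        self.compound_id = compound_id
        self.missing = tuple(missing)
        super().__init__(
            f"compound {compound_id!r} is missing descriptors: {', '.join(self.missing)}"
        )


class TableFormatError(HerblikeError):
    """A descriptor table violates the format contract (bad cell, bad header)."""


class DuplicateIdError(TableFormatError):
    """Duplicate compound identifiers within one library."""

    def __init__(self, duplicates) -> None:
        self.duplicates = sorted(duplicates)
        super().__init__(f"duplicate compound_id values: {', '.join(self.duplicates)}")
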
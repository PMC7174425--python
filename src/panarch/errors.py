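"""Exception hierarchy shared across the package."""


class PanarchError(Exception):
    """Base class for all panarch errors."""


class FormatError(PanarchError):
    """A file does not follow the declared dialect."""


class DuplicateIdError(FormatError):
    """A genome or cluster identifier occurs more than once."""


class SpeciesExcludedError(PanarchError):
    """A species fails the minimum-genome floor.

    Carries the observed genome count so callers can report it.
    """

    def __init__(self, species_id: str, n_genomes: int, n_min: int):
        self.species_id = species_id
        self.n_genomes = n_genomes
        self.n_min = n_min
        super().__init__(
            f"species {species_id!r} has {n_genomes} genomes after filtering; "
            f"at least {n_min} required"
        )


class AlignmentError(PanarchError):
    """Sequences in a core alignment are inconsistent."""


class TreeError(PanarchError):
    """A phylogeny is missing information (e.g. branch lengths)."""
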
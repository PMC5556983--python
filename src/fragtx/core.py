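"""Shared vocabulary of the time-course experiment.

The experiment samples twelve transcriptomes across three stages of
nitrogen availability: a pre-starvation reference (N_0), an early
starvation stage (e-N: starch accumulation), a late starvation stage
(l-N: TAG/lipid hyperaccumulation), and a nitrogen-resupply stage
(r+N: storage-compound degradation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical sample (column) order of the expression matrix.
TIME_POINTS: tuple[str, ...] = (
    "N_0",
    "N_2",
    "N_4",
    "N_8",
    "N_24",
    "N_48",
    "N_56",
    "N_96",
    "R_2",
    "R_4",
    "R_8",
    "R_14",
)

#: Pre-starvation reference time point.
REFERENCE: str = "N_0"

#: Stage membership of the eleven non-reference time points.
STAGES: dict[str, tuple[str, ...]] = {
    "e-N": ("N_2", "N_4", "N_8"),
    "l-N": ("N_24", "N_48", "N_56", "N_96"),
    "r+N": ("R_2", "R_4", "R_8", "R_14"),
}

#: The seven nitrogen-starvation time points (housekeeping stability window).
MINUS_N_POINTS: tuple[str, ...] = STAGES["e-N"] + STAGES["l-N"]

#: Non-reference time points in canonical order.
NON_REFERENCE_POINTS: tuple[str, ...] = TIME_POINTS[1:]

#: Minimum FPKM regarded as a reliable abundance estimate.
FPKM_FLOOR: float = 1.0

#: |log2 fold change| above which a gene is called responsive.
FC_THRESHOLD: float = 1.0

#: Display cap for |log2 fold change| ("highly regulated" beyond this).
FC_CAP: float = 4.0

#: Scaffold-margin distance (nt) below which a gene model counts as fragmented.
MARGIN_NT: int = 500

#: Pearson correlation threshold for fragment-pair detection.
PEARSON_THRESHOLD: float = 0.9

#: Significance threshold of the GO over-representation test.
ENRICHMENT_ALPHA: float = 1e-4

VALID_TRUNCATIONS = ("none", "N", "C")
VALID_LOCALIZATIONS = ("C", "M", "S", "O", "NA")


class FragtxError(Exception):
    """Base class for all package errors."""


class FormatError(FragtxError):
    """A file violated its format contract."""


class ConfigError(FragtxError):
    """An infeasible or inconsistent configuration."""


@dataclass(frozen=True)
class DomainHit:
    """A conserved-domain hit on a gene model.

    ``truncation`` records which terminus of the domain is missing:
    ``"N"`` (N-terminally truncated), ``"C"`` (C-terminally truncated)
    or ``"none"`` (full-length hit).
    """

    domain_id: str
    truncation: str = "none"

    def __post_init__(self) -> None:
        if self.truncation not in VALID_TRUNCATIONS:
            raise FormatError(
                f"invalid truncation {self.truncation!r} for domain {self.domain_id!r}"
            )


@dataclass
class LocusRecord:
    """A gene model with its coordinates and functional annotation.

    Coordinates are 1-based inclusive (GFF3 convention).
    """

    locus_id: str
    scaffold_id: str = ""
    start: int = 1
    end: int = 1
    scaffold_length: int = 1
    strand: str = "+"
    has_start_codon: bool = True
    defline: str = ""
    go_ids: frozenset[str] = field(default_factory=frozenset)
    domain_hits: tuple[DomainHit, ...] = ()
    localization: str = "NA"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= self.scaffold_length):
            raise FormatError(
                f"{self.locus_id}: coordinates {self.start}..{self.end} violate "
                f"1 <= start <= end <= scaffold_length ({self.scaffold_length})"
            )
        if self.localization not in VALID_LOCALIZATIONS:
            raise FormatError(
                f"{self.locus_id}: invalid localization {self.localization!r}"
            )

    @property
    def margin_distance(self) -> int:
        """Distance (nt) to the nearest scaffold margin."""
        return min(self.start - 1, self.scaffold_length - self.end)

    @property
    def domain_ids(self) -> frozenset[str]:
        return frozenset(h.domain_id for h in self.domain_hits)
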
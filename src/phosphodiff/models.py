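"""Domain types and coordinate conventions.

Protein coordinates are 1-based throughout.  Result tables from gel-based
phosphoproteomics workflows record, for each peptide, the position of the
residue *immediately before* the peptide in the parent protein
(``preceding_position``), so the peptide occupies protein positions
``preceding_position + 1 .. preceding_position + len(peptide)``.
Phospho-site offsets are 1-based positions *within* the peptide; the global
protein position of a site is therefore ``preceding_position + offset``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHO_RESIDUES = frozenset("STY")

GENOTYPES = ("WT", "KO")
SEXES = ("F", "M")


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


@dataclass(frozen=True)
class SampleDescriptor:
    """One biological sample in the 2x2 factorial design.

    ``lysate_protein_concentration`` is the per-sample lysate protein
    concentration (mass/volume) used as the normalization denominator for
    MS1 peak areas.  ``pair_id`` links a KO sample with its matched WT
    sample of the same sex for paired comparisons.
    """

    sample_id: str
    genotype: str
    sex: str
    lysate_protein_concentration: float
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: genotype must be one of {GENOTYPES}, "
                f"got {self.genotype!r}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"sample {self.sample_id!r}: sex must be one of {SEXES}, "
                f"got {self.sex!r}"
            )
        if not self.lysate_protein_concentration > 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: lysate protein concentration must "
                f"be strictly positive, got {self.lysate_protein_concentration}"
            )


def check_design(design: list[SampleDescriptor]) -> None:
    """Validate a study design: unique sample ids."""
    seen: set[str] = set()
    for s in design:
        if s.sample_id in seen:
            raise ValidationError(f"duplicate sample id {s.sample_id!r} in design")
        seen.add(s.sample_id)


@dataclass(frozen=True, order=True)
class PeptideKey:
    """Identity of a quantified phosphopeptide analyte.

    Two observations belong to the same analyte iff sequence, number of
    phosphates, and the set of confidently localized site offsets all agree;
    mono- and di-phosphorylated forms of one sequence are distinct analytes.
    ``localized_offsets`` is empty when site localization fell below the
    confidence threshold (the analyte is still counted and quantified, but
    contributes no motif windows).
    """

    peptide_sequence: str
    phospho_count: int
    localized_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.phospho_count < 1:
            raise ValidationError("phospho_count must be >= 1")
        if tuple(sorted(self.localized_offsets)) != self.localized_offsets:
            raise ValidationError("localized_offsets must be sorted")
        if self.localized_offsets and len(self.localized_offsets) != self.phospho_count:
            raise ValidationError(
                "localized_offsets, when present, must have phospho_count entries"
            )

    def __str__(self) -> str:
        offs = ".".join(str(o) for o in self.localized_offsets) or "-"
        return f"{self.peptide_sequence}|{self.phospho_count}|{offs}"

    @classmethod
    def from_string(cls, text: str) -> "PeptideKey":
        seq, count, offs = text.rsplit("|", 2)
        offsets = () if offs == "-" else tuple(int(o) for o in offs.split("."))
        return cls(seq, int(count), offsets)


@dataclass(frozen=True)
class PhosphopeptideObservation:
    """One phosphopeptide identification in one sample / gel fraction."""

    sample_id: str
    protein_accession: str
    gene_symbol: str
    peptide_sequence: str
    preceding_position: int
    phospho_offsets: tuple[int, ...]
    phospho_count: int
    met_ox_count: int
    gel_fraction: int
    ms1_peak_area: float
    site_confidence: float

    def __post_init__(self) -> None:
        seq = self.peptide_sequence
        if not seq or not seq.isalpha() or not seq.isupper():
            raise ValidationError(f"peptide sequence {seq!r} must be uppercase letters")
        if self.preceding_position < 0:
            raise ValidationError("preceding_position must be >= 0")
        if self.phospho_count < 1:
            raise ValidationError("phospho_count must be >= 1")
        if self.met_ox_count < 0:
            raise ValidationError("met_ox_count must be >= 0")
        if self.ms1_peak_area < 0:
            raise ValidationError("ms1_peak_area must be >= 0")
        if not 0.0 <= self.site_confidence <= 1.0:
            raise ValidationError("site_confidence must be in [0, 1]")
        if self.phospho_offsets:
            if len(self.phospho_offsets) != self.phospho_count:
                raise ValidationError(
                    f"{seq}: {len(self.phospho_offsets)} offsets given for "
                    f"phospho_count={self.phospho_count}"
                )
            for off in self.phospho_offsets:
                if not 1 <= off <= len(seq):
                    raise ValidationError(
                        f"{seq}: phospho offset {off} outside [1, {len(seq)}]"
                    )
                if seq[off - 1] not in PHOSPHO_RESIDUES:
                    raise ValidationError(
                        f"{seq}: residue {seq[off - 1]!r} at offset {off} is not S/T/Y"
                    )

    def key(self, confidence_min: float = 0.95) -> PeptideKey:
        """Analyte key; offsets are kept only when localization is confident."""
        offsets = (
            tuple(sorted(self.phospho_offsets))
            if self.site_confidence >= confidence_min and self.phospho_offsets
            else ()
        )
        return PeptideKey(self.peptide_sequence, self.phospho_count, offsets)


class ProteinDatabase:
    """Accession -> amino-acid sequence mapping (uppercase, non-empty)."""

    def __init__(self, records: dict[str, str] | None = None):
        self._records: dict[str, str] = {}
        for acc, seq in (records or {}).items():
            self.add(acc, seq)

    def add(self, accession: str, sequence: str) -> None:
        if accession in self._records:
            raise ValidationError(f"duplicate accession {accession!r}")
        if not sequence or not sequence.isalpha():
            raise ValidationError(f"{accession}: empty or non-alphabetic sequence")
        self._records[accession] = sequence.upper()

    def __getitem__(self, accession: str) -> str:
        return self._records[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def items(self):
        return self._records.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, ProteinDatabase) and self._records == other._records


@dataclass(frozen=True)
class Contrast:
    """A two-group split of the design along one factor (e.g. KO vs WT).

    ``level_a`` is the first-named group: detection/quant directions and
    signed statistics are reported as A relative to B.
    """

    name: str
    factor: str  # "genotype" or "sex"
    level_a: str
    level_b: str

    def split(self, design: list[SampleDescriptor]) -> tuple[list[str], list[str]]:
        a = [s.sample_id for s in design if getattr(s, self.factor) == self.level_a]
        b = [s.sample_id for s in design if getattr(s, self.factor) == self.level_b]
        if not a or not b:
            raise ValidationError(
                f"contrast {self.name!r}: empty group ({self.level_a}: {len(a)}, "
                f"{self.level_b}: {len(b)})"
            )
        return a, b


GENOTYPE_CONTRAST = Contrast("genotype", "genotype", "KO", "WT")
SEX_CONTRAST = Contrast("sex", "sex", "F", "M")
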
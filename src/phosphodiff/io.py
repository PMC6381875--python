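"""Readers and writers for the package's external formats.

FASTA for protein sequences (via Biopython), tab-separated tables for the
study design, per-sample observations and all result tables, plain text for
gene lists, and JSON for summary reports.  TSV dialect: UTF-8, tab
separator, '.' decimal separator, mandatory header.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .models import (
    PhosphopeptideObservation,
    ProteinDatabase,
    SampleDescriptor,
    ValidationError,
    check_design,
)

OBSERVATION_COLUMNS = [
    "sample_id",
    "protein_accession",
    "gene_symbol",
    "peptide_sequence",
    "preceding_position",
    "phospho_offsets",
    "phospho_count",
    "met_ox_count",
    "gel_fraction",
    "ms1_peak_area",
    "site_confidence",
]

DESIGN_COLUMNS = [
    "sample_id",
    "genotype",
    "sex",
    "lysate_protein_concentration",
    "pair_id",
]


def read_fasta(path: str | Path) -> ProteinDatabase:
    """Read a protein FASTA file; the accession is the first header token."""
    path = Path(path)
    # Cheap structural pre-check so malformed files fail with a line number
    # (Bio.SeqIO silently skips leading junk).
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValidationError(
                        f"{path}:{lineno}: expected FASTA header line starting "
                        f"with '>', got {line.strip()[:30]!r}"
                    )
                break
    db = ProteinDatabase()
    for record in SeqIO.parse(str(path), "fasta"):
        db.add(record.id, str(record.seq))
    return db


def write_fasta(db: ProteinDatabase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc, seq in db.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_design(path: str | Path) -> list[SampleDescriptor]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"design table missing columns: {sorted(missing)}")
    design = []
    for _, row in df.iterrows():
        pair = row["pair_id"]
        design.append(
            SampleDescriptor(
                sample_id=row["sample_id"],
                genotype=row["genotype"],
                sex=row["sex"],
                lysate_protein_concentration=float(row["lysate_protein_concentration"]),
                pair_id=None if pd.isna(pair) or pair == "" else pair,
            )
        )
    check_design(design)
    return design


def write_design(design: list[SampleDescriptor], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "genotype": s.genotype,
            "sex": s.sex,
            "lysate_protein_concentration": s.lysate_protein_concentration,
            "pair_id": s.pair_id or "",
        }
        for s in design
    ]
    pd.DataFrame(rows, columns=DESIGN_COLUMNS).to_csv(path, sep="\t", index=False)


def _offsets_to_str(offsets: tuple[int, ...]) -> str:
    return ";".join(str(o) for o in offsets)


def _offsets_from_str(text) -> tuple[int, ...]:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return ()
    return tuple(int(tok) for tok in str(text).split(";"))


def read_observations(
    path: str | Path, design: list[SampleDescriptor]
) -> list[PhosphopeptideObservation]:
    """Read a per-sample observation table, validating every row.

    Rows referencing sample ids absent from ``design`` are rejected; all
    validation failures are reported together with their row numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"phospho_offsets": str})
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"observation table missing columns: {sorted(missing)}")
    legal_ids = {s.sample_id for s in design}
    observations: list[PhosphopeptideObservation] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            if row.sample_id not in legal_ids:
                raise ValidationError(f"unknown sample id {row.sample_id!r}")
            observations.append(
                PhosphopeptideObservation(
                    sample_id=row.sample_id,
                    protein_accession=str(row.protein_accession),
                    gene_symbol=str(row.gene_symbol),
                    peptide_sequence=str(row.peptide_sequence),
                    preceding_position=int(row.preceding_position),
                    phospho_offsets=_offsets_from_str(row.phospho_offsets),
                    phospho_count=int(row.phospho_count),
                    met_ox_count=int(row.met_ox_count),
                    gel_fraction=int(row.gel_fraction),
                    ms1_peak_area=float(row.ms1_peak_area),
                    site_confidence=float(row.site_confidence),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(
            f"{len(errors)} invalid observation rows:\n" + "\n".join(errors[:50])
        )
    return observations


def write_observations(
    observations: list[PhosphopeptideObservation], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": o.sample_id,
            "protein_accession": o.protein_accession,
            "gene_symbol": o.gene_symbol,
            "peptide_sequence": o.peptide_sequence,
            "preceding_position": o.preceding_position,
            "phospho_offsets": _offsets_to_str(o.phospho_offsets),
            "phospho_count": o.phospho_count,
            "met_ox_count": o.met_ox_count,
            "gel_fraction": o.gel_fraction,
            "ms1_peak_area": repr(o.ms1_peak_area),
            "site_confidence": o.site_confidence,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | Path) -> list[str]:
    """Read a candidate-gene list, one symbol per line; blanks skipped."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_set(genes, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(g + "\n")


def validate_against_database(
    observations: list[PhosphopeptideObservation], db: ProteinDatabase
) -> list[str]:
    """Check every observation's coordinates against the protein database.

    Reports a violation when the peptide does not occur in its protein at
    positions ``preceding_position + 1 .. preceding_position + len`` (1-based)
    or when a phospho-site's global residue is not S/T/Y.
    """
    violations: list[str] = []
    for o in observations:
        if o.protein_accession not in db:
            violations.append(f"{o.peptide_sequence}: unknown accession {o.protein_accession}")
            continue
        protein = db[o.protein_accession]
        start = o.preceding_position  # 0-based start of peptide in protein
        if protein[start : start + len(o.peptide_sequence)] != o.peptide_sequence:
            violations.append(
                f"{o.protein_accession}: peptide {o.peptide_sequence} not found at "
                f"preceding position {o.preceding_position}"
            )
            continue
        for off in o.phospho_offsets:
            residue = protein[o.preceding_position + off - 1]
            if residue not in "STY":
                violations.append(
                    f"{o.protein_accession}: global site "
                    f"{o.preceding_position + off} is {residue!r}, not S/T/Y"
                )
    return violations


def write_report(results, path: str | Path, format: str = "tsv") -> None:
    """Write a result table (DataFrame or list of records) as TSV or JSON.

    Round-trip guarantee: ``read_report`` on the written file reproduces the
    table field-for-field.
    """
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown report format {format!r}")
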
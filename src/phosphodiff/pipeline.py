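"""End-to-end orchestration: QC, both contrasts, motifs, enrichment.

``run_all`` reads the four inputs (observations TSV, protein FASTA, design
TSV, candidate-gene list), validates coordinates, and writes the full
report bundle to the output directory.  Every applied threshold is echoed
in the run manifest, and all outputs are deterministic functions of the
inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from . import io as pio
from .detection import (
    DetectionMatrix,
    build_detection_matrix,
    detection_contrast_table,
    detection_frequency_summary,
    exclusive_peptides,
    pairwise_repeatability,
)
from .enrichment import GeneSet, annotate_hits, bias_direction_counts, proportion_enrichment
from .models import (
    GENOTYPE_CONTRAST,
    SEX_CONTRAST,
    Contrast,
    ProteinDatabase,
    ValidationError,
)
from .motifs import (
    extract_windows,
    motif_class_abundance,
    motifx_extract,
    proteome_windows,
    window_at,
    write_windows,
)
from .quant import (
    aggregate_observations,
    fold_change_scatter,
    group_sum_comparison,
    quant_contrast,
    quant_contrast_table,
)


@dataclass
class RunConfig:
    observations: str = ""
    fasta: str = ""
    design: str = ""
    gene_set: str = ""
    outdir: str = "results"
    min_detect: int = 3
    alpha: float = 0.05
    confidence_min: float = 0.95
    min_per_group: int = 3
    motif_width: int = 6
    min_occurrences: int = 5
    motif_significance: float = 4e-6
    scatter_cutoff: float = 1.0
    universe: int = 0  # 0 = use the number of proteins in the FASTA
    welch: bool = False
    bh_correction: bool = False
    two_sided_proportion: bool = False
    repeatability_denominator: str = "min"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 <= self.confidence_min <= 1:
            raise ValidationError("confidence_min must be in [0, 1]")
        if self.min_detect < 1 or self.min_per_group < 1:
            raise ValidationError("min_detect and min_per_group must be >= 1")
        if not 0 < self.motif_significance < 1:
            raise ValidationError("motif_significance must be in (0, 1)")
        if self.repeatability_denominator not in ("min", "union"):
            raise ValidationError("repeatability_denominator must be 'min' or 'union'")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        legal = set(cls.__dataclass_fields__)
        unknown = set(data) - legal
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def qc_summary(observations, matrix: DetectionMatrix, config: RunConfig) -> dict:
    """Residue composition, per-group detection frequencies, repeatability."""
    # Composition over localized sites of unique analytes.
    counts = {"S": 0, "T": 0, "Y": 0}
    for ks, key in matrix.keys.items():
        for off in key.localized_offsets:
            counts[key.peptide_sequence[off - 1]] += 1
    total_sites = sum(counts.values())
    composition = (
        {r: 100.0 * c / total_sites for r, c in counts.items()} if total_sites else {}
    )

    cells: dict[str, list[str]] = {}
    for s in matrix.design:
        cells.setdefault(f"{s.genotype}_{s.sex}", []).append(s.sample_id)
    frequency = {
        cell: detection_frequency_summary(matrix, samples)
        for cell, samples in sorted(cells.items())
    }

    groups = {
        "WT": [s.sample_id for s in matrix.design if s.genotype == "WT"],
        "KO": [s.sample_id for s in matrix.design if s.genotype == "KO"],
    }
    repeatability = {}
    for name, samples in groups.items():
        for level in ("peptide", "protein"):
            vals = pairwise_repeatability(
                matrix, samples, level=level, denominator=config.repeatability_denominator
            )
            repeatability[f"{name}_{level}"] = {
                "n_pairs": len(vals),
                "min": min(vals) if vals else None,
                "max": max(vals) if vals else None,
                "mean": float(np.mean(vals)) if vals else None,
            }
    return {
        "n_observations": len(observations),
        "n_peptide_keys": int(matrix.detected.shape[0]),
        "site_composition_percent": composition,
        "detection_frequency": {
            cell: {str(k): v for k, v in freq.items()} for cell, freq in frequency.items()
        },
        "repeatability_percent": repeatability,
    }


def _apply_bh(results, alpha: float) -> None:
    """Benjamini-Hochberg adjustment in place on quant contrast results."""
    if not results:
        return
    adjusted = _scipy_stats.false_discovery_control(
        [r.p_two_sided for r in results], method="bh"
    )
    for r, q in zip(results, adjusted):
        r.p_two_sided = float(q)
        r.significant = bool(q < alpha)


def _key_windows(keys, key_info, db: ProteinDatabase, width: int) -> list[str]:
    """One window per localized site of each key (unique-analyte foreground)."""
    windows = []
    for ks in keys:
        info = key_info.get(ks)
        if info is None:
            continue
        accession, preceding = info
        key = None
        # key string encodes sequence and localized offsets
        from .models import PeptideKey

        key = PeptideKey.from_string(ks)
        if not key.localized_offsets or accession not in db:
            continue
        protein = db[accession]
        for off in key.localized_offsets:
            pos = preceding + off
            if pos <= len(protein) and protein[pos - 1] in "STY":
                windows.append(window_at(protein, pos, width))
    return windows


def run_all(config: RunConfig) -> dict:
    """Run the complete analysis and write the report bundle.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    outdir = Path(config.outdir)
    for path_field in ("observations", "fasta", "design", "gene_set"):
        p = getattr(config, path_field)
        if not p or not Path(p).exists():
            raise ValidationError(f"input path for {path_field!r} missing: {p!r}")
    outdir.mkdir(parents=True, exist_ok=True)

    design = pio.read_design(config.design)
    db = pio.read_fasta(config.fasta)
    observations = pio.read_observations(config.observations, design)
    gene_symbols = pio.read_gene_set(config.gene_set)

    violations = pio.validate_against_database(observations, db)
    if violations:
        raise ValidationError(
            f"{len(violations)} coordinate violations; first: {violations[0]}"
        )

    matrix = build_detection_matrix(observations, design, config.confidence_min)
    qc = qc_summary(observations, matrix, config)

    contrasts = {"genotype": GENOTYPE_CONTRAST, "sex": SEX_CONTRAST}
    detection_results = {}
    for name, contrast in contrasts.items():
        res = exclusive_peptides(
            matrix,
            contrast,
            min_detect=config.min_detect,
            alpha=config.alpha,
            two_sided=config.two_sided_proportion,
        )
        detection_results[name] = res
        detection_contrast_table(res).to_csv(
            outdir / f"detection_{name}.tsv", sep="\t", index=False
        )

    qmatrix = aggregate_observations(observations, design, config.confidence_min)
    quant_results = {}
    for name, contrast in contrasts.items():
        res = quant_contrast(
            qmatrix,
            contrast,
            min_per_group=config.min_per_group,
            alpha=config.alpha,
            welch=config.welch,
        )
        if config.bh_correction:
            _apply_bh(res, config.alpha)
        quant_results[name] = res
        table = quant_contrast_table(res)
        table.to_csv(outdir / f"quant_{name}.tsv", sep="\t", index=False)
        heat = table[table["significant"]][["key", "bias_score_a", "neg_bias_score_b"]]
        heat.to_csv(outdir / f"bias_heatmap_{name}.tsv", sep="\t", index=False)

    scatter = fold_change_scatter(
        qmatrix, GENOTYPE_CONTRAST, SEX_CONTRAST, cutoff=config.scatter_cutoff
    )
    scatter.to_csv(outdir / "scatter.tsv", sep="\t", index=False)

    group_sums = {
        name: group_sum_comparison(
            qmatrix, contrast, list(qmatrix.areas.index)
        )
        for name, contrast in contrasts.items()
    }

    # Motif extraction on the differential key sets, per contrast direction,
    # against the whole-proteome background of the same central residue.
    key_info = {}
    for o in observations:
        ks = str(o.key(config.confidence_min))
        key_info.setdefault(ks, (o.protein_accession, o.preceding_position))
    backgrounds = {r: proteome_windows(db, r, config.motif_width) for r in "STY"}
    motif_rows = []
    for name, contrast in contrasts.items():
        for direction in (contrast.level_a, contrast.level_b):
            keys = {str(r.key) for r in detection_results[name] if r.direction == direction}
            keys |= {
                str(r.key)
                for r in quant_results[name]
                if r.significant and r.direction == direction
            }
            fg_all = _key_windows(sorted(keys), key_info, db, config.motif_width)
            if fg_all:
                write_windows(fg_all, outdir / f"windows_{name}_{direction}.txt")
            for residue in "STY":
                fg = [w for w in fg_all if w[config.motif_width] == residue]
                bg = backgrounds[residue]
                if not fg or not bg:
                    continue
                for m in motifx_extract(
                    fg,
                    bg,
                    width=config.motif_width,
                    min_occurrences=config.min_occurrences,
                    significance=config.motif_significance,
                ):
                    motif_rows.append(
                        {
                            "contrast": name,
                            "direction": direction,
                            "motif": str(m.pattern),
                            "center": m.pattern.center,
                            "constraints": ";".join(
                                f"{off:+d}{res}"
                                for off, res in sorted(m.pattern.constraints)
                            ),
                            "fg_matches": m.foreground_matches,
                            "fg_size": m.foreground_size,
                            "bg_matches": m.background_matches,
                            "bg_size": m.background_size,
                            "p_final": m.p_final,
                            "fold_enrichment": m.fold_enrichment,
                            "order": m.order,
                        }
                    )
    motif_table = pd.DataFrame(
        motif_rows,
        columns=[
            "contrast",
            "direction",
            "motif",
            "center",
            "constraints",
            "fg_matches",
            "fg_size",
            "bg_matches",
            "bg_size",
            "p_final",
            "fold_enrichment",
            "order",
        ],
    )
    motif_table.to_csv(outdir / "motifs.tsv", sep="\t", index=False)

    # Proline-directed class abundance, paired across matched KO/WT pairs.
    sample_windows = {s.sample_id: [] for s in design}
    for w in extract_windows(observations, db, config.confidence_min, config.motif_width):
        sample_windows[w.sample_id].append(w.sequence)
    # Detection-level windows: one per detected analyte site per sample.
    dedup = {sid: sorted(set(ws)) for sid, ws in sample_windows.items()}
    motif_class = motif_class_abundance(dedup, design)

    # Candidate-gene enrichment over proteins with sex-exclusive peptides.
    gene_map = {
        ks: sorted(qmatrix.genes.get(ks, frozenset())) for ks in qmatrix.genes
    }
    sex_keys = [str(r.key) for r in detection_results["sex"]]
    universe = config.universe if config.universe > 0 else len(db)
    gene_set = GeneSet.from_symbols("candidate", gene_symbols, universe=universe)
    tested_genes = set()
    for ks in sex_keys:
        tested_genes.update(gene_map.get(ks, []))
    k, hits = annotate_hits(sex_keys, gene_map, gene_set)
    n_tested = len(tested_genes)
    enrichment = {
        "k": k,
        "n": n_tested,
        "K": len(gene_set.genes),
        "N": universe,
        "hits": hits,
    }
    if 0 < k and n_tested > 0:
        res = proportion_enrichment(k, n_tested, len(gene_set.genes), universe)
        enrichment["z"] = res.z
        enrichment["p_one_sided"] = res.p_one_sided
        enrichment["proportion_tested"] = res.proportion_tested
        enrichment["proportion_universe"] = res.proportion_universe

    sex_bias = bias_direction_counts(
        detection_results["sex"], quant_results["sex"], SEX_CONTRAST
    )

    summary = {
        "qc": qc,
        "n_detection_calls": {k: len(v) for k, v in detection_results.items()},
        "n_quant_significant": {
            k: sum(r.significant for r in v) for k, v in quant_results.items()
        },
        "n_quant_tested": {k: len(v) for k, v in quant_results.items()},
        "group_sums": group_sums,
        "n_motifs": len(motif_rows),
        "motif_class": motif_class,
        "enrichment": enrichment,
        "sex_bias_direction": sex_bias,
        "n_scatter_keys": int(len(scatter)),
    }
    with open(outdir / "qc_summary.json", "w", encoding="utf-8") as fh:
        json.dump(qc, fh, indent=1, sort_keys=True)
    with open(outdir / "motif_class_comparison.json", "w", encoding="utf-8") as fh:
        json.dump(motif_class, fh, indent=1, sort_keys=True)
    with open(outdir / "enrichment.json", "w", encoding="utf-8") as fh:
        json.dump(enrichment, fh, indent=1, sort_keys=True)
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    manifest = {
        "config": asdict(config),
        "inputs": {
            name: hashlib.sha256(Path(getattr(config, name)).read_bytes()).hexdigest()
            for name in ("observations", "fasta", "design", "gene_set")
        },
        "outputs": sorted(
            p.name for p in outdir.iterdir() if p.name != "manifest.json"
        ),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return summary
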
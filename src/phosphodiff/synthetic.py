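"""Synthetic 2x2 factorial phosphoproteomics study generator.

Emulates a 16-sample (4 per genotype x sex cell) TiO2-enrichment-style
phosphoproteomics experiment: per-peptide Bernoulli detection across
replicates, log-normal MS1 peak areas with multiplicative measurement
noise, gel-fraction splitting, Met-oxidation variant rows, and planted
ground truth — group-exclusive peptides, multiplicative fold changes,
a +1-proline motif bias on WT-favored peptides, and a candidate-gene
annotation overlap — so that every downstream analysis stage can be tested
for recovery without any external data.

Determinism: one integer-seeded RNG stream per sample, derived from
(seed, sample_id), so adding samples never perturbs existing ones; all
study-level structure comes from a master stream seeded by ``seed`` alone.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np

from .models import (
    AMINO_ACIDS,
    PhosphopeptideObservation,
    ProteinDatabase,
    SampleDescriptor,
)
from . import io as pio

# Relative frequencies of S/T/Y among phosphosites: pSer dominates brain
# phosphoproteomes (~73/19/2 of phosphopeptides, renormalized here).
SITE_RESIDUE_PROBS = {"S": 0.777, "T": 0.202, "Y": 0.021}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_proteins: int = 215
    peptides_per_protein: int = 10
    replicates_per_cell: int = 4
    baseline_detection_prob: float = 0.7
    lognormal_mu: float = 13.0  # ln-scale mean of base MS1 areas (~4.4e5)
    lognormal_sigma: float = 1.5  # ln-scale spread between peptides
    n_exclusive_per_contrast: int = 50
    exclusive_on_prob: float = 0.9
    n_foldchange_peptides: int = 50
    fold_change: float = 4.0
    motif_bias_fraction: float = 1.0
    disease_gene_fraction: float = 0.05
    disease_overlap_boost: float = 0.3
    n_fractions: int = 3
    measurement_cv: float = 0.1  # sd of multiplicative ln-scale noise
    met_ox_fraction: float = 0.1
    diphospho_fraction: float = 0.1
    low_confidence_fraction: float = 0.05
    mean_concentration: float = 3.0
    concentration_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "baseline_detection_prob",
            "exclusive_on_prob",
            "motif_bias_fraction",
            "disease_gene_fraction",
            "disease_overlap_boost",
            "met_ox_fraction",
            "diphospho_fraction",
            "low_confidence_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        for name in ("n_proteins", "peptides_per_protein", "replicates_per_cell",
                     "n_exclusive_per_contrast", "n_foldchange_peptides", "n_fractions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_peptides(self) -> int:
        return self.n_proteins * self.peptides_per_protein


@dataclass
class GroundTruth:
    """Planted effects, for recovery testing against pipeline output."""

    exclusives: dict[str, list[dict]] = field(default_factory=dict)
    fold_changes: list[dict] = field(default_factory=list)
    motif_biased_keys: list[str] = field(default_factory=list)
    disease_genes: list[str] = field(default_factory=list)
    disease_overlap_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


@dataclass(frozen=True)
class _Peptide:
    index: int
    sequence: str
    offsets: tuple[int, ...]  # 1-based phosphosite offsets in the peptide
    role: str  # null | genotype_exclusive | sex_exclusive | foldchange
    favored: str | None  # WT/KO for genotype roles, F/M for sex exclusives
    motif_biased: bool
    confidence: float
    protein_index: int
    preceding_position: int
    base_area: float

    @property
    def accession(self) -> str:
        return f"PROT{self.protein_index:04d}"

    @property
    def gene(self) -> str:
        return f"GENE{self.protein_index:04d}"

    @property
    def key_string(self) -> str:
        offs = (
            ".".join(str(o) for o in self.offsets)
            if self.confidence >= 0.95
            else "-"
        )
        return f"{self.sequence}|{len(self.offsets)}|{offs}"


def _random_peptide(rng: np.random.Generator, diphospho: bool) -> tuple[str, tuple[int, ...]]:
    length = int(rng.integers(10, 18))
    residues = list(rng.choice(list(AMINO_ACIDS), size=length))
    residues[-1] = "K" if rng.random() < 0.5 else "R"
    site = int(rng.integers(3, length - 1))  # 1-based, keeps a +1 neighbor inside
    residue = rng.choice(list(SITE_RESIDUE_PROBS), p=list(SITE_RESIDUE_PROBS.values()))
    residues[site - 1] = str(residue)
    offsets = [site]
    if diphospho:
        choices = [p for p in range(2, length) if p not in (site, site + 1)]
        site2 = int(rng.choice(choices))
        residue2 = rng.choice(list(SITE_RESIDUE_PROBS), p=list(SITE_RESIDUE_PROBS.values()))
        residues[site2 - 1] = str(residue2)
        offsets.append(site2)
    return "".join(residues), tuple(sorted(offsets))


@lru_cache(maxsize=8)
def _blueprint(config: SimulationConfig) -> tuple[tuple[_Peptide, ...], ProteinDatabase]:
    """Deterministic study-level structure: peptides, roles, proteins."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed]))
    total = config.n_peptides
    n_excl = config.n_exclusive_per_contrast
    n_fc = config.n_foldchange_peptides
    if 2 * n_excl + n_fc > total:
        raise ValueError("more planted peptides than peptides in the study")

    # Assign roles to shuffled peptide indices.
    order = rng.permutation(total)
    roles: dict[int, tuple[str, str | None]] = {}
    cursor = 0
    for role, levels, count in (
        ("genotype_exclusive", ("WT", "KO"), n_excl),
        ("sex_exclusive", ("F", "M"), n_excl),
        ("foldchange", ("WT", "KO"), n_fc),
    ):
        for j in range(count):
            roles[int(order[cursor + j])] = (role, levels[j % 2])
        cursor += count

    peptides: list[_Peptide] = []
    seen: set[str] = set()
    for i in range(total):
        role, favored = roles.get(i, ("null", None))
        planted = role != "null"
        diphospho = (not planted) and rng.random() < config.diphospho_fraction
        motif_biased = (
            role in ("genotype_exclusive", "foldchange")
            and favored == "WT"
            and rng.random() < config.motif_bias_fraction
        )
        while True:
            seq, offsets = _random_peptide(rng, diphospho)
            if motif_biased:
                # Plant the proline-directed class: central residue S, +1 = P.
                site = offsets[0]
                chars = list(seq)
                chars[site - 1] = "S"
                chars[site] = "P"
                seq = "".join(chars)
            if seq not in seen:
                seen.add(seq)
                break
        if planted:
            confidence = 0.99
        else:
            confidence = 0.80 if rng.random() < config.low_confidence_fraction else 0.99
        base_area = float(np.exp(rng.normal(config.lognormal_mu, config.lognormal_sigma)))
        peptides.append(
            _Peptide(
                index=i,
                sequence=seq,
                offsets=offsets,
                role=role,
                favored=favored,
                motif_biased=motif_biased,
                confidence=confidence,
                protein_index=i // config.peptides_per_protein if config.peptides_per_protein else 0,
                preceding_position=0,  # filled below
                base_area=base_area,
            )
        )

    # Assemble proteins: short random N-flank, then the protein's peptides.
    db = ProteinDatabase()
    final: list[_Peptide] = []
    for p_idx in range(config.n_proteins):
        members = [
            pep
            for pep in peptides
            if pep.protein_index == p_idx
        ]
        flank = "M" + "".join(rng.choice(list(AMINO_ACIDS), size=2))
        seq_parts = [flank]
        pos = len(flank)
        for pep in members:
            final.append(
                _Peptide(
                    **{**pep.__dict__, "preceding_position": pos}
                )
            )
            seq_parts.append(pep.sequence)
            pos += len(pep.sequence)
        tail = "".join(rng.choice(list(AMINO_ACIDS), size=2))
        seq_parts.append(tail)
        if members:
            db.add(f"PROT{p_idx:04d}", "".join(seq_parts))
    final.sort(key=lambda p: p.index)
    return tuple(final), db


def generate_protein_database(config: SimulationConfig) -> ProteinDatabase:
    """The synthetic proteome; every emitted peptide occurs in its parent
    protein at the recorded preceding position."""
    return _blueprint(config)[1]


def generate_study(config: SimulationConfig) -> tuple[list[SampleDescriptor], GroundTruth]:
    """Study design (4 cells x replicates, matched KO/WT pairs within sex)
    plus the planted ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    design: list[SampleDescriptor] = []
    for sex in ("F", "M"):
        for genotype in ("WT", "KO"):
            for r in range(1, config.replicates_per_cell + 1):
                conc = float(
                    np.clip(
                        rng.normal(config.mean_concentration, config.concentration_sd),
                        0.5,
                        None,
                    )
                )
                design.append(
                    SampleDescriptor(
                        sample_id=f"{genotype}_{sex}{r}",
                        genotype=genotype,
                        sex=sex,
                        lysate_protein_concentration=conc,
                        pair_id=f"{sex}{r}",
                    )
                )
    peptides, _ = _blueprint(config)
    truth = GroundTruth(exclusives={"genotype": [], "sex": []})
    for pep in peptides:
        if pep.role == "genotype_exclusive":
            truth.exclusives["genotype"].append(
                {"key": pep.key_string, "favored": pep.favored, "gene": pep.gene}
            )
        elif pep.role == "sex_exclusive":
            truth.exclusives["sex"].append(
                {"key": pep.key_string, "favored": pep.favored, "gene": pep.gene}
            )
        elif pep.role == "foldchange":
            truth.fold_changes.append(
                {
                    "key": pep.key_string,
                    "fold": config.fold_change,
                    "favored": pep.favored,
                    "gene": pep.gene,
                }
            )
        if pep.motif_biased:
            truth.motif_biased_keys.append(pep.key_string)

    # Candidate-gene list: a boosted share of sex-biased genes plus a random
    # background fraction of the remaining genes.
    sex_genes = sorted({e["gene"] for e in truth.exclusives["sex"]})
    n_boost = int(round(config.disease_overlap_boost * len(sex_genes)))
    boosted = sorted(rng.choice(sex_genes, size=n_boost, replace=False)) if n_boost else []
    other = [
        f"GENE{i:04d}" for i in range(config.n_proteins) if f"GENE{i:04d}" not in set(sex_genes)
    ]
    background = [g for g in other if rng.random() < config.disease_gene_fraction]
    truth.disease_genes = sorted(set(boosted) | set(background))
    truth.disease_overlap_genes = list(boosted)
    return design, truth


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(sample_id.encode())])
    )


def simulate_observations(
    config: SimulationConfig,
    design: list[SampleDescriptor],
    truth: GroundTruth | None = None,
) -> list[PhosphopeptideObservation]:
    """Draw per-sample observation rows.

    Detection is Bernoulli per peptide per sample (probability 0 for
    exclusives in their off group); a detected peptide's total area is
    base_area x fold factor x exp(N(0, cv)), split across gel fractions,
    with Met-oxidation variant rows for a random subset of
    methionine-containing peptides.
    """
    peptides, _ = _blueprint(config)
    observations: list[PhosphopeptideObservation] = []
    for sample in design:
        rng = _sample_rng(config.seed, sample.sample_id)
        u = rng.random(len(peptides))
        for pep, draw in zip(peptides, u):
            if pep.role == "genotype_exclusive":
                p = config.exclusive_on_prob if sample.genotype == pep.favored else 0.0
            elif pep.role == "sex_exclusive":
                p = config.exclusive_on_prob if sample.sex == pep.favored else 0.0
            else:
                p = config.baseline_detection_prob
            if draw >= p:
                continue
            area = pep.base_area
            if pep.role == "foldchange" and sample.genotype == pep.favored:
                area *= config.fold_change
            if config.measurement_cv > 0:
                area *= float(np.exp(rng.normal(0.0, config.measurement_cv)))
            if config.n_fractions > 1:
                weights = rng.dirichlet([5.0] * config.n_fractions)
            else:
                weights = np.array([1.0])
            met_ox_split = "M" in pep.sequence and rng.random() < config.met_ox_fraction
            for frac_idx, w in enumerate(weights, start=1):
                frac_area = area * float(w)
                variants = [(0, frac_area)]
                if met_ox_split and frac_idx == 1:
                    variants = [(0, frac_area * 0.6), (1, frac_area * 0.4)]
                for ox, v_area in variants:
                    observations.append(
                        PhosphopeptideObservation(
                            sample_id=sample.sample_id,
                            protein_accession=pep.accession,
                            gene_symbol=pep.gene,
                            peptide_sequence=pep.sequence,
                            preceding_position=pep.preceding_position,
                            phospho_offsets=pep.offsets,
                            phospho_count=len(pep.offsets),
                            met_ox_count=ox,
                            gel_fraction=frac_idx,
                            ms1_peak_area=v_area,
                            site_confidence=pep.confidence,
                        )
                    )
    return observations


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        return GroundTruth.from_dict(json.load(fh))


def generate_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full study bundle (design, FASTA, observations,
    gene list, ground truth).  Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db = generate_protein_database(config)
    design, truth = generate_study(config)
    observations = simulate_observations(config, design, truth)
    paths = {
        "design": outdir / "design.tsv",
        "fasta": outdir / "proteins.fasta",
        "observations": outdir / "observations.tsv",
        "gene_set": outdir / "candidate_genes.txt",
        "ground_truth": outdir / "ground_truth.json",
    }
    pio.write_design(design, paths["design"])
    pio.write_fasta(db, paths["fasta"])
    pio.write_observations(observations, paths["observations"])
    pio.write_gene_set(truth.disease_genes, paths["gene_set"])
    write_ground_truth(truth, paths["ground_truth"])
    return paths
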
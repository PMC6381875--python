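import pytest

from phosphodiff.models import PhosphopeptideObservation, SampleDescriptor
from phosphodiff.pipeline import RunConfig, run_all
from phosphodiff.synthetic import SimulationConfig, generate_dataset, read_ground_truth


def make_obs(
    sample_id,
    seq="ASPK",
    area=1.0,
    fraction=1,
    ox=0,
    prec=0,
    offsets=(2,),
    conf=0.99,
    acc="P1",
    gene="G1",
    count=None,
):
    return PhosphopeptideObservation(
        sample_id=sample_id,
        protein_accession=acc,
        gene_symbol=gene,
        peptide_sequence=seq,
        preceding_position=prec,
        phospho_offsets=tuple(offsets),
        phospho_count=count if count is not None else max(1, len(offsets)),
        met_ox_count=ox,
        gel_fraction=fraction,
        ms1_peak_area=area,
        site_confidence=conf,
    )


def make_design(n_per_cell=2, conc=1.0):
    design = []
    for sex in ("F", "M"):
        for genotype in ("WT", "KO"):
            for r in range(1, n_per_cell + 1):
                design.append(
                    SampleDescriptor(
                        sample_id=f"{genotype}_{sex}{r}",
                        genotype=genotype,
                        sex=sex,
                        lysate_protein_concentration=conc,
                        pair_id=f"{sex}{r}",
                    )
                )
    return design


@pytest.fixture
def obs_factory():
    return make_obs


@pytest.fixture
def design8():
    """2 replicates per cell: 8 samples, 4 matched pairs."""
    return make_design(2)


@pytest.fixture
def design16():
    """The full factorial scale: 4 replicates per cell."""
    return make_design(4)


SMALL_CONFIG = SimulationConfig(
    seed=11,
    n_proteins=30,
    peptides_per_protein=5,
    n_exclusive_per_contrast=6,
    n_foldchange_peptides=6,
)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A reduced synthetic study for fast unit tests."""
    outdir = tmp_path_factory.mktemp("small_sim")
    paths = generate_dataset(SMALL_CONFIG, outdir)
    return {"config": SMALL_CONFIG, "paths": paths, "truth": read_ground_truth(paths["ground_truth"])}


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The full default study (16 samples, 50+50 exclusives, 50 fold-change
    peptides, 2000 null peptides) with the complete pipeline run once."""
    config = SimulationConfig(seed=42)
    datadir = tmp_path_factory.mktemp("default_sim")
    paths = generate_dataset(config, datadir)
    outdir = tmp_path_factory.mktemp("default_out")
    run_config = RunConfig(
        observations=str(paths["observations"]),
        fasta=str(paths["fasta"]),
        design=str(paths["design"]),
        gene_set=str(paths["gene_set"]),
        outdir=str(outdir),
    )
    summary = run_all(run_config)
    return {
        "config": config,
        "paths": paths,
        "truth": read_ground_truth(paths["ground_truth"]),
        "run_config": run_config,
        "outdir": outdir,
        "summary": summary,
    }
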
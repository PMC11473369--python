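import numpy as np
import pandas as pd
import pytest

from ribevol import normalization
from ribevol.io import CountMatrix, SampleTable
from ribevol.synthetic import (SimConfig, SorfSpec, ToyGenomeSpec,
                               simulate_counts, simulate_toy_genomes)
from ribevol.tevar import TEMatrix, compute_te


@pytest.fixture(scope="session")
def small_sim():
    """3 species x 4 replicates, 200 genes, moderate planted variance."""
    config = SimConfig(n_species=3, samples_per_species=[4, 4, 4],
                       n_genes=200, sigma_between=0.5, sigma_within=0.2,
                       seed=11)
    return simulate_counts(config)


@pytest.fixture(scope="session")
def small_te(small_sim):
    rna, ribo, samples, _ = small_sim
    return compute_te(normalization.normalize(rna),
                      normalization.normalize(ribo), samples)


@pytest.fixture(scope="session")
def toy_genomes():
    spec = ToyGenomeSpec(
        n_ortholog_genes=4,
        species_specific_genes={"human": 2, "chimp": 1},
        n_hominini_genes=2,
        sorfs=[SorfSpec("human", "preserved"),
               SorfSpec("human", "hominini"),
               SorfSpec("human", "intact"),
               SorfSpec("human", "de_novo", length_codons=100,
                        truncation_fraction=0.8),
               SorfSpec("human", "orphan"),
               SorfSpec("rhesus", "de_novo", length_codons=60,
                        truncation_fraction=0.7)])
    return simulate_toy_genomes(spec, seed=3)


def te_matrix_from_frame(frame: pd.DataFrame, species_of: dict[str, str],
                         scale: str = "log2") -> TEMatrix:
    return TEMatrix(frame, pd.Series(species_of), scale=scale)


def simple_counts(data: dict[str, list[float]], lengths=None) -> CountMatrix:
    df = pd.DataFrame(data, index=[f"g{i}" for i in
                                   range(len(next(iter(data.values()))))])
    ls = None
    if lengths is not None:
        ls = pd.Series(lengths, index=df.index)
    return CountMatrix(df, ls)


def paired_sample_table(species_reps: dict[str, int],
                        tissue: str = "LV") -> SampleTable:
    rows = []
    for sp, n in species_reps.items():
        for r in range(1, n + 1):
            key = f"{sp}_{tissue}_{r}"
            for assay in ("RNA", "RIBO"):
                rows.append({"sample_id": f"{key}_{assay}", "species": sp,
                             "tissue": tissue, "assay": assay,
                             "replicate": r, "pairing_key": key})
    return SampleTable(pd.DataFrame(rows))
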
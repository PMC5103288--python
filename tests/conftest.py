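import numpy as np
import pandas as pd
import pytest

from mycopop.core import GenotypeMatrix, GroupAssignment
from mycopop.simulate import SimulationConfig, simulate_genotypes


def make_matrix(dosages, positions=None, scaffold="sc1", strains=None):
    """Small handcrafted GenotypeMatrix helper."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_strains, n_loci = dosages.shape
    if positions is None:
        positions = list(range(1, n_loci + 1))
    if strains is None:
        strains = [f"S{i}" for i in range(n_strains)]
    if isinstance(scaffold, str):
        scaffold = [scaffold] * n_loci
    loci = pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": positions,
            "ref": ["A"] * n_loci,
            "alt": ["T"] * n_loci,
        }
    )
    return GenotypeMatrix(strains=strains, loci=loci, dosages=dosages)


def random_matrix(rng, n_strains=8, n_loci=40, scaffold="sc1"):
    dos = rng.integers(0, 3, size=(n_strains, n_loci))
    pos = np.sort(rng.choice(100_000, size=n_loci, replace=False)) + 1
    return make_matrix(dos, positions=pos, scaffold=scaffold)


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-population cohort with planted outliers, annotation, and truth."""
    from mycopop.simulate import simulate_annotation, simulate_phenotypes

    cfg = SimulationConfig(
        n_populations=3,
        strains_per_population=(12, 8, 12),
        n_loci=1500,
        scaffold_layout=(("sc1", 120_000), ("sc2", 80_000)),
        baseline_divergence=(0.2, 0.2, 0.2),
        inbreeding=(0.1, 0.1, 0.1),
        n_hybrids=2,
        outlier_fraction=0.03,
        outlier_divergence=0.7,
        n_genes=60,
        seed=11,
    )
    matrix, truth = simulate_genotypes(cfg)
    annotation, go_map = simulate_annotation(cfg, truth)
    phenotypes = simulate_phenotypes(cfg, truth)
    return {
        "config": cfg,
        "matrix": matrix,
        "truth": truth,
        "annotation": annotation,
        "go_map": go_map,
        "phenotypes": phenotypes,
        "assignment": truth.assignment(),
    }


@pytest.fixture
def two_pop_assignment():
    labels = {f"S{i}": ("A" if i < 5 else "B") for i in range(10)}
    return GroupAssignment(labels=labels)
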
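import numpy as np
import pandas as pd
import pytest

from strainreg.simulate import SimulationConfig, CohortSimulator


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized cohort with all planted structure (shared)."""
    cfg = SimulationConfig(seed=11, n_genes=300)
    return CohortSimulator(cfg).run()


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects at all: treatment, interaction and synergy off."""
    cfg = SimulationConfig(seed=12, n_genes=400, frac_interaction_genes=0.0,
                           frac_motif_genes=0.0, frac_synergy_genes=0.0,
                           treatment_effect_sd=0.0)
    return CohortSimulator(cfg).run()


@pytest.fixture()
def small_design():
    rows = []
    for strain in ("B6", "BALB"):
        for treat in ("Ctrl", "IL4"):
            for rep in (1, 2, 3):
                rows.append((f"{strain}_{treat}_r{rep}", strain, treat, rep))
    design = pd.DataFrame(rows, columns=["sample", "strain", "treatment",
                                         "replicate"])
    return design.set_index("sample", drop=False)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000,
                     max_len=2_000):
    rows = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        rows.append((chrom, start, start + length, f"iv{i}", 0.0, "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])
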
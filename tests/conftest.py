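import numpy as np
import pandas as pd
import pytest

from capacitrack import synthetic_data as sd
from capacitrack import to_log2
from capacitrack.soft_clustering import standardize_profiles
from capacitrack.stage_identity import SignatureSet, build_signatures

TIMEPOINTS = ("d0", "d1", "d2", "d3", "d7", "d10")
STAGES = ("EPI", "post-E", "post-L")


@pytest.fixture(scope="session")
def small_timecourse():
    """100 genes (50 variable, 10 per archetype), 6 timepoints x 3
    replicates x 2 cell lines, mild noise."""
    return sd.generate_timecourse(
        n_genes=100, n_variable=50, timepoints=TIMEPOINTS,
        n_replicates=3, n_cell_lines=2, noise_cv=0.1, seed=1,
    )


@pytest.fixture(scope="session")
def noiseless_timecourse():
    return sd.generate_timecourse(
        n_genes=100, n_variable=50, timepoints=TIMEPOINTS,
        n_replicates=3, n_cell_lines=2, noise_cv=0.0, seed=1,
    )


@pytest.fixture(scope="session")
def planted_profiles():
    """Standardized temporal profiles of 1000 planted archetype genes at
    noise_cv=0.2 (one cell line), plus the generating truth."""
    matrix, sheet, truth = sd.generate_timecourse(
        n_genes=1000, n_variable=1000, timepoints=TIMEPOINTS,
        n_replicates=3, n_cell_lines=1, noise_cv=0.2, seed=11,
    )
    prof = standardize_profiles(to_log2(matrix), sheet)
    return prof, truth


@pytest.fixture(scope="session")
def stage_reference():
    matrix, sheet = sd.generate_stage_reference(
        n_genes=500, stages=STAGES, cells_per_stage=20,
        separation=3.0, noise_cv=0.0, seed=5,
    )
    return matrix, sheet


@pytest.fixture(scope="session")
def signatures(stage_reference) -> SignatureSet:
    matrix, sheet = stage_reference
    return build_signatures(matrix, sheet, list(STAGES))


@pytest.fixture()
def toy_signatures() -> SignatureSet:
    """The 3-gene, 2-stage signature set with a hand-checkable exact
    mixture: x = 0.75*A + 0.25*B for x=(1.5, 0.5, 1)."""
    return SignatureSet(
        pd.DataFrame({"A": [2.0, 0.0, 1.0], "B": [0.0, 2.0, 1.0]},
                     index=["g1", "g2", "g3"])
    )


def archetype_agreement(mm, truth) -> float:
    """Fraction of genes hard-assigned to their planted archetype's cluster
    after optimal cluster-to-archetype matching (Hungarian on the
    contingency table)."""
    from scipy.optimize import linear_sum_assignment

    genes = mm.gene_ids
    arch = [truth.gene_archetype[g] for g in genes]
    arch_levels = sorted(set(arch))
    clusters = list(mm.centroids.index)
    table = np.zeros((len(clusters), len(arch_levels)))
    for g, a in zip(genes, arch):
        table[clusters.index(int(mm.hard_assignment[g])), arch_levels.index(a)] += 1
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / len(genes))
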
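"""Shared fixtures: synthetic cohorts and (expensive) fitted results.

The planted cohort is the generator's default study design: 11 cases vs 11
controls, 1000 reads/sample, a shared 5-residue motif at the CDR3 start in
cases (and at the end in controls, making the signal purely positional).
Grid searches in the fixtures use the reduced grid (k in {4, 5}, PCs 1-6)
so the whole suite stays fast; the full grid is exercised on unit scale.
"""

from __future__ import annotations

import numpy as np
import pytest

import tcrkmer as t

REDUCED_SPECS = t.default_grid(ks=(4, 5), include_full_cdr3=False)
MAX_PC = 6


@pytest.fixture(scope="session")
def planted_cohort() -> t.Cohort:
    return t.generate_cohort(t.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def planted_grid(planted_cohort) -> t.GridResult:
    return t.grid_search(planted_cohort, specs=REDUCED_SPECS, max_pc=MAX_PC)


@pytest.fixture(scope="session")
def planted_loocv(planted_cohort) -> t.CVResult:
    return t.loocv(planted_cohort, specs=REDUCED_SPECS, max_pc=MAX_PC)


@pytest.fixture(scope="session")
def replicate_grids() -> list[tuple[t.Cohort, t.GridResult]]:
    """Grid-search results on 20 independently seeded planted cohorts."""
    out = []
    for seed in range(20):
        cohort = t.generate_cohort(t.GeneratorConfig(seed=seed))
        out.append(
            (cohort, t.grid_search(cohort, specs=REDUCED_SPECS, max_pc=MAX_PC))
        )
    return out


def random_repertoire(
    rng: np.random.Generator,
    sample_id: str = "s1",
    n_clonotypes: int | None = None,
    min_len: int = 4,
    max_len: int = 18,
    max_count: int = 20,
    label: str = "unknown",
) -> t.Repertoire:
    """A repertoire of random CDR3s for oracle comparisons."""
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    if n_clonotypes is None:
        n_clonotypes = int(rng.integers(1, 51))
    clonos = []
    for _ in range(n_clonotypes):
        length = int(rng.integers(min_len, max_len + 1))
        aa = "".join(rng.choice(alphabet, size=length))
        clonos.append(
            t.Clonotype(
                cdr3_aa=aa,
                count=int(rng.integers(1, max_count + 1)),
                v_call=f"TRGV{int(rng.integers(1, 5))}",
                j_call=f"TRGJ{int(rng.integers(1, 3))}",
            )
        )
    return t.Repertoire(
        sample_id=sample_id, clonotypes=t.merge_clonotypes(clonos), label=label
    )
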
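import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_bed(tmp_path):
    """Three-locus BED: one tRNA, one 5S, one SINE."""
    path = tmp_path / "loci.bed"
    path.write_text(
        "chr1\t100\t172\ttRNA-Ile-TAT-1\t0\t+\n"
        "chr8\t500\t620\tRn5s-1\t0\t+\n"
        "chr2\t900\t1200\tSINE-B2-1\t0\t-\n"
    )
    return path


@pytest.fixture
def chip_scores_fixture(rng):
    """50-locus x 6-sample score matrix with 5 shifted loci (3 WT vs 3 KO)."""
    n = 50
    base = rng.normal(2.0, 1.0, n)
    mat = base[:, None] + rng.normal(0.0, 0.3, (n, 6))
    mat[:5, 3:] += 2.0
    scores = pd.DataFrame(
        mat,
        index=[f"L{i:03d}" for i in range(n)],
        columns=[f"{g}_{r}" for g in ("WT", "KO") for r in (1, 2, 3)],
    )
    groups = ["WT"] * 3 + ["KO"] * 3
    return scores, groups
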
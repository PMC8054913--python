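import numpy as np
import pandas as pd
import pytest

from organodyn.exprpipe import CountMatrix, run_pipeline
from organodyn.synthgen import SynthExprConfig, simulate_counts

#: documented recovery conditions: two species, three timepoints (the days
#: the differential analysis contrasts), three replicates, 20% planted
#: shifts, negative-binomial dispersion 0.05 (~22% CV between batches)
RECOVERY_CONFIG = dict(
    n_genes=2000,
    timepoints=(3, 5, 10),
    n_replicates=3,
    shift_fraction=0.2,
    dispersion=0.05,
    seed=1,
)


@pytest.fixture(scope="session")
def recovery_run():
    """Full pipeline on the documented noisy synthetic time course."""
    cfg = SynthExprConfig(**RECOVERY_CONFIG)
    cm, truth = simulate_counts(cfg)
    res = run_pipeline(cm, term_map=truth.term_map, k=10, m=2.0, seed=1)
    return cm, truth, res


@pytest.fixture(scope="session")
def noisefree_run():
    """Same design in the deterministic (noise-free) limit."""
    cfg = SynthExprConfig(**{**RECOVERY_CONFIG, "noise_free": True})
    cm, truth = simulate_counts(cfg)
    res = run_pipeline(cm, term_map=truth.term_map, k=10, m=2.0, seed=1)
    return cm, truth, res


def make_count_matrix(counts: dict, meta_rows: list, lengths: dict) -> CountMatrix:
    """Assemble a small CountMatrix from plain dicts (test helper)."""
    df = pd.DataFrame(counts)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(
        counts=df,
        sample_meta=meta,
        gene_length=pd.Series(lengths),
    )


@pytest.fixture
def toy_counts() -> CountMatrix:
    """Two species x two days x two replicates, four genes."""
    genes = ["gA", "gB", "gC", "gD"]
    rng = np.random.default_rng(0)
    counts = {}
    meta_rows = []
    for sp in ("human", "gorilla"):
        for day in (3, 5):
            for rep in (1, 2):
                name = f"{sp}_d{day}_r{rep}"
                counts[name] = rng.integers(10, 1000, size=4)
                meta_rows.append(
                    {"sample": name, "species": sp, "day": day, "replicate": rep}
                )
    df = pd.DataFrame(counts, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(
        counts=df,
        sample_meta=meta,
        gene_length=pd.Series([1000.0, 1500.0, 2000.0, 800.0], index=genes),
    )
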
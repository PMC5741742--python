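import numpy as np
import pandas as pd
import pytest

from hybridtx import SimulationConfig, simulate_allele_counts, simulate_expression


def make_dataset(gene_means: dict, n_replicates: int = 3, jitter: float = 0.0, seed: int = 0):
    """Build a tiny matrix + sheet from per-line mean FPKM.

    ``gene_means`` maps gene_id -> {line_id: mean}; lines are the two 4N
    parents plus hybrid clones. Optional multiplicative jitter makes
    replicates distinguishable for t-tests.
    """
    lines = [
        ("tauGFP4N", "parent_ES", "4N", "NA"),
        ("m5S4N8", "parent_FIB", "4N", "NA"),
    ]
    clone_lines = sorted(
        {ln for means in gene_means.values() for ln in means} - {"tauGFP4N", "m5S4N8"}
    )
    for c in clone_lines:
        phen = "ES_like" if c.startswith("tme") else "FIB_like"
        lines.append((c, "hybrid", "near4N", phen))
    rng = np.random.default_rng(seed)
    rows, meta_rows = {}, []
    for line, role, ploidy, phen in lines:
        for r in range(1, n_replicates + 1):
            sid = f"{line}_r{r}"
            vals = []
            for g in gene_means:
                m = gene_means[g][line]
                vals.append(m * (1 + jitter * rng.standard_normal()) if jitter else m)
            rows[sid] = vals
            meta_rows.append(
                dict(sample_id=sid, line_id=line, role=role, ploidy=ploidy,
                     phenotype=phen, replicate=r)
            )
    matrix = pd.DataFrame(rows, index=pd.Index(list(gene_means), name="gene_id"))
    meta = pd.DataFrame(meta_rows)
    return matrix, meta


@pytest.fixture(scope="session")
def zero_noise_run():
    """A noiseless 2,000-gene simulated study with allele counts."""
    cfg = SimulationConfig(n_genes=2000, noise_sd=0.0, seed=42)
    matrix, meta, truth = simulate_expression(cfg)
    counts = simulate_allele_counts(cfg, truth)
    return cfg, matrix, meta, truth, counts


@pytest.fixture(scope="session")
def noisy_run():
    """A 2,000-gene simulated study at the default replicate noise."""
    cfg = SimulationConfig(n_genes=2000, noise_sd=0.05, seed=43)
    matrix, meta, truth = simulate_expression(cfg)
    counts = simulate_allele_counts(cfg, truth)
    return cfg, matrix, meta, truth, counts
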
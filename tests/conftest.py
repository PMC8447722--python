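import numpy as np
import pandas as pd
import pytest

from popcnv import (SimConfig, ElementDef, assign_libraries, normalize_coverage,
                    simulate_coverage_matrix, simulate_population)
from popcnv.simulate import library_meta_frame

W = 5000
MB = 1_000_000


def scaled_config(seed=7, noise=0.1, elements=None, contigs=None, n_clones=15):
    """A desk-scale population: 3 contigs, elements from 3 to 200 windows."""
    contigs = contigs or {"c0": 100 * W, "c1": 300 * W, "c2": 200 * W}
    if elements is None:
        elements = (
            ElementDef("eA", 100 * W / MB, 48.0, ((0, 100),), 6),
            ElementDef("eB", 50 * W / MB, 48.0, ((150, 200),), 6),
            ElementDef("eC", 3 * W / MB, 36.0, ((250, 253),), 4),
            ElementDef("eD", 200 * W / MB, 48.0, ((400, 600),), 6),
        )
    return SimConfig(n_clones=n_clones, elements=elements, basal_2c_mb=414.0,
                     window_size_bp=W, contig_lengths=contigs,
                     noise_dispersion=noise, seed=seed)


@pytest.fixture(scope="session")
def small_sim():
    """One simulated 29-library population plus its normalized matrix."""
    cfg = scaled_config()
    genotypes = simulate_population(cfg)
    libraries = assign_libraries(genotypes, cfg.elements, seed=cfg.seed)
    raw, exon_means = simulate_coverage_matrix(genotypes, libraries, cfg)
    norm = normalize_coverage(raw, exon_means)
    return {
        "config": cfg,
        "genotypes": genotypes,
        "libraries": libraries,
        "raw": raw,
        "norm": norm,
        "exon_means": exon_means,
        "meta": library_meta_frame(libraries),
    }


def copy_vector_matrix(copy_numbers, n_diploid_flank=5, noise_sd=0.05,
                       n_var=10, seed=0, contig="ctg"):
    """A one-contig normalized matrix: diploid flanks around a variable
    segment whose per-library values equal per-library copy numbers."""
    from popcnv import WindowCoverageMatrix, tile_windows

    rng = np.random.default_rng(seed)
    libs = [f"L{i}" for i in range(len(copy_numbers))]
    n = n_diploid_flank * 2 + n_var
    vals = np.full((n, len(libs)), 2.0)
    seg = slice(n_diploid_flank, n_diploid_flank + n_var)
    vals[seg] = np.asarray(copy_numbers, dtype=float)[None, :]
    vals = np.clip(vals + rng.normal(0, noise_sd, size=vals.shape), 0, None)
    ws = tile_windows({contig: n * W}, W)
    return WindowCoverageMatrix(window_set=ws,
                                values=pd.DataFrame(vals, columns=libs),
                                normalized=True)
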
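import numpy as np
import pandas as pd
import pytest

from synterate import (
    GenomeAnnotation,
    OrthologMap,
    SimulationConfig,
    evolve_gene_orders,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def identity_map(n: int, circular: bool = True) -> OrthologMap:
    """Ortholog map of two genomes with identical gene order and strands."""
    return OrthologMap(
        genes_a=np.array([f"a{i}" for i in range(n)], dtype=object),
        genes_b=np.array([f"b{i}" for i in range(n)], dtype=object),
        rank_a=np.arange(n), rank_b=np.arange(n),
        strand_a=np.full(n, "+"), strand_b=np.full(n, "+"),
        circular_a=circular, circular_b=circular,
    )


def map_from_orders(order_a, order_b, circular: bool = True) -> OrthologMap:
    """Ortholog map from two signed gene-id orderings (shared ids)."""
    rank_a = {abs(g): i for i, g in enumerate(order_a)}
    strand_a = {abs(g): "+" if g > 0 else "-" for g in order_a}
    ids = [abs(g) for g in order_b]
    return OrthologMap(
        genes_a=np.array([f"g{g}" for g in ids], dtype=object),
        genes_b=np.array([f"g{g}" for g in ids], dtype=object),
        rank_a=np.array([rank_a[g] for g in ids]),
        rank_b=np.arange(len(ids)),
        strand_a=np.array([strand_a[g] for g in ids]),
        strand_b=np.array(["+" if g > 0 else "-" for g in order_b]),
        circular_a=circular, circular_b=circular,
    )


def annotation_from_strands(strands, length_per_gene: int = 1000,
                            oric: int = 0, resistance: str = "N",
                            rrna_flags=None) -> GenomeAnnotation:
    n = len(strands)
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "start": [i * length_per_gene + 100 for i in range(n)],
        "end": [i * length_per_gene + 900 for i in range(n)],
        "strand": list(strands),
        "is_rrna": list(rrna_flags) if rrna_flags is not None else [False] * n,
    })
    return GenomeAnnotation(replicon_id="toy", length=n * length_per_gene,
                            circular=True, oric=oric, genes=genes,
                            resistance=resistance)


@pytest.fixture(scope="session")
def small_clade():
    """A light mixed-rate clade reused by several integration tests."""
    cfg = SimulationConfig(n_species=8, n_resistant=3, n_genes=300,
                           tree_model="yule", depth=0.05, rate_N=800.0,
                           rate_R=2400.0, gene_loss_rate=0.3, seed=11)
    return evolve_gene_orders(cfg)


def points_from_clade(clade, subsample=250, n_resamples=50, seed=0):
    from synterate import resampled_estimate

    rng = np.random.default_rng(seed)
    rows = []
    for a, b in clade.pairs():
        omap = clade.ortholog_map(a, b)
        est = resampled_estimate(omap, subsample, n_resamples, rng=rng,
                                 include_inversions=False)
        rows.append({"species_a": a, "species_b": b, "x": clade.x(a, b),
                     "goc": est.goc_mean, "category": clade.pair_category(a, b)})
    return pd.DataFrame(rows)
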
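import numpy as np
import pandas as pd
import pytest

from promscreen import (
    CountMatrix,
    GeneRecord,
    GenomeAnnotation,
    SyntheticSpec,
    simulate_bundle,
)


@pytest.fixture
def toy_matrix() -> CountMatrix:
    """3 genes x 2 samples with a forced ranking."""
    df = pd.DataFrame(
        {"S1": [10, 5, 1], "S2": [1, 5, 10]}, index=["a", "b", "c"]
    )
    return CountMatrix(df)


@pytest.fixture
def linear_two_gene() -> GenomeAnnotation:
    """A(0,100,+), B(250,400,+) on a 500 bp linear replicon."""
    return GenomeAnnotation(
        replicon_id="toy",
        length=500,
        circular=False,
        genes=[
            GeneRecord("A", 0, 100, "+"),
            GeneRecord("B", 250, 400, "+"),
        ],
    )


@pytest.fixture
def default_bundle():
    """One default synthetic study bundle (200 genes, 4 samples)."""
    return simulate_bundle(SyntheticSpec(seed=11))


def random_annotation(
    rng: np.random.Generator,
    n_genes: int,
    length: int = 10_000,
    circular: bool = True,
) -> GenomeAnnotation:
    """Random non-overlapping toy annotation for oracle comparisons."""
    n = n_genes
    if n == 0:
        return GenomeAnnotation("rand", length, [], circular=circular)
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n, replace=False))
    genes = []
    for i in range(n):
        start, end = int(cuts[2 * i]), int(cuts[2 * i + 1])
        genes.append(
            GeneRecord(
                f"g{i:03d}", start, end, rng.choice(["+", "-"]),
            )
        )
    return GenomeAnnotation("rand", length, genes, circular=circular)


def walk_gap_oracle(annotation: GenomeAnnotation, gene_id: str) -> int:
    """Brute-force upstream gap length: walk base by base from the gene's
    5' boundary away from the gene until a position covered by any feature
    (or the replicon edge) is reached."""
    gene = annotation.gene(gene_id)
    L = annotation.length

    def covered(p: int) -> bool:
        return any(f.start <= p < f.end for f in annotation.genes)

    steps = 0
    if gene.strand == "+":
        p = gene.start - 1
        while steps < L:
            if p < 0:
                if not annotation.circular:
                    return steps
                p += L
            if covered(p):
                return steps
            steps += 1
            p -= 1
        return steps
    p = gene.end
    while steps < L:
        if p >= L:
            if not annotation.circular:
                return steps
            p -= L
        if covered(p):
            return steps
        steps += 1
        p += 1
    return steps
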
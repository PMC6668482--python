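import numpy as np
import pandas as pd
import pytest

from tedrift import AnnotationSet, ToyGenomeSpec, make_toy_genome


@pytest.fixture(scope="session")
def toy_genome():
    """Desk-scale two-chromosome genome shared by enrichment tests."""
    return make_toy_genome(ToyGenomeSpec(seed=3))


@pytest.fixture(scope="session")
def annotation(toy_genome):
    return toy_genome.annotation


@pytest.fixture()
def mini_annotation():
    """Hand-built single-chromosome annotation with known geometry.

    chr1 (10 kb): a + strand gene at [3000, 4000) whose 5'UTR overlaps an
    exon (hierarchy probe), a - strand gene at [7000, 8000), two dyads at
    100 and 200, one chromatin state-5 block, and a masked block [0, 500).
    """
    genes = pd.DataFrame(
        [
            ("Gp", "chr1", 3000, 4000, "+", False),
            ("Gm", "chr1", 7000, 8000, "-", True),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand", "essential"],
    )
    parts = pd.DataFrame(
        [
            ("Gp", "five_prime_utr", "chr1", 3000, 3100),
            ("Gp", "exon", "chr1", 3000, 3400),  # deliberately overlaps the 5'UTR
            ("Gp", "intron", "chr1", 3400, 3500),
            ("Gp", "exon", "chr1", 3500, 3900),
            ("Gp", "three_prime_utr", "chr1", 3900, 4000),
            ("Gm", "three_prime_utr", "chr1", 7000, 7100),
            ("Gm", "exon", "chr1", 7100, 7900),
            ("Gm", "five_prime_utr", "chr1", 7900, 8000),
        ],
        columns=["gene_id", "part", "chrom", "start", "end"],
    )
    states = pd.DataFrame(
        [("chr1", 1000, 2000, 5)], columns=["chrom", "start", "end", "state"]
    )
    dyads = pd.DataFrame([("chr1", 100), ("chr1", 200)], columns=["chrom", "pos"])
    mask = pd.DataFrame([("chr1", 0, 500)], columns=["chrom", "start", "end"])
    return AnnotationSet(
        chrom_sizes={"chr1": 10_000},
        genes=genes,
        gene_parts=parts,
        states=states,
        dyads=dyads,
        mask=mask,
    )


def sites_frame(chroms, positions, **extra):
    frame = pd.DataFrame({"chrom": chroms, "pos": np.asarray(positions, dtype=np.int64)})
    for key, val in extra.items():
        frame[key] = val
    return frame
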
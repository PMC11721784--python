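import numpy as np
import pytest

from denovopop.io_formats import AlleleState, GenotypeMatrix, VariantRecord
from denovopop.synthetic_data import gen_catalog_variants


@pytest.fixture(scope="session")
def catalog_bundle(tmp_path_factory):
    """A small two-population catalog with planted LoF truth, on disk."""
    out = tmp_path_factory.mktemp("catalog")
    return gen_catalog_variants(
        {"Africa": 60, "Europe": 40},
        n_genes=4,
        lof_freq=[[5 / 60, 0.0], [1.0, 0.5], [0.0, 0.1], [0.2, 1.0]],
        seed=11,
        out_dir=out,
    )


def translation_walk_status(seq: str, ref_protein_len: int) -> str:
    """Independent brute-force oracle for ORF classification.

    Walks the standard genetic code over the raw edited sequence via
    Biopython and applies the loss-of-function definition directly.
    """
    from Bio.Seq import Seq

    if not seq.startswith("ATG"):
        return "START_LOST"
    n_codons = len(seq) // 3
    protein = str(Seq(seq[: 3 * n_codons]).translate())
    stop = protein.find("*")
    if stop == -1:
        return "STOP_LOST"
    if stop < ref_protein_len:
        return "PREMATURE_STOP"
    return "FUNCTIONAL"


@pytest.fixture
def small_genotypes():
    """3 accessions x 2 variants with every allele state exercised."""
    variants = [
        VariantRecord("1", 5, "A", "T"),
        VariantRecord("1", 9, "C", "G"),
    ]
    calls = np.array(
        [
            [AlleleState.REF, AlleleState.REF],
            [AlleleState.ALT, AlleleState.REF],
            [AlleleState.HET, AlleleState.MISSING],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["acc1", "acc2", "acc3"], variants, calls)
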
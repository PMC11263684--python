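import warnings

import pytest

from vacinus.peptides import VariantClass, VariantRecord
from vacinus.simulate import TilSpec, make_til_dataset

# scanpy emits benign FutureWarnings under numpy 2; keep test output readable
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def missense_variant():
    """Missense at interior position 10 of a 30-residue protein."""
    wt = "ARNDCQEGHILKMFPSTWYVARNDCQEGHI"
    mt = wt[:9] + "W" + wt[10:]
    return VariantRecord(
        variant_id="v_mis",
        gene="G1",
        variant_class=VariantClass.MISSENSE,
        protein_pos=10,
        wt_protein=wt,
        mt_protein=mt,
        vaf=0.3,
        read_count=25,
        tpm=10.0,
    )


@pytest.fixture
def frameshift_variant():
    """Frameshift at position 5 with a 12-residue novel tail (mutant len 16)."""
    wt = "ARNDCQEGHI"
    mt = wt[:4] + "WLKMNPQSTVYA"
    return VariantRecord(
        variant_id="v_fs",
        gene="G2",
        variant_class=VariantClass.FRAMESHIFT,
        protein_pos=5,
        wt_protein=wt,
        mt_protein=mt,
        vaf=0.2,
        read_count=40,
        tpm=8.0,
    )


@pytest.fixture(scope="session")
def three_program_dataset():
    """Three well-separated expression programs at the default 5-sd effect."""
    comp = {"exhausted": 0.34, "effector": 0.33, "naive/memory": 0.33}
    return make_til_dataset(TilSpec(seed=11, n_cells=450, composition=comp))


@pytest.fixture(scope="session")
def til_dataset():
    """Full seven-subtype CD8 TIL fixture with CD4 contaminants."""
    return make_til_dataset(TilSpec(seed=5, n_cells=700, n_cd4_cells=60))
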
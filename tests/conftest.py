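import numpy as np
import pytest

from aneuvar import simulate
from aneuvar.types import (
    Affection,
    CallSet,
    Individual,
    Pedigree,
    VariantKey,
)


@pytest.fixture(scope="session")
def table2_fixture():
    """Risk-gene screen fixture: (callset, annotations)."""
    return simulate.build_table2_fixture()


@pytest.fixture(scope="session")
def table2_metadata():
    return simulate.table2_fixture_metadata()


@pytest.fixture(scope="session")
def family_fixture():
    """(callset, annotations, pedigree, control frequency table)."""
    return simulate.build_family_fixture()


@pytest.fixture(scope="session")
def family_metadata():
    return simulate.family_fixture_metadata()


def make_callset(sample_ids, variant_names, zygosity):
    """Small hand-built CallSet; variant_names become GENE:c. keys."""
    variants = [VariantKey(f"G{i}", f"NM_{i}", name)
                for i, name in enumerate(variant_names)]
    return CallSet(sample_ids, variants,
                   np.asarray(zygosity, dtype=np.int8))


def make_trio(child_affection=Affection.AFFECTED, family_id="F1"):
    return Pedigree([
        Individual("dad", family_id, None, None, "male",
                   Affection.UNAFFECTED),
        Individual("mom", family_id, None, None, "female",
                   Affection.UNAFFECTED),
        Individual("kid", family_id, "dad", "mom", "unknown",
                   child_affection),
    ])
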
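import pytest

from tapemeasure.architecture import build_reference_architecture
from tapemeasure.generate import GeneratorParams, generate_sequence
from tapemeasure.mutants import load_packaged_table


@pytest.fixture(scope="session")
def arch():
    return build_reference_architecture()


@pytest.fixture(scope="session")
def reference_sequence(arch):
    """Zero-noise synthetic sequence plus its planted annotation."""
    return generate_sequence(arch, GeneratorParams(seed=0))


@pytest.fixture(scope="session")
def table1():
    return load_packaged_table(1)


@pytest.fixture(scope="session")
def table2():
    return load_packaged_table(2)
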
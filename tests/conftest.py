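import copy
from pathlib import Path

import pytest
import yaml
from importlib import resources

from iemscreen import base_case_values, evaluate, load_default_parameters


@pytest.fixture(scope="session")
def pset():
    return load_default_parameters()


@pytest.fixture(scope="session")
def base_values(pset):
    return base_case_values(pset)


@pytest.fixture(scope="session")
def base_outputs(base_values):
    return evaluate(base_values)


@pytest.fixture(scope="session")
def default_yaml_doc():
    """The bundled parameter file as a mutable dict (deep-copied per use)."""
    ref = resources.files("iemscreen.data") / "parameters.yaml"
    return yaml.safe_load(ref.read_text())


@pytest.fixture
def write_params(tmp_path, default_yaml_doc):
    """Write a (possibly mutated) copy of the bundled parameters to disk."""

    def _write(mutate=None) -> Path:
        doc = copy.deepcopy(default_yaml_doc)
        if mutate is not None:
            mutate(doc)
        p = tmp_path / "params.yaml"
        p.write_text(yaml.safe_dump(doc))
        return p

    return _write
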
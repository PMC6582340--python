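import pytest

from searchkin import ModelParameters
from searchkin.fixtures import TOY_PRESETS, make_toy_complex, toy_complex_spec


@pytest.fixture(scope="session")
def toy_paths(tmp_path_factory):
    """preset name -> {"pdb": Path, "cif": Path} for every toy complex."""
    out = tmp_path_factory.mktemp("toys")
    return {name: make_toy_complex(toy_complex_spec(name), out)
            for name in TOY_PRESETS}


@pytest.fixture()
def default_params():
    return ModelParameters()
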
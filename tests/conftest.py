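import pytest

from dpsircloud import (
    CP,
    LOP,
    default_panel_spec,
    default_schema,
    generate_panel,
)


@pytest.fixture(scope="session")
def schema_and_grades():
    return default_schema()


@pytest.fixture(scope="session")
def schema(schema_and_grades):
    return schema_and_grades[0]


@pytest.fixture(scope="session")
def grades(schema_and_grades):
    return schema_and_grades[1]


@pytest.fixture(scope="session")
def panel_spec():
    return default_panel_spec(seed=42)


@pytest.fixture(scope="session")
def cp_panel(panel_spec):
    return generate_panel(panel_spec, CP)


@pytest.fixture(scope="session")
def lop_panel(panel_spec):
    return generate_panel(panel_spec, LOP)
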
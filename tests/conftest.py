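import pytest

from provflow.registry import Component, Registry, SemanticType
from provflow.fixtures import build_fixture_registry


def make_toy_registry() -> Registry:
    """A tiny arithmetic registry for executor and store tests."""
    reg = Registry()
    reg.register_type(SemanticType("number", "Number", "A JSON number"))
    reg.register_type(SemanticType("viz", "Visualization", "A chart description"))
    reg.register_component(Component(
        id="inject", kind="prompt", label="Inject number",
        description="Provide a starting number",
        inputs={}, output="number",
        config_schema={
            "type": "object",
            "properties": {"value": {"type": "number"}},
            "required": ["value"],
            "additionalProperties": False,
        },
        run=lambda inputs, config: config["value"],
        story="The number {value} was provided.",
    ))
    reg.register_component(Component(
        id="plus_one", kind="resolver", label="Plus one",
        description="Add one to a number",
        inputs={"x": "number"}, output="number",
        run=lambda inputs, config: inputs["x"] + 1,
        story="One was added to the number.",
    ))
    reg.register_component(Component(
        id="double", kind="resolver", label="Double",
        description="Multiply a number by two",
        inputs={"x": "number"}, output="number",
        run=lambda inputs, config: inputs["x"] * 2,
    ))
    reg.register_component(Component(
        id="add", kind="resolver", label="Add numbers",
        description="Sum of two numbers",
        inputs={"a": "number", "b": "number"}, output="number",
        run=lambda inputs, config: inputs["a"] + inputs["b"],
    ))

    def _boom(inputs, config):
        raise RuntimeError("boom")

    reg.register_component(Component(
        id="fail", kind="resolver", label="Always fails",
        description="A resolver that raises",
        inputs={"x": "number"}, output="number",
        run=_boom,
    ))
    return reg


@pytest.fixture
def toy_registry() -> Registry:
    return make_toy_registry()


@pytest.fixture
def fixture_registry() -> Registry:
    return build_fixture_registry()
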
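import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qcai.adapter import (
    CROSS_ATTENTION,
    SELF_ATTENTION,
    AttentionRecord,
    LayerTopology,
    TargetSpec,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_record(
    attention,
    grad_attention,
    query_act=None,
    key_act=None,
    grad_query=None,
    grad_key=None,
    layer_id=0,
    kind=CROSS_ATTENTION,
    query_source="cdr3b",
    key_source="pep",
    d=4,
):
    """Assemble a valid AttentionRecord around given attention/grad tensors."""
    attention = np.asarray(attention, dtype=float)
    grad_attention = np.asarray(grad_attention, dtype=float)
    if attention.ndim == 2:
        attention = attention[np.newaxis]
    if grad_attention.ndim == 2:
        grad_attention = grad_attention[np.newaxis]
    _, n, m = attention.shape
    if kind == SELF_ATTENTION:
        key_source = query_source
    return AttentionRecord(
        topology=LayerTopology(layer_id, kind, query_source, key_source),
        attention=attention,
        query_act=np.zeros((n, d)) if query_act is None else np.asarray(query_act, float),
        key_act=np.zeros((m, d)) if key_act is None else np.asarray(key_act, float),
        grad_attention=grad_attention,
        grad_query=np.zeros((n, d)) if grad_query is None else np.asarray(grad_query, float),
        grad_key=np.zeros((m, d)) if grad_key is None else np.asarray(grad_key, float),
    )


def random_inputs(rng, pep_len=9, cdr_len=12):
    return {
        "pep": [AA[i] for i in rng.integers(0, 20, pep_len)],
        "cdr3b": [AA[i] for i in rng.integers(0, 20, cdr_len)],
    }


@pytest.fixture
def class_target():
    return TargetSpec(kind="class", class_id=0)


@pytest.fixture
def toy_run(class_target):
    from qcai.adapter import run_with_capture
    from qcai.fixtures import ToyModelConfig, make_toy_model

    model = make_toy_model(ToyModelConfig(seed=0))
    inputs = {"pep": list("ACDEF"), "cdr3b": list("GHIKLM")}
    return run_with_capture(model, inputs, class_target)
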
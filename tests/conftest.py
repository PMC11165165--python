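import pytest

from teratoassay.assay_io import AssayArm, DoseGroup


def make_arm(doses, n, counts, **meta):
    """Build a validated arm from parallel dose/count sequences."""
    fields = {
        "cell_line": "test-line",
        "recipient": "test-mouse",
        "route": "subcutaneous",
        "model_class": "syngeneic",
        "monitoring_weeks": 12.0,
    }
    fields.update(meta)
    if isinstance(n, int):
        n = [n] * len(doses)
    return AssayArm(
        groups=tuple(
            DoseGroup(dose=int(d), n_animals=int(m), n_positive=int(k))
            for d, m, k in zip(doses, n, counts)
        ),
        **fields,
    )


@pytest.fixture
def arm_factory():
    return make_arm


@pytest.fixture
def clean_step_arm():
    """0/5 at 10^2, 5/5 at 10^3: the textbook symmetric step (TD50 = 10^2.5)."""
    return make_arm((1e2, 1e3), 5, (0, 5))


@pytest.fixture
def all_negative_arm():
    return make_arm((1e6, 1e7), 5, (0, 0), route="tail_vein", model_class="xeno")
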
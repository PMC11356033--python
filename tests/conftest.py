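import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from lipidqc import AnnotationTable, LipidAnnotation, parse_formula

_COUNTER = {"n": 0}


def make_annotation(formula, lipid_class, rt_min, ms_level="MS1", name="", id=None):
    if id is None:
        _COUNTER["n"] += 1
        id = f"t{_COUNTER['n']}"
    return LipidAnnotation(
        id=id,
        name=name or f"{lipid_class} {formula}",
        lipid_class=lipid_class,
        formula=formula,
        composition=parse_formula(formula),
        rt_min=rt_min,
        ms_level=ms_level,
    )


def make_table(rows, runtime_min=15.0, platform="test"):
    """rows: iterable of (formula, class, rt[, ms_level]) tuples."""
    anns = [make_annotation(*r) for r in rows]
    return AnnotationTable(annotations=anns, runtime_min=runtime_min, platform=platform)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def annotation_factory():
    return make_annotation
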
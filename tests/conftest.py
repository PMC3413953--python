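import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from setmix.registry_data import Cohort, CountRecord, jsog_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_cohort() -> Cohort:
    return jsog_fixture()


@st.composite
def count_records(draw, year=None, method=None, with_set_multiples=False):
    """Random registry records satisfying every structural invariant."""
    n_impl = draw(st.integers(min_value=1, max_value=200_000))
    n_preg = draw(st.integers(min_value=1, max_value=n_impl))
    n_set = draw(st.integers(min_value=0, max_value=n_preg))
    n_mult = draw(st.integers(min_value=0, max_value=n_preg))
    set_mult = (
        draw(st.integers(min_value=0, max_value=min(n_set, n_mult)))
        if with_set_multiples
        else None
    )
    return CountRecord(
        year=year if year is not None else draw(st.integers(1990, 2030)),
        method=method or draw(st.sampled_from(["fresh-IVF-ET", "fresh-ICSI", "frozen", "total"])),
        n_implantations=n_impl,
        n_pregnancies=n_preg,
        n_set_pregnancies=n_set,
        n_multiple_pregnancies=n_mult,
        n_set_multiple_pregnancies=set_mult,
    )


@st.composite
def cohorts(draw, max_records=8):
    n = draw(st.integers(min_value=0, max_value=max_records))
    methods = ["fresh-IVF-ET", "fresh-ICSI", "frozen", "other", "total"]
    keys = draw(
        st.lists(
            st.tuples(st.integers(1990, 2030), st.sampled_from(methods)),
            min_size=n, max_size=n, unique=True,
        )
    )
    records = tuple(
        draw(count_records(year=year, method=method, with_set_multiples=True))
        for year, method in keys
    )
    return Cohort(records, label="random")
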
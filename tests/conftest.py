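import dataclasses

import pytest

from mammotherm import (
    DEFAULT_BOUNDARY,
    DEFAULT_HEALTHY,
    DEFAULT_TUMOR,
    HEALTHY,
    TUMOR,
    build_domain,
    build_mesh,
    load_paper_charts,
    solve_steady,
)


@pytest.fixture(scope="session")
def healthy():
    return DEFAULT_HEALTHY


@pytest.fixture(scope="session")
def tumor_props():
    return DEFAULT_TUMOR


@pytest.fixture(scope="session")
def bc():
    return DEFAULT_BOUNDARY


@pytest.fixture(scope="session")
def paper_charts():
    return load_paper_charts()


@pytest.fixture(scope="session")
def coarse_tumor_solution():
    """One solved tumor scenario (R1=50, tumor (10,10), R2=3, 1 mm mesh),
    shared by tests that only need *a* converged field."""
    spec = build_domain(50, (10, 10), 3)
    grid = build_mesh(spec, 1.0)
    field = solve_steady(grid, {HEALTHY: DEFAULT_HEALTHY, TUMOR: DEFAULT_TUMOR}, DEFAULT_BOUNDARY)
    return grid, field


@pytest.fixture(scope="session")
def coarse_baseline_solution():
    """Tumor-free R1=50 solve on the same 1 mm mesh family."""
    spec = build_domain(50, (0, 0), 0)
    grid = build_mesh(spec, 1.0)
    field = solve_steady(grid, {HEALTHY: DEFAULT_HEALTHY}, DEFAULT_BOUNDARY)
    return grid, field


@pytest.fixture()
def replace():
    return dataclasses.replace
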
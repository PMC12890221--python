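import numpy as np
import pytest

from shade import BasisSystem, MultitypePattern, ObservationWindow


@pytest.fixture(scope="session")
def basis():
    return BasisSystem()  # cubic B-splines, P=6, r_max=150, r_min=25


@pytest.fixture(scope="session")
def gauss_basis():
    return BasisSystem(family="gaussian", P=4, r_max=100.0, r_min=25.0)


@pytest.fixture
def window():
    return ObservationWindow(0.0, 1000.0, 0.0, 1000.0)


@pytest.fixture
def two_type_pattern(window):
    """Deterministic small pattern with 3 'T' and 2 'B' cells."""
    pts = np.array([[10.0, 10.0], [500.0, 500.0], [900.0, 100.0],
                    [200.0, 800.0], [700.0, 700.0]])
    types = np.array(["T", "T", "T", "B", "B"], dtype=object)
    return MultitypePattern(pts, types, window, image_id="img1",
                            labels=("B", "T"))


def random_pattern(rng, window, n_by_type, image_id="img"):
    pts, types = [], []
    for lab, n in n_by_type.items():
        pts.append(np.column_stack([
            rng.uniform(window.x_min, window.x_max, n),
            rng.uniform(window.y_min, window.y_max, n)]))
        types.extend([lab] * n)
    return MultitypePattern(np.vstack(pts), np.array(types, dtype=object),
                            window, image_id=image_id,
                            labels=tuple(sorted(n_by_type)))
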
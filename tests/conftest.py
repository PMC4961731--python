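import pytest

from spinecarve.phantom import PhantomSpec, default_box, generate_phantom

# A compact phantom for unit tests: same intensity statistics as the
# default study phantom, smaller grid so the whole suite stays fast.
SMALL_GEOMETRY = dict(
    shape=(80, 80, 56),
    body_center_mm=(40.0, 32.0, 28.0),
    body_radii_mm=(20.0, 15.0, 11.0),
    process_length_mm=10.0,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(seed=11, **SMALL_GEOMETRY)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    volume, truth = generate_phantom(small_spec)
    return volume, truth, default_box(small_spec)
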
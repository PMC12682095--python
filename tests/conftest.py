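import pytest

from targetperim.bundles import BundleModel
from targetperim.observer import (
    BlindSpotSpec,
    Observer,
    make_healthy_field,
)
from targetperim.units import FieldLocation, NormativeModel, ReferenceField

BS_CENTRE = FieldLocation(15.0, -1.5)


@pytest.fixture(scope="session")
def normative() -> NormativeModel:
    return NormativeModel()


@pytest.fixture(scope="session")
def bundle_model() -> BundleModel:
    # session-scoped so the inverse-transform cache is shared across tests
    return BundleModel(bs_centre=BS_CENTRE)


@pytest.fixture(scope="session")
def reference(normative) -> ReferenceField:
    return ReferenceField(normative, gh=0.0, age=45.0)


@pytest.fixture
def bs_centre() -> FieldLocation:
    return BS_CENTRE


def noiseless_observer(field, seed: int = 0) -> Observer:
    """Deterministic observer: a stimulus is seen iff it is at or below the
    true threshold (up to the vanishing psychometric spread)."""
    return Observer(
        true_field=field, slope_sd=1e-9, fp_rate=0.0, fn_rate=0.0, rng_seed=seed
    )


@pytest.fixture
def healthy_noiseless():
    fld = make_healthy_field(shadows=(), blind_spot=BlindSpotSpec(centre=BS_CENTRE))
    return noiseless_observer(fld)
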
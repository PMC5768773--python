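import pytest

from ventmix.isotope_core import Convention, IsotopeValue


@pytest.fixture
def iso():
    """Shorthand constructors for isotope values."""

    class _Iso:
        @staticmethod
        def f14c(v, s=0.0):
            return IsotopeValue(v, s, Convention.F14C)

        @staticmethod
        def d13c(v, s=0.0):
            return IsotopeValue(v, s, Convention.DELTA13C)

        @staticmethod
        def conc(v, s=0.0):
            return IsotopeValue(v, s, Convention.CONC)

    return _Iso


@pytest.fixture
def noise_free_truth():
    from ventmix.synthetic import GeneratorTruth

    return GeneratorTruth(noise_f14c=0.0, noise_d13c=0.0, noise_conc_rel=0.0, drop_f14c=())
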
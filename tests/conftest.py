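import pytest

from spinpre import BindingContext, SpinSystemParams


@pytest.fixture(scope="session")
def params():
    return SpinSystemParams()


@pytest.fixture(scope="session")
def ctx():
    return BindingContext()


def bisect_gamma2(ratio, params, lo=0.0, hi=1e7, iters=200):
    """Independent bisection oracle for the ratio -> Gamma2 inversion."""
    import math

    r2 = math.pi * params.linewidth_dia

    def forward(g):
        return r2 / (r2 + g) * math.exp(-g * params.t_evol)

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if forward(mid) > ratio:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
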
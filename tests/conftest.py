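import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def zero_params(module) -> None:
    """Zero every learnable parameter of a module tree (oracle convention)."""
    for _, p in module.named_parameters():
        p.data = np.zeros_like(p.data)


def numeric_gradient(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar-valued fn at x."""
    grad = np.zeros_like(x, dtype=np.float64)
    flat = grad.reshape(-1)
    xf = x.reshape(-1)
    for i in range(xf.size):
        orig = xf[i]
        xf[i] = orig + eps
        hi = fn(x)
        xf[i] = orig - eps
        lo = fn(x)
        xf[i] = orig
        flat[i] = (hi - lo) / (2 * eps)
    return grad
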
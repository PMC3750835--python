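import numpy as np
import pytest

from corrdiff import DWIStack


def brute_force_cdi(signal, bvalues, qmin, qmax, radii):
    """Independent nested-loop CDI estimator (the reference oracle).

    For every voxel, enumerates the in-bounds box neighborhood, multiplies
    the in-range signals per neighbor, and averages.  Deliberately written
    as plain loops, sharing no code with corrdiff.cdi_core.
    """
    nx, ny, nz, _ = signal.shape
    selected = [i for i, b in enumerate(bvalues) if qmin <= b <= qmax]
    rx, ry, rz = radii
    out = np.empty((nx, ny, nz))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                total = 0.0
                count = 0
                for xx in range(max(0, x - rx), min(nx, x + rx + 1)):
                    for yy in range(max(0, y - ry), min(ny, y + ry + 1)):
                        for zz in range(max(0, z - rz), min(nz, z + rz + 1)):
                            prod = 1.0
                            for i in selected:
                                prod *= signal[xx, yy, zz, i]
                            total += prod
                            count += 1
                out[x, y, z] = total / count
    return out


@pytest.fixture
def random_stack():
    def make(shape=(8, 8, 8, 3), seed=0, spacing=(1.0, 1.0, 1.0), bvalues=None):
        rng = np.random.default_rng(seed)
        if bvalues is None:
            bvalues = list(np.linspace(0, 2000, shape[3]))
        signal = rng.uniform(0.1, 1.0, size=shape)
        return DWIStack(signal=signal, bvalues=bvalues, spacing=spacing)

    return make
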
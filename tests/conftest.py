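import numpy as np
import pytest

import engramkit as ek


@pytest.fixture(scope="session")
def noiseless_render():
    """One noiseless slice plus its ground truth (shared; rendering is slow)."""
    rp = ek.RenderParams(seed=5, noise_sd=0.0, background_level=0.0)
    truth = ek.EnsembleGroundTruth(n_cells=300, p_gfp=0.05, p_fos=0.05,
                                   rho=0.40)
    bundle, table = ek.render_slice(truth, rp)
    return bundle, table


@pytest.fixture(scope="session")
def noisy_render():
    """One slice at the default SNR plus its ground truth."""
    rp = ek.RenderParams(seed=11)
    truth = ek.EnsembleGroundTruth(n_cells=300, p_gfp=0.05, p_fos=0.05,
                                   rho=0.40)
    bundle, table = ek.render_slice(truth, rp)
    return bundle, table


@pytest.fixture
def fixed_params():
    """Detection settings that make the noiseless path fully deterministic."""
    return ek.DetectionParams(threshold_mode="fixed", threshold_value=75.0,
                              background_radius=None)


def truth_counts(table, region="total"):
    """Ground-truth (hoechst, gfp, fos, overlap) from a per-cell table."""
    sub = table if region == "total" else table[table.region == region]
    return (
        len(sub),
        int(sub.gfp.sum()),
        int(sub.fos.sum()),
        int((sub.gfp & sub.fos).sum()),
    )
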
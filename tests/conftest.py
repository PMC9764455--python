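import numpy as np
import pytest

from phenoquant import synthetic, microenv


@pytest.fixture(scope="session")
def standard_phantom():
    """The standard confocal phantom: 100 sites at peak SNR 5, seed 1."""
    cfg = synthetic.ConfocalPhantomConfig(n_sites=100, site_peak_snr=5.0,
                                          seed=1)
    stack, truth = synthetic.gen_confocal_phantom(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def enrichment_phantom():
    """Noiseless phantom with a 2-fold Gaussian enrichment (sigma 0.5 um)
    around well-separated sites."""
    cfg = synthetic.ConfocalPhantomConfig(
        shape_voxels=(40, 256, 256), n_sites=20, site_peak_snr=10.0,
        enrichment_amplitude=2.0, enrichment_sigma_um=0.5,
        min_separation_um=2.5, noise_model="none", seed=2)
    stack, truth = synthetic.gen_confocal_phantom(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def noiseless_ion_phantom():
    cfg = synthetic.IonPhantomConfig(n_larvae=10, noise_sd=0.0, seed=7)
    stack, truth = synthetic.gen_ion_phantom(cfg)
    return cfg, stack, truth


def match_events(detected_times, true_times, tol_s=2.0):
    """Greedy 1-1 matching of event times; returns (tp, fp, fn)."""
    used = set()
    tp = 0
    det = list(detected_times)
    for t in true_times:
        cands = [i for i, d in enumerate(det)
                 if abs(d - t) <= tol_s and i not in used]
        if cands:
            used.add(min(cands, key=lambda i: abs(det[i] - t)))
            tp += 1
    return tp, len(det) - tp, len(true_times) - tp
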
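import numpy as np
import pytest

from livesort.simulate import make_probe, make_templates, make_units, simulate_trains, render_recording
from livesort.train import TrainParams, TemplateBank, compute_pair_cc, learn_templates
from livesort.preprocess import PreprocSpec


@pytest.fixture(scope="session")
def small_bank():
    """A hand-built 3-template bank on an 8-channel probe (no learning)."""
    geom = make_probe(8)
    templates, peaks, widths = make_templates(geom, 3, seed=7, M=61)
    # bank templates live in the matcher's common-mode-rejected subspace
    templates = templates - templates.mean(axis=2, keepdims=True)
    basis = np.linalg.svd(
        templates.transpose(0, 2, 1).reshape(-1, 61), full_matrices=False
    )[2][:6]
    feats = np.einsum("pm,kmc->kpc", basis, templates)
    return TemplateBank(
        templates=templates,
        pca_basis=basis,
        template_features=feats,
        pair_cc=compute_pair_cc(templates),
        detect_threshold=50.0,
        centroids=feats.reshape(3, -1),
        template_to_cluster=np.arange(3),
        min_isi_samples=15,
        preproc=PreprocSpec(fs=30000.0),
        geometry=geom,
    )


@pytest.fixture(scope="session")
def short_session():
    """A 12 s noisy 10-unit session with its learned bank (shared; ~25 s)."""
    geom = make_probe(16)
    units = make_units(geom, 10, seed=1)
    gt = simulate_trains(units, 12.0, None, seed=3, geometry=geom)
    rec = render_recording(gt, noise_sd_uv=10.0, amp_jitter=0.1, seed=4)
    bank = learn_templates(rec, TrainParams(min_train_s=12.0, seed=0))
    return {"geom": geom, "units": units, "gt": gt, "rec": rec, "bank": bank}
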
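"""Shared fixtures: synthetic benchmarks generated at test time."""

import numpy as np
import pytest

from synaptomap import detect, synth


@pytest.fixture(scope="session")
def snr5_benchmark():
    """The standard detection benchmark: SNR 5, ~0.5 puncta/um^2.

    Returns a trained classifier plus a held-out image with its truth, so
    detection tests score against planted ground truth.
    """
    bank = detect.psd95_bank()
    train_spec = synth.TruthSpec(seed=101)
    test_spec = synth.TruthSpec(seed=102)
    feats, labels = [], []
    for spec in (train_spec,):
        stack, truth = synth.synth_image(spec)
        img = stack.data[0]
        cands = detect.candidate_puncta(img)
        f = detect.nld_features(img, cands, bank)
        t0 = truth[truth["channel"] == 0]
        lab = detect.label_candidates(cands, t0[["y_px", "x_px"]].to_numpy())
        feats.append(f)
        labels.append(lab)
    model = detect.train_punctum_classifier(
        np.vstack(feats), np.concatenate(labels), seed=0)
    stack, truth = synth.synth_image(test_spec)
    return dict(model=model, bank=bank, test_image=stack.data[0],
                test_truth=truth[truth["channel"] == 0],
                pixel_size_nm=test_spec.pixel_size_nm)


@pytest.fixture(scope="session")
def planted_mixture_small():
    """3 well-separated components in 6-D for clustering tests."""
    mix = synth.MixtureSpec(components={1: 3}, separation=8.0, seed=7)
    return synth.synth_param_table(mix, 600)
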
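"""Shared fixtures: phantom cases and one session-scoped overfit model.

The overfit model (a reduced network trained on a single phantom volume)
is expensive to build, so it is trained once per session and shared by the
learning-sanity, saliency, equivariance and determinism tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from pkseg.evaluation import dice
from pkseg.inference import predict_case
from pkseg.phantom import PhantomSpec, render_phantom
from pkseg.preprocessing import (compute_foreground_box, fit_fingerprint,
                                 prepare_case)
from pkseg.training import PreparedCase, TrainConfig, train_on_cases
from pkseg.unet import NetConfig

#: spacing used for desk-scale training fixtures: coarser in-plane than the
#: canonical geometry so a 32^3 patch spans organ-scale context
FIXTURE_SPACING = (0.8, 0.6, 0.6)

TINY_NET = dict(patch_size=(32, 32, 32), strides=None, n_resolutions=3,
                base_kernels=16)


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def zero_noise_spec() -> PhantomSpec:
    return PhantomSpec(seed=11, ct_noise_sd=0.0, pet_noise_sd_kbq_cc=0.0)


@pytest.fixture(scope="session")
def rendered_case(phantom_spec):
    return render_phantom(phantom_spec, 6.0)


@pytest.fixture(scope="session")
def prepared_case(rendered_case) -> PreparedCase:
    ct, pet, labels, meta = rendered_case
    box = compute_foreground_box(ct)
    fp = fit_fingerprint([ct], [box], target_spacing=FIXTURE_SPACING)
    ct_p, pet_p, lab_p = prepare_case(ct, pet, labels, fp)
    return PreparedCase(ct=ct_p, pet=pet_p, labels=lab_p, meta=meta)


@pytest.fixture(scope="session")
def overfit_model(prepared_case):
    """Reduced network overfitted to one phantom volume (flip augmentation on).

    Returns (model, training log, per-organ DSC on the training volume).
    """
    net_cfg = NetConfig(in_channels=2, n_classes=7, **TINY_NET)
    train_cfg = TrainConfig(epochs=50, patches_per_epoch=8, seed=5,
                            augment_flip=True)
    model, log = train_on_cases([prepared_case], net_cfg, train_cfg)
    pred = predict_case(model, prepared_case)
    ref = prepared_case.labels.data
    dscs = {lab: dice(pred.data == lab, ref == lab) for lab in range(1, 7)}
    return model, log, dscs
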
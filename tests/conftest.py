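import numpy as np
import pytest

from desep import segnet
from desep.phantoms import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def desk_seg():
    """Desk U-Net trained on 20 phantoms for 30 epochs, plus 10 held-out
    phantoms. Shared across tests that need a trained segmentation model."""
    cfg = PhantomConfig.desk(n_patients=30, seed=999)
    cohort = generate_cohort(cfg, with_followups=False)
    net_cfg = segnet.UNetConfig.preset("desk", seed=999)
    model = segnet.build_model(net_cfg)
    segnet.train(model,
                 [(p.baseline_volume, p.baseline_mask) for p in cohort[:20]],
                 net_cfg)
    return model, cohort[:20], cohort[20:]


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient desk cohort with follow-ups, planted signal on."""
    cfg = PhantomConfig.desk(n_patients=40, seed=5, log_hr_morphology=1.5)
    return generate_cohort(cfg), cfg
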
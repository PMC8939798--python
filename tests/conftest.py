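import numpy as np
import pytest

from biocal import calibration, synthetic


@pytest.fixture(scope="session")
def glucose_fit():
    """Glucose calibration model fitted to one seeded synthetic dataset."""
    true = synthetic.true_glucose_model()
    x, y = synthetic.generate_calibration_data(true, synthetic.glucose_standards(), seed=4)
    model = calibration.make_model(
        x, y, trend="asymmetric_logistic", independent_key="S", dependent_key="absorbance"
    )
    return calibration.fit_mle(model, x, y)


@pytest.fixture(scope="session")
def linear_normal_model():
    """Identity-trend normal-noise model on [0, 10]: mu = x, sigma = 0.5."""
    return calibration.CalibrationModel(
        noise=calibration.NoiseSpec(family="normal", trend="polynomial", trend_degree=1, scale_degree=0),
        theta=np.array([0.0, 1.0, 0.5]),
        cal_x=np.linspace(0.0, 10.0, 20),
        cal_y=np.linspace(0.0, 10.0, 20),
    )


@pytest.fixture(scope="session")
def growth28():
    """Default 28-well synthetic growth experiment with its ground truth."""
    cfg = synthetic.GrowthExperimentConfig(seed=0)
    ds, truth = synthetic.generate_growth_dataset(cfg, return_truth=True)
    return ds, truth
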
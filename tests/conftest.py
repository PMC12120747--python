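import numpy as np
import pytest

from organovote import GeneratorConfig, generate_cohort


def disc_mask(radius_px: int, pad: int = 4) -> np.ndarray:
    """Binary disc of the given radius (pixel-centre inclusion)."""
    side = 2 * radius_px + 2 * pad
    yy, xx = np.mgrid[:side, :side]
    c = side / 2 - 0.5
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def ellipse_mask(a_px: int, b_px: int, pad: int = 4) -> np.ndarray:
    side = 2 * max(a_px, b_px) + 2 * pad
    yy, xx = np.mgrid[:side, :side]
    c = side / 2 - 0.5
    return ((xx - c) / a_px) ** 2 + ((yy - c) / b_px) ** 2 <= 1.0


class StubModel:
    """Duck-typed classifier returning a fixed or seeded random vote stream."""

    def __init__(self, label=None, p_correct=None, truth_column="cea_class", seed=0):
        self.label = label
        self.p_correct = p_correct
        self.truth_column = truth_column
        self.rng = np.random.default_rng(seed)

    def predict(self, frame):
        n = len(frame)
        if self.label is not None:
            return np.array([self.label] * n, dtype=object)
        truth = frame[self.truth_column].to_numpy(dtype=object)
        correct = self.rng.random(n) < self.p_correct
        flip = {"High": "Low", "Low": "High"}
        return np.array([t if ok else flip[t] for t, ok in zip(truth, correct)], dtype=object)


@pytest.fixture(scope="session")
def eba_cohort():
    """Moderate no-separation Eba cohort shared across read-only tests."""
    cfg = GeneratorConfig(n_high_patients=3, n_low_patients=2,
                          pdos_per_patient_per_batch=60, seed=11)
    return generate_cohort(cfg)
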
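import numpy as np
import pytest

from structassess import synthetic as syn

# Per-residue mean pLDDT of the binding-site key residues in the published
# AlphaFold models of the human P2X7 receptor, and the site global averages
# (used both as aggregation inputs and as planted profiles).
AF2_ORTHOSTERIC = {64: 90.65, 66: 90.94, 189: 92.86, 292: 80.30, 294: 86.87, 311: 93.78}
AF2_ALLOSTERIC = {88: 90.65, 95: 77.73, 103: 85.82, 105: 92.00, 293: 83.90, 312: 93.72}
AF3_ORTHOSTERIC = {64: 86.13, 66: 84.82, 189: 88.06, 292: 83.42, 294: 84.64, 311: 87.68}
AF3_ALLOSTERIC = {88: 81.18, 95: 74.12, 103: 82.18, 105: 86.68, 293: 84.25, 312: 88.47}
AF2_ORTHOSTERIC_GLOBAL = 89.23
AF2_ALLOSTERIC_GLOBAL = 87.30
AF3_ORTHOSTERIC_GLOBAL = 85.79


@pytest.fixture
def trimer():
    """60-residue poly-alanine trimer with uniform confidence 80."""
    model, truth = syn.make_trimer(syn.FixtureSpec(seed=11, n_residues=60))
    return model, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
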
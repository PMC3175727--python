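"""The seven speller classifiers behind one signed-score contract.

Five linear models — Fisher's LDA, stepwise LDA, Bayesian LDA,
least-squares linear SVM and a negentropy-based discriminative
projection — plus two nonlinear ones: a Gaussian-kernel SVM and a small
sigmoidal feed-forward network.  Every model fits on a balanced +/-1
training set and scores a feature vector with a signed distance to the
class boundary (positive = target).
"""

from .base import BoundaryClassifier, score
from .blda import BayesianLDA
from .fe import NegentropyProjection, mutual_information_objective, negentropy
from .linear import EmptyModelError, FisherLDA, StepwiseLDA
from .nn import SigmoidNet, n_parameters
from .svm import (
    KernelSVM,
    LinearLSSVM,
    LSSVM_GAMMA_GRID,
    RBF_C_GRID,
    RBF_GAMMA_GRID,
)

#: Canonical method labels used throughout the evaluation harness.
METHODS = {
    "lda": FisherLDA,
    "swlda": StepwiseLDA,
    "blda": BayesianLDA,
    "svm": LinearLSSVM,
    "nsvm": KernelSVM,
    "fe": NegentropyProjection,
    "nn": SigmoidNet,
}

__all__ = [
    "BoundaryClassifier",
    "score",
    "FisherLDA",
    "StepwiseLDA",
    "EmptyModelError",
    "BayesianLDA",
    "LinearLSSVM",
    "KernelSVM",
    "NegentropyProjection",
    "mutual_information_objective",
    "negentropy",
    "SigmoidNet",
    "n_parameters",
    "METHODS",
    "LSSVM_GAMMA_GRID",
    "RBF_C_GRID",
    "RBF_GAMMA_GRID",
]
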
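import numpy as np
import pytest

from genrisksim import SNPSpec, StudySpec


def brute_force_auc(case_scores, control_scores):
    """O(n^2) pair-counting AUC oracle: P(case > control) + 0.5 P(tie)."""
    total = 0.0
    for x in case_scores:
        for y in control_scores:
            total += (x > y) + 0.5 * (x == y)
    return total / (len(case_scores) * len(control_scores))


@pytest.fixture
def null_panel():
    """Three SNPs with OR = 1: no association with disease."""
    return [
        SNPSpec("null1", 0.2, 1.0),
        SNPSpec("null2", 0.5, 1.0),
        SNPSpec("null3", 0.7, 1.0),
    ]


@pytest.fixture
def small_panel():
    """Three SNPs with heterogeneous effects and Woolf-symmetric CIs."""
    def with_ci(snp_id, raf, orv, sd=0.05):
        z = 1.959964
        return SNPSpec(snp_id, raf, orv,
                       ci_low=orv * np.exp(-z * sd), ci_high=orv * np.exp(z * sd))
    return [with_ci("a", 0.2, 1.2), with_ci("b", 0.5, 1.5), with_ci("c", 0.7, 2.0)]


@pytest.fixture
def small_study(small_panel):
    return StudySpec(
        study_id="small", disease="test", d=0.2, model_type="bayes",
        snps=tuple(small_panel), n_sim=20_000, n_iter=5,
    )
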
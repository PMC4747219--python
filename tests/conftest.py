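import numpy as np
import pytest

from sagp_risk.data_model import ClinicalRecord, CohortBundle, ExpressionMatrix
from sagp_risk.rddg import PartitionDesign, PartitionModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def q1_model():
    """Single-quadrant HR sector (both genes high), cutoffs at the origin."""
    return PartitionModel(
        pair_id="pair",
        design=PartitionDesign(1, frozenset({"Q1"})),
        angle_index=0,
        c1=0.0,
        c2=0.0,
        fit=None,
        mode="DDG2D",
    )


@pytest.fixture
def small_bundle():
    """Five-sample cohort with two correlated features and survival labels."""
    expr = ExpressionMatrix(
        ["gA", "gB", "gC"],
        ["s1", "s2", "s3", "s4", "s5"],
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0, 5.0],
                [1.5, 2.5, 2.9, 4.2, 5.1],
                [5.0, 1.0, 4.0, 2.0, 3.0],
            ]
        ),
    )
    clinical = [
        ClinicalRecord("s1", 1.0, 1, grade="G3", subtype="basal", cohort="c"),
        ClinicalRecord("s2", 2.0, 0, grade="G3", subtype="basal", cohort="c"),
        ClinicalRecord("s3", 3.0, 1, grade="G3", subtype="non_basal", cohort="c"),
        ClinicalRecord("s4", 4.0, 0, grade="G1", subtype="non_basal", cohort="c"),
        ClinicalRecord("s5", 5.0, 1, grade="G3", subtype="basal", cohort="c"),
    ]
    return CohortBundle(expr, clinical, "c")


def exponential_cohort(rng, n=120, beta=1.0, frac_hr=0.4, h0=0.1, cmax=12.0):
    """Simple PH survival fixture with a known binary risk group."""
    group = rng.random(n) < frac_hr
    t_event = rng.exponential(1.0 / (h0 * np.exp(beta * group)))
    t_cens = rng.uniform(0, cmax, n)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return times, events, group.astype(int)
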
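import pytest

from folcog.derivations import Cohort, apply_eligibility, derive_flags
from folcog.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort (n=2204) with derived flags, post-eligibility."""
    df, truth = generate_cohort(SyntheticConfig(seed=0))
    cohort = derive_flags(Cohort(data=df, source="synthetic"))
    kept, log = apply_eligibility(cohort)
    return {"raw": df, "truth": truth, "cohort": kept, "exclusions": log}


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort (n=400) for fast unit tests."""
    df, truth = generate_cohort(SyntheticConfig(n=400, seed=42))
    return df, truth
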
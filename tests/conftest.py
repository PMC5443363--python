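import pandas as pd
import pytest

from bmiage import lms, synth


@pytest.fixture(scope="session")
def reference() -> lms.LMSReferenceTable:
    """Default synthetic two-sex LMS reference table."""
    return synth.make_reference()


@pytest.fixture(scope="session")
def reference_csv(reference, tmp_path_factory):
    """The reference written to disk in the canonical CSV schema."""
    path = tmp_path_factory.mktemp("ref") / "synthetic_ref.csv"
    frame = reference.frame
    frame["sex"] = frame["sex"].map(lambda s: s.value)
    frame.to_csv(path, index=False)
    return path


@pytest.fixture()
def small_cohort_csv(tmp_path):
    """A hand-written three-row cohort file."""
    path = tmp_path / "BMI_Data.csv"
    pd.DataFrame(
        {
            "ID": [1, 2, 3],
            "Sex": ["F", "male", "F"],
            "Age_y": [10.5, 4.25, 17.9],
            "Height_cm": [140.0, 105.0, 165.0],
            "Weight_kg": [35.0, 17.5, 58.0],
            "BMI": ["", "", ""],
        }
    ).to_csv(path, index=False)
    return path
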
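import pandas as pd
import pytest

from metaepi import make_dataset


def trial_row(
    ma_id="MA001",
    trial_id="T1",
    setting="ST",
    events_exp=10,
    n_exp=50,
    events_ctrl=12,
    n_ctrl=50,
    sample_size=100,
    **extra,
):
    row = {
        "ma_id": ma_id,
        "trial_id": trial_id,
        "setting": setting,
        "events_exp": events_exp,
        "n_exp": n_exp,
        "events_ctrl": events_ctrl,
        "n_ctrl": n_ctrl,
        "sample_size": sample_size,
    }
    row.update(extra)
    return row


def ma_row(
    ma_id="MA001",
    review_id="R001",
    review_year=2018,
    medical_field="pneumology",
    intervention_type="pharmacological",
    control_type="placebo",
    outcome_class="objective",
    benefit_direction="event_harmful",
    is_primary_outcome=True,
):
    return dict(
        ma_id=ma_id,
        review_id=review_id,
        review_year=review_year,
        medical_field=medical_field,
        intervention_type=intervention_type,
        control_type=control_type,
        outcome_class=outcome_class,
        benefit_direction=benefit_direction,
        is_primary_outcome=is_primary_outcome,
    )


def build_dataset(trial_rows, ma_rows):
    return make_dataset(pd.DataFrame(trial_rows), pd.DataFrame(ma_rows))


@pytest.fixture
def minimal_dataset():
    """One MA with a PC trial and two ST trials: smallest eligible shape."""
    trials = [
        trial_row(trial_id="T1", setting="PC", events_exp=8, events_ctrl=14),
        trial_row(trial_id="T2", setting="ST"),
        trial_row(trial_id="T3", setting="ST", events_exp=9, events_ctrl=11),
    ]
    return build_dataset(trials, [ma_row()])
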
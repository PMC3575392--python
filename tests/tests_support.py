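"""Helpers shared by tests (importable, unlike conftest fixtures)."""

import numpy as np

from rxagsp.io import ExpressionCohort


def make_simple_cohort(values, time=None, event=None, cohort_id="c"):
    values = np.asarray(values, dtype=float)
    return ExpressionCohort(
        cohort_id=cohort_id,
        genes=[f"g{i}" for i in range(values.shape[0])],
        samples=[f"s{i}" for i in range(values.shape[1])],
        values=values,
        time=time,
        event=event,
    )
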
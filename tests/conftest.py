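import numpy as np
import pandas as pd
import pytest

from mircargo.diffexpr import CONTROL, TREATED, ExpressionMatrix
from mircargo.qpcr import CtCard


def make_matrix(values, transcript_ids=None) -> ExpressionMatrix:
    """ExpressionMatrix from a (transcripts x 2n) array: first half control."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1] // 2
    samples = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
    ids = transcript_ids or [f"tx{i}" for i in range(values.shape[0])]
    groups = pd.Series([CONTROL] * n + [TREATED] * n, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=ids, columns=samples), groups)


def make_card(ct_by_target, condition="ev", spike_id="spike", spike_ct=24.0,
              ntc=None, preps=None) -> CtCard:
    """CtCard from {target: [ct per prep]} (None = non-detect).

    ``ntc`` optionally maps target -> NTC Ct (None = clean non-detect);
    targets without an entry get no NTC well.
    """
    n_preps = len(next(iter(ct_by_target.values())))
    preps = preps or [f"p{i + 1}" for i in range(n_preps)]
    rows = []
    for prep_i, prep in enumerate(preps):
        rows.append({"target_id": spike_id, "prep_id": prep, "ct": spike_ct,
                     "is_ntc": False, "is_spike_in": True})
        for target, cts in ct_by_target.items():
            ct = cts[prep_i]
            rows.append({"target_id": target, "prep_id": prep,
                         "ct": np.nan if ct is None else float(ct),
                         "is_ntc": False, "is_spike_in": False})
    for target, ct in (ntc or {}).items():
        rows.append({"target_id": target, "prep_id": "NTC",
                     "ct": np.nan if ct is None else float(ct),
                     "is_ntc": True, "is_spike_in": False})
    return CtCard(pd.DataFrame(rows), condition=condition)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
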
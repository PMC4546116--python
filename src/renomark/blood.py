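"""Blood-marker summary statistics: test/control ratios, reduction factors
and fold increases from measured or synthetic blood panels."""

from __future__ import annotations

import numpy as np
import pandas as pd


class UndefinedRatioError(ZeroDivisionError):
    """A control-group mean of zero makes the ratio undefined."""


def derive_ratios(test_panels, control_panels) -> pd.DataFrame:
    """Per-analyte test/control summaries over groups of blood panels.

    percent_of_control = 100 * mean(test) / mean(control);
    reduction_factor = 100 / percent, rounded to one decimal (how many times
    lower than control); fold_increase = percent / 100, with ``fold_int``
    rounded to the nearest integer for "n-fold" phrasing.
    """
    if not test_panels or not control_panels:
        raise ValueError("both panel lists must be non-empty")
    analytes = sorted(test_panels[0].values)
    for p in list(test_panels) + list(control_panels):
        if sorted(p.values) != analytes:
            raise ValueError("panels must share the same analyte set")
    rows = []
    for analyte in analytes:
        t = float(np.mean([p.values[analyte] for p in test_panels]))
        c = float(np.mean([p.values[analyte] for p in control_panels]))
        if c == 0:
            raise UndefinedRatioError(f"control mean for {analyte!r} is zero")
        percent = 100.0 * t / c
        rows.append(
            {
                "analyte": analyte,
                "percent_of_control": percent,
                "reduction_factor": round(100.0 / percent, 1),
                "fold_increase": percent / 100.0,
                "fold_int": int(round(percent / 100.0)),
            }
        )
    return pd.DataFrame(rows)
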
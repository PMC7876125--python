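"""Bundled reference datasets.

``load_method_comparison_panel`` returns the blood cyanide method-comparison
panel: 30 volunteers in six exposure groups (controls, firemen — each split by
smoking status — and non-fatal/fatal fire casualties), each measured in five
determinations by the paper sensor and by GC/MS.  Per-sample columns give the
mean and sample SD for each method plus the originally reported t statistic
and relative error, kept for cross-checking.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_method_comparison_panel", "GROUP_ORDER"]

#: Canonical group ordering of the panel.
GROUP_ORDER = (
    "control_nonsmoker",
    "control_smoker",
    "firemen_nonsmoker",
    "firemen_smoker",
    "nonfatal_casualties",
    "fatal_casualties",
)


def load_method_comparison_panel() -> pd.DataFrame:
    path = resources.files("padsense") / "data" / "method_comparison_panel.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p)
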
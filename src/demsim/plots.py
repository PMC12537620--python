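"""Optional matplotlib views of the scenario comparisons."""

from __future__ import annotations

import numpy as np

from .outcomes import ScenarioComparison


def plot_avoidable_cases(table, ax=None):
    """Bar chart of percent avoidable cases per scenario (one sex)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = table[table["scenario"] != "reference"]
    ax.bar(t["scenario"], -t["total_cases_pct_change"])
    ax.set_ylabel("potentially avoidable dementia cases (%)")
    ax.tick_params(axis="x", rotation=60)
    ax.axhline(0, color="k", lw=0.8)
    return ax


def plot_byage_differences(cmp: ScenarioComparison, ax=None, per_100k=False):
    """By-age case difference curve, absolute or per 100,000 life years."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    y = cmp.per_100k_cases_diff if per_100k else cmp.by_age_cases_diff
    ax.plot(np.arange(len(y)), y, label=cmp.scenario)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("age")
    ax.set_ylabel(
        "case difference per 100,000 life years" if per_100k else "case difference"
    )
    ax.legend()
    return ax


def plot_tornado(tornado, sex: str, scenario: str, ax=None):
    """Horizontal lower/point/upper bars per parameter (one scenario)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = tornado[(tornado["sex"] == sex) & (tornado["scenario"] == scenario)]
    ypos = np.arange(len(t))
    ax.barh(ypos, t["upper"] - t["lower"], left=t["lower"], height=0.6, alpha=0.6)
    ax.plot(t["point"], ypos, "k|", markersize=12)
    ax.set_yticks(ypos, t["parameter"])
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("potentially avoidable dementia cases (%)")
    ax.set_title(f"{sex}, {scenario}")
    return ax
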